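"""Token counting and relative contributions (adaptiveness) for codons/dicodons.

Given a reference set of coding sequences, token counts o_t are turned into
relative adaptiveness a_t = o_t / max{o_t'} where the maximum runs over the
token's synonymy class (synonymous codons, or dicodons encoding the same
ordered dipeptide).  With expression weighting, counts become
b_t = sum_i o_t(s_i) w(s_i) and the weighted contribution is
f_t = b_t / max{b_t'} over the same classes.  A value of 1 marks the
translationally optimal member of each class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genetic_code import GeneticCode, STANDARD_CODE
from .seq_io import CodingSequence, tokenize_codons, tokenize_dicodons

__all__ = [
    "CountTable",
    "ContributionTable",
    "count_tokens",
    "weighted_count_tokens",
    "relative_adaptiveness",
    "power_transform",
    "expected_product_table",
]

logger = logging.getLogger(__name__)

#: Floor for contributions of tokens that are unobservable in the reference
#: set; far below any meaningful contribution, so it cannot mask signal.
DEFAULT_EPSILON = 1e-12

#: Pseudo-count added to zero integer counts within observed synonymy
#: classes (classic CAI convention); not used on the weighted path.
DEFAULT_PSEUDOCOUNT = 0.5


def _tokenize(seq: CodingSequence, arity: int, code: GeneticCode) -> list[str]:
    if arity == 1:
        return tokenize_codons(seq, code)
    if arity == 2:
        return tokenize_dicodons(seq, code)
    raise ValueError(f"arity must be 1 or 2, got {arity!r}")


@dataclass(frozen=True)
class CountTable:
    """Token -> non-negative real count over a sequence set.

    ``weighted`` marks expression-weighted counts; ``total_weight`` records
    the normalizing sum of weights (the number of sequences when unweighted).
    """

    arity: int
    counts: dict[str, float]
    weighted: bool
    total_weight: float
    #: un-normalized weighted sums (sum_i o_t(s_i) w(s_i)); kept so that the
    #: per-class ratio can be formed before the division by the total weight,
    #: which makes the constant-weight reduction to plain counts bitwise exact
    raw_counts: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")

    def ratio_basis(self) -> dict[str, float]:
        """The counts that per-class normalization should be computed from."""
        return self.raw_counts if self.raw_counts is not None else self.counts


@dataclass(frozen=True)
class ContributionTable:
    """Token -> relative contribution in (0, 1].

    ``kind`` is ``"a"`` for plain adaptiveness and ``"f"`` for the
    expression-weighted variant; ``power`` tracks exponentiation applied by
    :func:`power_transform` (1 for the plain geometric-mean index, 2 for the
    squared-contribution variant).
    """

    arity: int
    values: dict[str, float]
    kind: str
    power: float = 1.0
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.kind not in ("a", "f"):
            raise ValueError(f"kind must be 'a' or 'f', got {self.kind!r}")
        bad = [t for t, v in self.values.items() if not (0 < v <= 1)]
        if bad:
            raise ValueError(f"contributions outside (0, 1]: {bad[:5]!r}")

    def get(self, token: str) -> float:
        """Contribution of ``token``; the epsilon floor if absent."""
        return self.values.get(token, self.epsilon)

    # -- serialization ---------------------------------------------------

    def to_frame(self, code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
        rows = [
            {
                "token": t,
                "class": _class_label(t, code),
                "value": v,
                "kind": self.kind,
                "arity": self.arity,
                "power": self.power,
            }
            for t, v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path, code: GeneticCode = STANDARD_CODE) -> None:
        self.to_frame(code).to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContributionTable":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        required = {"token", "value", "kind", "arity", "power"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"contribution table missing columns: {sorted(missing)}")
        arities = df["arity"].unique()
        kinds = df["kind"].unique()
        powers = df["power"].unique()
        if len(arities) != 1 or len(kinds) != 1 or len(powers) != 1:
            raise ValueError("mixed arity/kind/power in contribution table")
        return cls(
            arity=int(arities[0]),
            values=dict(zip(df["token"], df["value"].astype(float))),
            kind=str(kinds[0]),
            power=float(powers[0]),
        )


def _class_label(token: str, code: GeneticCode) -> str:
    key = code.synonymy_class(token)
    return key if isinstance(key, str) else "".join(key)


def count_tokens(
    seqs: Sequence[CodingSequence],
    arity: int,
    code: GeneticCode = STANDARD_CODE,
) -> CountTable:
    """Plain token counts o_t summed over a sequence set.

    Every sense token of the requested arity is present in the output, with
    count 0 when unobserved.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    counts = dict.fromkeys(code.sense_tokens(arity), 0.0)
    for seq in seqs:
        for tok in _tokenize(seq, arity, code):
            counts[tok] += 1.0
    return CountTable(arity=arity, counts=counts, weighted=False, total_weight=float(len(seqs)))


def weighted_count_tokens(
    seqs: Sequence[CodingSequence],
    weights: Mapping[str, float],
    arity: int,
    code: GeneticCode = STANDARD_CODE,
) -> CountTable:
    """Expression-weighted counts b_t = sum_i o_t(s_i) w(s_i) / sum_i w(s_i).

    Sequences without a weight are skipped (and logged).  The division by
    the total weight is a bookkeeping normalization — it cancels in the
    per-class ratio that defines f_t.
    """
    counts = dict.fromkeys(code.sense_tokens(arity), 0.0)
    total_weight = 0.0
    n_skipped = 0
    for seq in seqs:
        w = weights.get(seq.gene_id)
        if w is None:
            n_skipped += 1
            continue
        if w < 0:
            raise ValueError(f"negative weight for {seq.gene_id!r}: {w}")
        if w == 0:
            continue
        total_weight += w
        for tok in _tokenize(seq, arity, code):
            counts[tok] += w
    if n_skipped:
        logger.info("weighted_count_tokens: skipped %d sequences without weights", n_skipped)
    if total_weight == 0:
        raise ValueError("all weights are zero or no sequence has a weight")
    normalized = {t: v / total_weight for t, v in counts.items()}
    return CountTable(
        arity=arity,
        counts=normalized,
        weighted=True,
        total_weight=total_weight,
        raw_counts=counts,
    )


def relative_adaptiveness(
    counts: CountTable,
    code: GeneticCode = STANDARD_CODE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    epsilon: float = DEFAULT_EPSILON,
) -> ContributionTable:
    """Counts -> per-class relative contributions (a_t, or f_t when weighted).

    Each token's count is divided by the largest count in its synonymy
    class, so every observed class has maximum exactly 1.  On the unweighted
    path, zero counts inside observed classes receive ``pseudocount`` before
    division; on the weighted path a zero stays zero and is floored at
    ``epsilon`` (near-zero weighted contributions are a finding, not noise
    to smooth away).  Classes with no observed member at all get ``epsilon``
    throughout.
    """
    values: dict[str, float] = {}
    kind = "f" if counts.weighted else "a"
    basis = counts.ratio_basis()
    for _, members in code.classes(counts.arity).items():
        class_counts = {t: basis.get(t, 0.0) for t in members}
        cmax = max(class_counts.values())
        if cmax == 0:
            for t in members:
                values[t] = epsilon
            continue
        for t, c in class_counts.items():
            if c == 0 and not counts.weighted and pseudocount > 0:
                c = pseudocount
            values[t] = max(c / cmax, epsilon)
    return ContributionTable(
        arity=counts.arity, values=values, kind=kind, power=1.0, epsilon=epsilon
    )


def power_transform(contribs: ContributionTable, k: float) -> ContributionTable:
    """Raise every contribution to the power ``k`` (k = 2: squared variant)."""
    if k <= 0:
        raise ValueError(f"power must be positive, got {k}")
    values = {t: v**k for t, v in contribs.values.items()}
    return replace(contribs, values=values, power=contribs.power * k)


def expected_product_table(
    codon_contribs: ContributionTable,
    code: GeneticCode = STANDARD_CODE,
) -> ContributionTable:
    """Expected dicodon contributions as products of codon contributions.

    For each sense dicodon (c1, c2) the expected value is
    contrib(c1) * contrib(c2); comparing it with directly estimated dicodon
    contributions exposes pair-level effects not reducible to single-codon
    usage.
    """
    if codon_contribs.arity != 1:
        raise ValueError("expected_product_table requires an arity-1 table")
    values = {
        a + b: codon_contribs.get(a) * codon_contribs.get(b)
        for a in code.sense_codons
        for b in code.sense_codons
    }
    values = {t: max(v, codon_contribs.epsilon) for t, v in values.items()}
    return ContributionTable(
        arity=2,
        values=values,
        kind=codon_contribs.kind,
        power=codon_contribs.power,
        epsilon=codon_contribs.epsilon,
    )
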