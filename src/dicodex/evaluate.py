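"""Evaluation of expression indexes against measured expression.

Covers: per-sample index-expression correlations, paired comparisons between
scoring schemes across samples, length-stratified correlations, comparison
of contribution distributions, the observed-vs-expected dicodon analysis
(does pair usage reduce to single-codon usage?), and screening for dicodons
with anomalously low weighted contributions — candidates for translational
inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contributions import ContributionTable, expected_product_table
from .expression_io import ExpressionProfile, length_strata
from .genetic_code import GeneticCode, STANDARD_CODE
from .index import IndexResult
from .seq_io import CodingSequence

__all__ = [
    "KNOWN_INHIBITORY_DICODONS",
    "SchemeCorrelation",
    "InhibitoryScreen",
    "correlate",
    "paired_scheme_test",
    "stratified_correlations",
    "distribution_compare",
    "low_contribution_screen",
    "expected_vs_observed",
]

#: The 17 codon pairs experimentally associated with strong translational
#: inhibition in S. cerevisiae (GFP reporter screen of random codon triplets).
KNOWN_INHIBITORY_DICODONS: tuple[str, ...] = (
    "AGGCGA", "ATACGA", "CGAATA", "CGACCG", "CGACGA", "CGACGG", "CGACTG",
    "CGAGCG", "CTGCGA", "GTACGA", "GTGCGA", "AGGCGG", "ATACGG", "CTCCCG",
    "CTGCCG", "CTGATA", "GTACCG",
)


@dataclass(frozen=True)
class SchemeCorrelation:
    sample_id: str
    scheme: str
    method: Literal["pearson", "spearman"]
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class InhibitoryScreen:
    threshold: float
    flagged: tuple[str, ...]  # ascending by contribution
    values: dict[str, float]
    known_overlap: tuple[str, ...]


def _index_values(index_map: Mapping[str, IndexResult | float]) -> dict[str, float]:
    return {
        g: (r.index if isinstance(r, IndexResult) else float(r))
        for g, r in index_map.items()
    }


def _expression_vector(profile: ExpressionProfile, genes: Sequence[str], scale: str) -> np.ndarray:
    raw = np.array([profile.values[g] for g in genes], dtype=float)
    if scale == "stored":
        return raw
    if scale == "log":
        if profile.scale == "log_normalized":
            return raw
        if np.any(raw <= 0):
            raise ValueError("log view requires positive linear expression values")
        return np.log(raw)
    if scale == "linear":
        return np.exp(raw) if profile.scale == "log_normalized" else raw
    raise ValueError(f"unknown expression scale view {scale!r}")


def correlate(
    index_map: Mapping[str, IndexResult | float],
    profile: ExpressionProfile,
    method: Literal["pearson", "spearman"] = "pearson",
    expression_scale: str = "linear",
    scheme: str = "",
    genes: Iterable[str] | None = None,
) -> SchemeCorrelation:
    """Correlation between an index map and an expression profile.

    Computed over the gene intersection (optionally restricted to ``genes``).
    ``expression_scale`` selects the view of expression entering the
    correlation: ``"linear"`` (the default; log-normalized microarray values
    are exponentiated before being treated as expression levels), ``"log"``,
    or ``"stored"``.  Spearman is invariant to that choice; Pearson is not.
    """
    values = _index_values(index_map)
    common = sorted(set(values) & profile.genes())
    if genes is not None:
        common = sorted(set(common) & set(genes))
    if len(common) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(common)}")
    x = np.array([values[g] for g in common])
    y = _expression_vector(profile, common, expression_scale)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant index or expression vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SchemeCorrelation(
        sample_id=profile.sample_id,
        scheme=scheme,
        method=method,
        r=float(r),
        p_value=float(p),
        n=len(common),
    )


def paired_scheme_test(
    r_vector_a: Sequence[float], r_vector_b: Sequence[float]
) -> tuple[float, float, float]:
    """Paired two-sided t-test comparing per-sample correlations of two schemes.

    Returns ``(mean difference B - A, t statistic, p-value)``.  Identical
    vectors (zero-variance differences) are an error rather than a NaN.
    """
    a = np.asarray(r_vector_a, dtype=float)
    b = np.asarray(r_vector_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("r vectors must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need >= 2 paired samples")
    diff = b - a
    if np.ptp(diff) == 0 and diff.std() == 0:
        raise ValueError("zero-variance differences: schemes are identical")
    t, p = stats.ttest_rel(b, a)
    return float(diff.mean()), float(t), float(p)


def stratified_correlations(
    seqs: Sequence[CodingSequence],
    index_map: Mapping[str, IndexResult | float],
    profile: ExpressionProfile,
    low_p: float = 20,
    high_p: float = 80,
    method: Literal["pearson", "spearman"] = "pearson",
    expression_scale: str = "linear",
    scheme: str = "",
) -> tuple[SchemeCorrelation, SchemeCorrelation]:
    """Correlations recomputed within short- and long-sequence strata."""
    short, long = length_strata(seqs, low_p=low_p, high_p=high_p)
    r_short = correlate(
        index_map, profile, method=method, expression_scale=expression_scale,
        scheme=scheme + ":short", genes=short,
    )
    r_long = correlate(
        index_map, profile, method=method, expression_scale=expression_scale,
        scheme=scheme + ":long", genes=long,
    )
    return r_short, r_long


def distribution_compare(
    contribs_a: ContributionTable, contribs_b: ContributionTable
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test between two contribution tables."""
    if contribs_a.arity != contribs_b.arity:
        raise ValueError("contribution tables have different arity")
    a = np.array(list(contribs_a.values.values()))
    b = np.array(list(contribs_b.values.values()))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty contribution table")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def low_contribution_screen(
    contribs: ContributionTable,
    threshold: float,
    known_inhibitors: Iterable[str] = KNOWN_INHIBITORY_DICODONS,
) -> InhibitoryScreen:
    """Flag dicodons whose contribution falls below ``threshold``.

    Returns the flagged tokens sorted ascending by contribution, plus the
    overlap with a supplied list of known inhibitory dicodons.  Dicodons
    with near-zero weighted contribution in highly expressed genes are
    candidates for mediating translational inhibition.
    """
    if contribs.arity != 2:
        raise ValueError("screen requires a dicodon (arity-2) table")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    flagged = sorted(
        (t for t, v in contribs.values.items() if v < threshold),
        key=lambda t: (contribs.values[t], t),
    )
    known = frozenset(known_inhibitors)
    overlap = tuple(t for t in flagged if t in known)
    return InhibitoryScreen(
        threshold=threshold,
        flagged=tuple(flagged),
        values={t: contribs.values[t] for t in flagged},
        known_overlap=overlap,
    )


def expected_vs_observed(
    dicodon_contribs: ContributionTable,
    codon_contribs: ContributionTable,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Observed dicodon contributions against single-codon products.

    Joins the directly estimated dicodon table with the expected table built
    from codon-contribution products (one row per sense dicodon, 3721 rows
    for the standard code).  The ``ratio`` column, observed / expected,
    highlights pairs whose usage departs from what single-codon frequencies
    predict; ratios far below 1 mark depleted (candidate inhibitory) pairs.
    """
    if dicodon_contribs.arity != 2 or codon_contribs.arity != 1:
        raise ValueError("need a dicodon table and a codon table")
    if (dicodon_contribs.kind, dicodon_contribs.power) != (
        codon_contribs.kind,
        codon_contribs.power,
    ):
        raise ValueError("kind/power mismatch between dicodon and codon tables")
    expected = expected_product_table(codon_contribs, code)
    rows = []
    for token in code.sense_dicodons:
        obs = dicodon_contribs.get(token)
        exp = expected.get(token)
        rows.append(
            {
                "token": token,
                "observed": obs,
                "expected": exp,
                "ratio": obs / exp if exp > 0 else math.inf,
            }
        )
    return pd.DataFrame(rows)
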