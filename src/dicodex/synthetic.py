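"""Synthetic CDS + expression fixtures with known bias structure.

The generator couples codon choice to expression through a logistic link:
gene i draws a log-expression E_i, and each of its codons is the amino
acid's preferred codon with probability pi_i = logistic(alpha * (E_i - E0)),
otherwise a uniformly chosen synonym.  On top of this single-codon bias, a
set of inhibitory dicodons D_inh is avoided specifically by highly expressed
genes: scanning left to right, a codon that would complete an inhibitory
pair is resampled (away from pair-forming codons) with probability
pi_i * inhibition_strength.  This is the minimal construction in which pair
usage carries information about expression that is not reducible to
single-codon frequencies — exactly what dicodon-based indexes are meant to
detect.

Default inhibitory pairs combine a preferred codon with a suboptimal codon
of a two-codon amino acid: pairs of this composition occur often enough in
a genome-scale simulation for their targeted depletion to be statistically
identifiable, while never being the optimal (class-maximal) pair that
per-class normalization would mask.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .expression_io import ExpressionProfile
from .genetic_code import GeneticCode, STANDARD_CODE
from .seq_io import RawRecord

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "default_preferred_codons",
    "default_inhibitory_dicodons",
    "simulate_genes",
    "write_fixture",
]


def default_preferred_codons(code: GeneticCode = STANDARD_CODE) -> dict[str, str]:
    """One preferred codon per amino acid (alphabetically first synonym)."""
    return {aa: codons[0] for aa, codons in sorted(code.classes(1).items())}


def default_inhibitory_dicodons(
    code: GeneticCode = STANDARD_CODE,
    preferred: dict[str, str] | None = None,
    n: int = 17,
) -> tuple[str, ...]:
    """A deterministic set of ``n`` planted inhibitory dicodons.

    Each pair is (preferred codon of aa1, non-preferred codon of a two-codon
    aa2), cycling over distinct amino-acid combinations.  See the module
    docstring for why this composition is used.
    """
    if preferred is None:
        preferred = default_preferred_codons(code)
    classes = code.classes(1)
    two_codon_aas = sorted(aa for aa, cs in classes.items() if len(cs) == 2)
    first_aas = sorted(classes)
    out: list[str] = []
    i = 0
    while len(out) < n:
        aa1 = first_aas[i % len(first_aas)]
        aa2 = two_codon_aas[i % len(two_codon_aas)]
        nonpref = [c for c in classes[aa2] if c != preferred[aa2]][0]
        token = preferred[aa1] + nonpref
        if token not in out:
            out.append(token)
        i += 1
    return tuple(out)


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults define the standard study conditions."""

    n_genes: int = 2000
    length_range: tuple[int, int] = (100, 600)  # codons, inclusive
    expr_mean: float = 2.0  # log-scale expression mean
    expr_sd: float = 1.5  # log-scale expression sd
    alpha: float = 2.0  # steepness of the expression->bias link
    e0: float = 2.0  # midpoint of the link (genes at E0 have pi = 0.5)
    preferred_codons: dict[str, str] = field(default_factory=default_preferred_codons)
    inhibitory_dicodons: tuple[str, ...] = field(
        default_factory=default_inhibitory_dicodons
    )
    inhibition_strength: float = 0.9
    seed: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 51:
            raise ValueError("lengths must be >= 51 codons so fixtures pass QC")
        if lo > hi:
            raise ValueError(f"invalid length range {self.length_range}")
        if not 0 <= self.inhibition_strength <= 1:
            raise ValueError("inhibition_strength must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Exactly what was simulated, for parameter-recovery checks."""

    expression: dict[str, float]
    pi: dict[str, float]  # realized preferred-codon mixing proportion per gene
    preferred_codons: dict[str, str]
    inhibitory_dicodons: tuple[str, ...]
    params: SimulationParams


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_genes(
    params: SimulationParams,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[list[RawRecord], ExpressionProfile, SyntheticTruth]:
    """Generate FASTA records, an expression profile, and the ground truth.

    Identical parameters (including the seed) give byte-identical output.
    Sequences are ATG + body + TAA, bodies drawn per the module docstring;
    amino acids are i.i.d. uniform over the 20 standard residues.
    """
    rng = np.random.default_rng(params.seed)
    classes = code.classes(1)
    aas = sorted(classes)  # 20 amino acids, deterministic order
    syn_lists = [list(classes[aa]) for aa in aas]
    pref_idx = []
    for aa, syns in zip(aas, syn_lists):
        pref = params.preferred_codons.get(aa)
        if pref not in syns:
            raise ValueError(f"preferred codon {pref!r} does not encode {aa!r}")
        pref_idx.append(syns.index(pref))
    d_inh = set(params.inhibitory_dicodons)
    for token in d_inh:
        if not code.is_sense_dicodon(token):
            raise ValueError(f"inhibitory dicodon {token!r} is not a sense dicodon")
    # codons allowed as the right member after an inhibitory left member
    blocked_after: dict[str, set[str]] = {}
    for token in d_inh:
        blocked_after.setdefault(token[:3], set()).add(token[3:])

    lo, hi = params.length_range
    n = params.n_genes
    width = len(str(n))
    records: list[RawRecord] = []
    expression: dict[str, float] = {}
    pis: dict[str, float] = {}
    e_values = rng.normal(params.expr_mean, params.expr_sd, size=n)
    lengths = rng.integers(lo, hi + 1, size=n)
    for i in range(n):
        gene_id = f"g{i + 1:0{width}d}"
        e_i = float(e_values[i])
        pi_i = _logistic(params.alpha * (e_i - params.e0))
        L = int(lengths[i])
        aa_idx = rng.integers(0, len(aas), size=L)
        use_pref = rng.random(L) < pi_i
        syn_draw = rng.random(L)
        codons: list[str] = []
        for j in range(L):
            syns = syn_lists[aa_idx[j]]
            if use_pref[j]:
                codons.append(syns[pref_idx[aa_idx[j]]])
            else:
                codons.append(syns[int(syn_draw[j] * len(syns))])
        if d_inh and params.inhibition_strength > 0:
            p_avoid = pi_i * params.inhibition_strength
            for j in range(1, L):
                blocked = blocked_after.get(codons[j - 1])
                if blocked is None or codons[j] not in blocked:
                    continue
                if rng.random() >= p_avoid:
                    continue
                alternatives = [c for c in syn_lists[aa_idx[j]] if c not in blocked]
                if alternatives:
                    codons[j] = alternatives[int(rng.random() * len(alternatives))]
        seq = "ATG" + "".join(codons) + "TAA"
        records.append(RawRecord(gene_id=gene_id, sequence=seq))
        expression[gene_id] = e_i
        pis[gene_id] = pi_i
    profile = ExpressionProfile(
        sample_id="sim", values=expression, scale="log_normalized"
    )
    truth = SyntheticTruth(
        expression=expression,
        pi=pis,
        preferred_codons=dict(params.preferred_codons),
        inhibitory_dicodons=tuple(params.inhibitory_dicodons),
        params=params,
    )
    return records, profile, truth


def write_fixture(
    params: SimulationParams,
    outdir: str | Path,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[Path, Path, Path]:
    """Write FASTA, expression TSV, and a JSON truth file into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, profile, truth = simulate_genes(params, code)
    fasta = outdir / "synthetic_cds.fa"
    with open(fasta, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for k in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[k : k + 60] + "\n")
    expr = outdir / "synthetic_expression.tsv"
    with open(expr, "w") as fh:
        fh.write("gene_id\tsim\n")
        for rec in records:
            fh.write(f"{rec.gene_id}\t{profile.values[rec.gene_id]:.10g}\n")
    truth_path = outdir / "synthetic_truth.json"
    payload = {
        "expression": truth.expression,
        "pi": truth.pi,
        "preferred_codons": truth.preferred_codons,
        "inhibitory_dicodons": list(truth.inhibitory_dicodons),
        "params": {
            **{
                k: v
                for k, v in asdict(truth.params).items()
                if k not in ("preferred_codons", "inhibitory_dicodons")
            },
            "length_range": list(truth.params.length_range),
        },
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return fasta, expr, truth_path
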