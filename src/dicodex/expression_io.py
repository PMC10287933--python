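"""Expression tables, per-gene weights, percentile reference sets, length strata.

A reference set S_p holds the genes whose expression lies strictly above the
p-th percentile of the sample; S_0 is the full gene set.  Contributions are
estimated on S_p, optionally weighting each gene's token counts by
w = exp(E) (log-normalized microarray values) or w = E (linear TPM).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .seq_io import CodingSequence

__all__ = [
    "ExpressionProfile",
    "ReferenceSet",
    "read_expression_table",
    "weights_from_expression",
    "select_reference_set",
    "length_strata",
]

logger = logging.getLogger(__name__)

Scale = Literal["log_normalized", "linear"]


@dataclass(frozen=True)
class ExpressionProfile:
    """One sample's gene -> expression map, tagged with its scale."""

    sample_id: str
    values: dict[str, float]
    scale: Scale

    def __post_init__(self) -> None:
        if self.scale not in ("log_normalized", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and any(v < 0 for v in self.values.values()):
            raise ValueError("linear-scale expression values must be >= 0")

    def genes(self) -> set[str]:
        return set(self.values)


@dataclass(frozen=True)
class ReferenceSet:
    """Genes with expression above percentile ``p`` in ``source_sample``."""

    p: float
    gene_ids: frozenset[str]
    source_sample: str
    threshold: float = field(default=float("nan"))


def read_expression_table(
    path: str | Path,
    scale: Scale,
    sep: str | None = None,
    gene_column: str | int = 0,
    duplicate_policy: Literal["error", "mean"] = "error",
) -> list[ExpressionProfile]:
    """Read a delimited expression table into one profile per sample column.

    The gene-ID column is the first column by default (name or position via
    ``gene_column``); every remaining numeric column becomes one
    :class:`ExpressionProfile`.  Missing (NA) cells are omitted from the
    corresponding profile.  The delimiter is inferred from the extension
    (.csv -> comma, otherwise tab) unless ``sep`` is given.
    """
    path = Path(path)
    if sep is None:
        name = path.name[:-3] if path.suffix == ".gz" else path.name
        sep = "," if name.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if isinstance(gene_column, int):
        gene_column = df.columns[gene_column]
    df[gene_column] = df[gene_column].astype(str)
    if df[gene_column].duplicated().any():
        if duplicate_policy == "error":
            dups = df[gene_column][df[gene_column].duplicated()].unique()
            raise ValueError(f"duplicate gene rows: {list(dups[:5])!r}")
        df = df.groupby(gene_column, as_index=False, sort=False).mean(numeric_only=True)
    sample_cols = [
        c for c in df.columns if c != gene_column and pd.api.types.is_numeric_dtype(df[c])
    ]
    if not sample_cols:
        raise ValueError(f"no numeric sample columns in {path}")
    profiles = []
    for col in sample_cols:
        sub = df[[gene_column, col]].dropna()
        values = dict(zip(sub[gene_column], sub[col].astype(float)))
        profiles.append(ExpressionProfile(sample_id=str(col), values=values, scale=scale))
    return profiles


def weights_from_expression(
    profile: ExpressionProfile, exp_base: float | None = None
) -> dict[str, float]:
    """Per-gene weights w(s_i) derived from expression.

    Log-normalized profiles use w = base**E (natural base by default,
    matching exponentiation of log-normalized microarray values); linear
    (TPM) profiles use w = E unchanged.
    """
    if profile.scale == "linear":
        if exp_base is not None:
            raise ValueError("exp_base applies only to log_normalized profiles")
        return dict(profile.values)
    if exp_base is None:
        return {g: math.exp(e) for g, e in profile.values.items()}
    if exp_base <= 1:
        raise ValueError(f"exp_base must be > 1, got {exp_base}")
    return {g: exp_base**e for g, e in profile.values.items()}


def select_reference_set(
    profile: ExpressionProfile,
    available_genes: Iterable[str],
    p: float,
) -> ReferenceSet:
    """Build the reference set S_p over genes with both sequence and expression.

    The p-th percentile is computed by linear interpolation over the
    intersection; membership requires expression strictly above it.  p = 0
    returns the full intersection.
    """
    if not 0 <= p < 100:
        raise ValueError(f"percentile must be in [0, 100), got {p}")
    pool = sorted(set(available_genes) & profile.genes())
    if not pool:
        raise ValueError(
            f"no genes shared between sequences and profile {profile.sample_id!r}"
        )
    if p == 0:
        return ReferenceSet(
            p=0.0,
            gene_ids=frozenset(pool),
            source_sample=profile.sample_id,
            threshold=-math.inf,
        )
    values = np.array([profile.values[g] for g in pool])
    threshold = float(np.percentile(values, p))
    members = frozenset(g for g in pool if profile.values[g] > threshold)
    return ReferenceSet(
        p=float(p),
        gene_ids=members,
        source_sample=profile.sample_id,
        threshold=threshold,
    )


def length_strata(
    seqs: Sequence[CodingSequence],
    low_p: float = 20,
    high_p: float = 80,
) -> tuple[set[str], set[str]]:
    """Split gene IDs into short/long strata by codon length percentiles.

    Short genes lie strictly below the ``low_p``-th percentile of codon
    length, long genes strictly above the ``high_p``-th.  A degenerate
    (constant) length distribution yields two empty strata with a warning.
    """
    if len(seqs) < 5:
        raise ValueError(f"need >= 5 sequences to stratify, got {len(seqs)}")
    lengths = np.array([s.raw_length_codons for s in seqs], dtype=float)
    lo = float(np.percentile(lengths, low_p))
    hi = float(np.percentile(lengths, high_p))
    short = {s.gene_id for s in seqs if s.raw_length_codons < lo}
    long = {s.gene_id for s in seqs if s.raw_length_codons > hi}
    if not short and not long:
        warnings.warn("degenerate length distribution: both strata empty")
    return short, long
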