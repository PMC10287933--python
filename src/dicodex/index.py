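"""Geometric-mean expression index of a coding sequence.

The index of a sequence is the geometric mean of its tokens' contributions,

    index = ( prod_i C(token_i) ) ** (1 / L),

with L the number of retained tokens (codons or overlapping dicodons, after
discarding the first codon/dicodon and stop-containing tokens).  With plain
codon adaptiveness this is the classic CAI; dicodon contributions and
expression-weighted contributions generalize it.  Squaring the contributions
first is the power-2 variant; since (prod C^2)^(1/L) = ((prod C)^(1/L))^2 it
is a monotone transform of the plain index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .contributions import ContributionTable, _tokenize
from .genetic_code import GeneticCode, STANDARD_CODE
from .seq_io import CodingSequence

__all__ = ["IndexResult", "expression_index", "index_profile", "results_to_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndexResult:
    gene_id: str
    index: float
    L_used: int
    arity: int
    kind: str
    power: float


def expression_index(
    seq: CodingSequence,
    contribs: ContributionTable,
    code: GeneticCode = STANDARD_CODE,
) -> IndexResult:
    """Geometric mean of the sequence's token contributions, in log domain.

    Dicodon contributions reach the 1e-12 floor, so naive products underflow
    for long sequences; the mean of logs is exact to rounding.  Tokens absent
    from the table receive the table's epsilon (and are logged).
    """
    tokens = _tokenize(seq, contribs.arity, code)
    if not tokens:
        raise ValueError(f"{seq.gene_id!r}: no tokens after tokenization")
    log_sum = 0.0
    n_missing = 0
    for tok in tokens:
        v = contribs.values.get(tok)
        if v is None:
            v = contribs.epsilon
            n_missing += 1
        log_sum += math.log(v)
    if n_missing:
        logger.debug("%s: %d tokens absent from contribution table", seq.gene_id, n_missing)
    value = math.exp(log_sum / len(tokens))
    return IndexResult(
        gene_id=seq.gene_id,
        index=value,
        L_used=len(tokens),
        arity=contribs.arity,
        kind=contribs.kind,
        power=contribs.power,
    )


def index_profile(
    seqs: Sequence[CodingSequence],
    contribs: ContributionTable,
    code: GeneticCode = STANDARD_CODE,
) -> dict[str, IndexResult]:
    """One :class:`IndexResult` per gene, in input order; failures are skipped."""
    if not seqs:
        raise ValueError("empty sequence list")
    out: dict[str, IndexResult] = {}
    for seq in seqs:
        try:
            out[seq.gene_id] = expression_index(seq, contribs, code)
        except ValueError as exc:
            logger.warning("skipping %s: %s", seq.gene_id, exc)
    return out


def results_to_frame(results: dict[str, IndexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "index": r.index,
                "L_used": r.L_used,
                "arity": r.arity,
                "kind": r.kind,
                "power": r.power,
            }
            for r in results.values()
        ]
    )
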