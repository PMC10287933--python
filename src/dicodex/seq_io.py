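"""CDS FASTA input, quality control, and codon/dicodon tokenization.

QC keeps coding sequences longer than 50 sense codons, in frame, and free of
ambiguity characters.  Tokenization discards the first codon and the first
dicodon of every sequence, as well as stop codons and any dicodon containing
a stop codon; dicodons are the overlapping pairs of adjacent codons, written
as 6-mers.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

from .genetic_code import GeneticCode, STANDARD_CODE

__all__ = [
    "RawRecord",
    "CodingSequence",
    "QCReport",
    "read_cds_fasta",
    "qc_filter",
    "tokenize_codons",
    "tokenize_dicodons",
]

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class RawRecord:
    gene_id: str
    sequence: str


@dataclass(frozen=True)
class CodingSequence:
    """A QC'd coding sequence as an ordered list of codons.

    ``codons`` holds every codon triplet except a trailing stop; internal
    stop codons (rare annotation artefacts) are retained here and excluded
    at tokenization.  ``raw_length_codons`` is the number of sense codons.
    """

    gene_id: str
    codons: tuple[str, ...]
    raw_length_codons: int


@dataclass
class QCReport:
    """Per-record exclusion log produced by :func:`qc_filter`."""

    n_input: int = 0
    n_retained: int = 0
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)  # id, reason, detail

    def add(self, gene_id: str, reason: str, detail: str = "") -> None:
        self.exclusions.append((gene_id, reason, detail))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason, _ in self.exclusions:
            out[reason] = out.get(reason, 0) + 1
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\treason\tdetail\n")
            for gene_id, reason, detail in self.exclusions:
                fh.write(f"{gene_id}\t{reason}\t{detail}\n")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_cds_fasta(
    path: str | Path,
    id_regex: str | None = None,
    strict: bool = False,
) -> list[RawRecord]:
    """Read a (possibly gzipped) CDS FASTA file into raw records.

    The gene ID is the first whitespace-delimited token of the header; when
    ``id_regex`` is given, its first capture group applied to the full header
    wins instead (useful for Ensembl-style ``gene:XYZ`` annotations).
    """
    pattern = re.compile(id_regex) if id_regex else None
    records: list[RawRecord] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            gene_id = rec.id
            if pattern is not None:
                m = pattern.search(rec.description)
                if m:
                    gene_id = m.group(1)
            records.append(RawRecord(gene_id=gene_id, sequence=str(rec.seq)))
    if strict and not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def qc_filter(
    records: Iterable[RawRecord],
    min_codons: int = 50,
    code: GeneticCode = STANDARD_CODE,
    isoform_policy: Literal["longest", "first", "error"] = "longest",
    report: QCReport | None = None,
) -> list[CodingSequence]:
    """Apply QC to raw records and return :class:`CodingSequence` objects.

    Rules, in order: sequence length must be a multiple of 3; only ACGT
    characters are allowed (after uppercasing); a trailing stop codon is
    removed; the number of sense codons must be strictly greater than
    ``min_codons``.  Internal stop codons do not reject a record — the
    affected tokens are dropped later, at tokenization.  Duplicate gene IDs
    are resolved by ``isoform_policy`` (keep longest, keep first, or raise).
    All exclusions are logged into ``report`` when given.
    """
    if report is None:
        report = QCReport()
    kept: dict[str, CodingSequence] = {}
    order: list[str] = []
    for rec in records:
        report.n_input += 1
        seq = rec.sequence.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            report.add(rec.gene_id, "not_multiple_of_3", f"length={len(seq)}")
            continue
        if not _ACGT.issuperset(seq):
            bad = sorted(set(seq) - _ACGT)
            report.add(rec.gene_id, "non_acgt", "".join(bad))
            continue
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        if codons and code.is_stop(codons[-1]):
            codons = codons[:-1]
        n_sense = sum(1 for c in codons if not code.is_stop(c))
        if n_sense <= min_codons:
            report.add(rec.gene_id, "too_short", f"sense_codons={n_sense}")
            continue
        n_internal_stops = len(codons) - n_sense
        if n_internal_stops:
            logger.debug(
                "%s: %d internal stop codon(s) retained for token-level exclusion",
                rec.gene_id,
                n_internal_stops,
            )
        cds = CodingSequence(
            gene_id=rec.gene_id, codons=codons, raw_length_codons=n_sense
        )
        if rec.gene_id in kept:
            if isoform_policy == "error":
                raise ValueError(f"duplicate gene ID {rec.gene_id!r}")
            if isoform_policy == "longest" and n_sense > kept[rec.gene_id].raw_length_codons:
                report.add(kept[rec.gene_id].gene_id, "shorter_isoform", "")
                kept[rec.gene_id] = cds
            else:
                report.add(rec.gene_id, "duplicate_id", f"policy={isoform_policy}")
            continue
        kept[rec.gene_id] = cds
        order.append(rec.gene_id)
    out = [kept[g] for g in order]
    report.n_retained = len(out)
    return out


def tokenize_codons(
    seq: CodingSequence, code: GeneticCode = STANDARD_CODE
) -> list[str]:
    """Codon tokens of a CDS: positions 2..L, stop codons excluded.

    For a clean CDS of L sense codons this yields L-1 tokens.
    """
    return [c for c in seq.codons[1:] if not code.is_stop(c)]


def tokenize_dicodons(
    seq: CodingSequence,
    code: GeneticCode = STANDARD_CODE,
    overlapping: bool = True,
) -> list[str]:
    """Dicodon tokens of a CDS.

    Dicodons are overlapping adjacent codon pairs (codon i with codon i+1).
    The first dicodon (positions 1-2) is discarded, as is any pair containing
    a stop codon.  For a clean CDS of L sense codons this yields L-2 tokens.
    With ``overlapping=False`` the sequence is instead cut into disjoint
    pairs (positions 2-3, 4-5, ...), for sensitivity analysis.
    """
    codons = seq.codons
    out: list[str] = []
    if overlapping:
        pairs = ((codons[i], codons[i + 1]) for i in range(1, len(codons) - 1))
    else:
        pairs = (
            (codons[i], codons[i + 1]) for i in range(1, len(codons) - 1, 2)
        )
    for a, b in pairs:
        if code.is_stop(a) or code.is_stop(b):
            continue
        out.append(a + b)
    return out
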