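"""Standard genetic code and the synonymy structure over codons and dicodons.

Synonymy is the equivalence that underlies relative adaptiveness: two codons
are synonymous when they encode the same amino acid; two dicodons (adjacent
codon pairs, written as 6-mers) are synonymous when they encode the same
ordered dipeptide.  Stop codons and stop-containing dicodons are excluded
throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "InvalidTokenError",
    "STANDARD_CODE",
    "standard_code",
]

_ACGT = frozenset("ACGT")


class InvalidTokenError(ValueError):
    """Raised for tokens that are not sense codons/dicodons.

    ``reason`` is one of ``"length"``, ``"alphabet"``, ``"stop"``.
    """

    def __init__(self, token: str, reason: str, message: str):
        super().__init__(message)
        self.token = token
        self.reason = reason


@dataclass(frozen=True, eq=False)  # identity-hashed so per-instance caches work
class GeneticCode:
    """A codon -> amino-acid map defining synonymy for codons and dicodons.

    Parameters
    ----------
    codon_to_aa
        Map from each of the 64 uppercase DNA triplets to a one-letter amino
        acid, or ``"*"`` for a stop codon.
    """

    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...] = field(init=False)
    stop_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"expected 64 codons, got {len(self.codon_to_aa)}")
        sense = tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != "*"))
        stops = tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa == "*"))
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "stop_codons", stops)

    # -- membership -----------------------------------------------------

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"

    def is_sense_codon(self, codon: str) -> bool:
        aa = self.codon_to_aa.get(codon)
        return aa is not None and aa != "*"

    def is_sense_dicodon(self, dicodon: str) -> bool:
        return (
            len(dicodon) == 6
            and self.is_sense_codon(dicodon[:3])
            and self.is_sense_codon(dicodon[3:])
        )

    @property
    def sense_dicodons(self) -> tuple[str, ...]:
        """All 61*61 ordered sense codon pairs as 6-mers, sorted."""
        return self._sense_dicodons()

    @lru_cache(maxsize=1)
    def _sense_dicodons(self) -> tuple[str, ...]:
        return tuple(
            a + b for a, b in itertools.product(self.sense_codons, self.sense_codons)
        )

    def sense_tokens(self, arity: int) -> tuple[str, ...]:
        if arity == 1:
            return self.sense_codons
        if arity == 2:
            return self.sense_dicodons
        raise ValueError(f"arity must be 1 or 2, got {arity!r}")

    # -- synonymy --------------------------------------------------------

    def synonymy_class(self, token: str) -> str | tuple[str, str]:
        """Return the synonymy-class key of a codon or dicodon.

        For a codon this is its amino acid; for a dicodon the ordered pair
        of amino acids (the dipeptide).  Tokens of the wrong length, with
        non-ACGT characters, or containing a stop codon are rejected.
        """
        if len(token) not in (3, 6):
            raise InvalidTokenError(
                token, "length", f"token must be 3 or 6 nt, got {len(token)}: {token!r}"
            )
        if not _ACGT.issuperset(token):
            raise InvalidTokenError(
                token, "alphabet", f"token contains non-ACGT characters: {token!r}"
            )
        if len(token) == 3:
            if self.is_stop(token):
                raise InvalidTokenError(token, "stop", f"stop codon: {token!r}")
            return self.codon_to_aa[token]
        first, second = token[:3], token[3:]
        if self.is_stop(first) or self.is_stop(second):
            raise InvalidTokenError(
                token, "stop", f"dicodon contains a stop codon: {token!r}"
            )
        return (self.codon_to_aa[first], self.codon_to_aa[second])

    def synonyms(self, codon: str) -> tuple[str, ...]:
        """All sense codons encoding the same amino acid as ``codon``."""
        aa = self.synonymy_class(codon)
        return self.codons_for(aa)

    @lru_cache(maxsize=None)
    def codons_for(self, aa: str) -> tuple[str, ...]:
        """Sense codons encoding amino acid ``aa``, sorted."""
        out = tuple(c for c in self.sense_codons if self.codon_to_aa[c] == aa)
        if not out:
            raise KeyError(f"no sense codon encodes {aa!r}")
        return out

    def classes(self, arity: int) -> dict[object, tuple[str, ...]]:
        """Partition of the sense tokens of the given arity into synonymy classes."""
        out: dict[object, list[str]] = {}
        for tok in self.sense_tokens(arity):
            out.setdefault(self.synonymy_class(tok), []).append(tok)
        return {k: tuple(v) for k, v in out.items()}


def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (NCBI translation table 1)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return GeneticCode(codon_to_aa=mapping)


STANDARD_CODE = standard_code()
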