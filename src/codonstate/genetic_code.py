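"""Standard genetic code and its synonymous-family structure.

Every codon statistic in this package (RSCU, relative adaptiveness,
CAI) is defined over the families of synonymous codons of the standard
nuclear code (NCBI translation table 1). This module derives that
structure once from Biopython's codon table and exposes it as plain
dictionaries plus a small :class:`GeneticCode` facade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data import CodonTable

_BASES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only (61 entries)
AA_OF: dict[str, str] = dict(_STANDARD.forward_table)

#: the three stop codons of the standard code
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: all 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(AA_OF))

#: all 64 codons in lexicographic order
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)

#: amino acid -> lexicographically sorted tuple of its synonymous codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in AA_OF.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c, a in AA_OF.items() if a == aa)) for aa in FAMILIES
}

#: codon -> tuple of its synonyms (including itself)
FAMILY_OF: dict[str, tuple[str, ...]] = {
    codon: FAMILIES[aa] for codon, aa in AA_OF.items()
}

#: amino acids encoded by a single codon (Met, Trp); they carry no
#: synonymous choice and are excluded from CAI scoring
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, fam in FAMILIES.items() if len(fam) == 1
)


def is_valid_codon(codon: str) -> bool:
    """True for an unambiguous DNA triplet (sense or stop)."""
    return len(codon) == 3 and all(b in _BASES for b in codon)


def translate_codon(codon: str) -> str:
    """One-letter amino acid, ``*`` for stop, ``X`` for an ambiguous codon."""
    if codon in AA_OF:
        return AA_OF[codon]
    if codon in STOP_CODONS:
        return "*"
    return "X"


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code as a queryable object.

    Exists mainly so downstream code can pass the code around
    explicitly; all fields default to the standard table 1 structure.
    """

    aa_of: Mapping[str, str] = field(default_factory=lambda: dict(AA_OF))
    stop_codons: frozenset[str] = STOP_CODONS

    def __post_init__(self) -> None:
        n = len(self.aa_of) + len(self.stop_codons)
        if n != 64:
            raise ValueError(f"genetic code must cover 64 codons, got {n}")

    def family(self, codon: str) -> tuple[str, ...]:
        return FAMILY_OF[codon]

    def translate(self, codon: str) -> str:
        return translate_codon(codon)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


STANDARD_CODE = GeneticCode()
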