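"""Deterministic codon optimization by synonymous argmax recoding.

Every sense codon is replaced by the synonym with the highest relative
adaptiveness in the supplied weight table (ties broken by higher
reference count, then lexicographic codon order), so the optimized
sequence has CAI exactly 1 by construction. Stop codons and
N-containing codons are left untouched. The protein sequence is
conserved by construction and re-verified on every call.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cai import WeightTable, cai_score
from .errors import ValidationError
from .genetic_code import AA_OF, FAMILIES, translate_codon
from .sequence_io import CdsRecord, validate_cds


@dataclass(frozen=True)
class OptimizationResult:
    original_id: str
    optimized_sequence: str
    cai_before: float
    cai_after: float
    n_changed: int

    @property
    def optimized_record(self) -> CdsRecord:
        return CdsRecord(
            transcript_id=f"{self.original_id}_opt",
            gene_symbol="",
            sequence=self.optimized_sequence,
        )


def argmax_codon_table(weights: WeightTable) -> dict[str, str]:
    """Amino acid -> preferred codon under the weight table.

    Preference: maximal w, then maximal reference count, then
    lexicographically smallest codon.
    """
    table: dict[str, str] = {}
    for aa, family in FAMILIES.items():
        table[aa] = sorted(
            family,
            key=lambda c: (-weights[c], -weights.reference_counts.get(c, 0), c),
        )[0]
    return table


def optimize(cds: CdsRecord, weights: WeightTable) -> OptimizationResult:
    """Synonymously recode a CDS to the per-family argmax codons."""
    reason = validate_cds(cds)
    if reason is not None:
        raise ValidationError(f"{cds.transcript_id}: {reason}")
    best = argmax_codon_table(weights)
    out: list[str] = []
    n_changed = 0
    for codon in cds.codons():
        if codon in AA_OF:
            new = best[AA_OF[codon]]
            if new != codon:
                n_changed += 1
            out.append(new)
        else:
            # stop codon or N-containing codon: preserved verbatim
            out.append(codon)
    optimized = "".join(out)
    ok, pos = verify_synonymous(cds, CdsRecord(cds.transcript_id, "", optimized))
    if not ok:  # pragma: no cover - argmax recoding cannot change the protein
        raise AssertionError(f"optimization altered the protein at codon {pos}")
    return OptimizationResult(
        original_id=cds.transcript_id,
        optimized_sequence=optimized,
        cai_before=cai_score(cds, weights).cai,
        cai_after=cai_score(optimized, weights).cai,
        n_changed=n_changed,
    )


def verify_synonymous(a: CdsRecord, b: CdsRecord) -> tuple[bool, int | None]:
    """Codon-wise translation identity, stop included.

    Returns (True, None) if the two sequences encode the same protein,
    else (False, index of the first mismatching codon).
    """
    if a.n_codons != b.n_codons or len(a.sequence) != len(b.sequence):
        raise ValidationError(
            f"length mismatch: {a.n_codons} vs {b.n_codons} codons"
        )
    for i, (ca, cb) in enumerate(zip(a.codons(), b.codons())):
        if translate_codon(ca) != translate_codon(cb):
            return False, i
    return True, None
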