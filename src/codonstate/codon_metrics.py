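"""Codon counting, RSCU, per-thousand frequencies and rarity classes.

Counts are taken over frame-0, non-overlapping triplets. Codons
containing N are skipped (ambiguous base calls carry no synonymous
information); stop codons are counted in the raw tally but flagged and
excluded from RSCU and downstream adaptiveness statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .genetic_code import (
    AA_OF,
    FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
    is_valid_codon,
    translate_codon,
)
from .sequence_io import CdsRecord


@dataclass(frozen=True)
class CodonCounts:
    """Per-gene or pooled codon counts.

    ``n_codons`` is the total of all counted codons, stop codons
    included; ``n_stop`` flags how many of them are stops.
    """

    label: str
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for codon, n in self.counts.items():
            if not is_valid_codon(codon):
                raise ValidationError(f"invalid codon key {codon!r}")
            if n < 0:
                raise ValidationError(f"negative count for {codon}")

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def n_stop(self) -> int:
        return sum(n for c, n in self.counts.items() if c in STOP_CODONS)

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def count_codons(cds: CdsRecord | str, label: str | None = None) -> CodonCounts:
    """Tally frame-0 codons of a CDS; triplets containing N are skipped."""
    if isinstance(cds, CdsRecord):
        seq, lab = cds.sequence, cds.transcript_id
    else:
        seq, lab = cds, label or "sequence"
    if len(seq) % 3 != 0:
        raise ValidationError(f"{lab}: length {len(seq)} not divisible by 3")
    counts: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(label if label is not None else lab, counts)


def pool_counts(tables: Sequence[CodonCounts], label: str | None = None) -> CodonCounts:
    """Element-wise sum of several count tables."""
    if not tables:
        raise ValidationError("pool_counts requires a non-empty list")
    pooled: dict[str, int] = {}
    for t in tables:
        for codon, n in t.counts.items():
            pooled[codon] = pooled.get(codon, 0) + n
    lab = label if label is not None else f"pooled({len(tables)} tables)"
    return CodonCounts(lab, pooled)


def rscu(counts: CodonCounts) -> dict[str, float]:
    """Relative synonymous codon usage per sense codon.

    RSCU of codon j in a synonymous family of size n is its count
    divided by the family mean count; families with zero total are
    reported as NaN (undefined). Single-codon families are always 1
    when observed.
    """
    out: dict[str, float] = {}
    for aa, family in FAMILIES.items():
        total = sum(counts.get(c) for c in family)
        if total == 0:
            for c in family:
                out[c] = math.nan
            continue
        expected = total / len(family)
        for c in family:
            out[c] = counts.get(c) / expected
    return out


def per_thousand(counts: CodonCounts) -> dict[str, float]:
    """Codon frequency per 1,000 counted codons (stops included)."""
    n = counts.n_codons
    if n == 0:
        raise ValidationError("per_thousand undefined for empty counts")
    return {codon: 1000.0 * counts.get(codon) / n for codon in sorted(counts.counts)}


@dataclass(frozen=True)
class RarityClasses:
    """Codon rarity classification derived from a weight table.

    ``common`` / ``rare`` / ``extremely_rare`` by relative adaptiveness
    w: extremely rare below ``extreme_w``, rare below ``rare_w``.
    Single-codon families (Met, Trp) are always common — with no
    synonymous alternative a codon cannot be under-preferred.
    """

    classes: Mapping[str, str]
    rare_w: float
    extreme_w: float

    def count_by_class(self) -> dict[str, int]:
        out = {"common": 0, "rare": 0, "extremely_rare": 0}
        for cls in self.classes.values():
            out[cls] += 1
        return out


def classify_rarity(
    weights: "Mapping[str, float] | object",
    rare_w: float = 0.3,
    extreme_w: float = 0.1,
) -> RarityClasses:
    """Classify every sense codon by its relative adaptiveness.

    ``weights`` is a codon->w mapping or an object with a ``weights``
    attribute (a weight table).
    """
    if not 0 < extreme_w < rare_w <= 1:
        raise ValidationError(
            f"thresholds must satisfy 0 < extreme_w < rare_w <= 1, "
            f"got extreme_w={extreme_w}, rare_w={rare_w}"
        )
    w = getattr(weights, "weights", weights)
    classes: dict[str, str] = {}
    for codon in SENSE_CODONS:
        if len(FAMILIES[AA_OF[codon]]) == 1:
            classes[codon] = "common"
        elif w[codon] < extreme_w:
            classes[codon] = "extremely_rare"
        elif w[codon] < rare_w:
            classes[codon] = "rare"
        else:
            classes[codon] = "common"
    return RarityClasses(classes, rare_w=rare_w, extreme_w=extreme_w)


def usage_table(
    counts: CodonCounts,
    weights: "Mapping[str, float] | None" = None,
    rarity: RarityClasses | None = None,
) -> pd.DataFrame:
    """Tabular codon-usage report (one row per observed or sense codon)."""
    rscu_map = rscu(counts)
    pt = {c: 1000.0 * counts.get(c) / counts.n_codons for c in SENSE_CODONS}
    rows = []
    for codon in SENSE_CODONS:
        row = {
            "codon": codon,
            "amino_acid": translate_codon(codon),
            "count": counts.get(codon),
            "rscu": rscu_map[codon],
            "per_thousand": pt[codon],
        }
        if weights is not None:
            w = getattr(weights, "weights", weights)
            row["weight"] = w[codon]
        if rarity is not None:
            row["class"] = rarity.classes[codon]
        rows.append(row)
    return pd.DataFrame(rows)


def write_usage_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def iter_sense_counts(counts: CodonCounts) -> Iterable[tuple[str, int]]:
    for codon in SENSE_CODONS:
        yield codon, counts.get(codon)
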