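"""Codon adaptation index: weight tables, scoring, distributions, ranking.

The relative adaptiveness of codon j for amino acid i is

    w_ij = x_ij / max_j x_ij

where x_ij are codon counts pooled over a reference gene set, so the
most-used codon of every synonymous family has w = 1. The CAI of a
gene is the geometric mean of w over its scored codons. Stop codons
and the single-codon families ATG (Met) and TGG (Trp) are excluded
from scoring: they offer no synonymous choice, and under w = 1 they
would only dilute n_scored. A pseudocount (default 0.5) is added to
every reference count so no weight is exactly zero.

A gene of interest is ranked against the CAI distribution of a gene
set by midrank percentile; "uses more rare codons than X% of genes"
is reported as 100 minus that percentile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_metrics import CodonCounts
from .errors import ValidationError
from .genetic_code import (
    AA_OF,
    FAMILIES,
    SENSE_CODONS,
    SINGLE_CODON_AAS,
    translate_codon,
)
from .sequence_io import CdsRecord

logger = logging.getLogger(__name__)

#: codons never entering the geometric mean: Met, Trp (single-codon families)
NON_SCORED_SENSE = frozenset(
    codon for codon, aa in AA_OF.items() if aa in SINGLE_CODON_AAS
)


@dataclass(frozen=True)
class WeightTable:
    """Per-codon relative adaptiveness against a reference set."""

    weights: Mapping[str, float]
    reference_counts: Mapping[str, int] = field(default_factory=dict)
    pseudocount: float = 0.0
    reference: str = ""

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.weights)
        if missing:
            raise ValidationError(f"weight table missing codons {sorted(missing)[:5]}")
        for codon, w in self.weights.items():
            if not 0 < w <= 1:
                raise ValidationError(f"weight for {codon} out of (0, 1]: {w}")
        for fam in FAMILIES.values():
            if not math.isclose(max(self.weights[c] for c in fam), 1.0):
                raise ValidationError(f"family {fam} has no codon with w = 1")

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": translate_codon(c),
                "reference_count": self.reference_counts.get(c, 0),
                "w": self.weights[c],
            }
            for c in SENSE_CODONS
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, reference: str = "") -> "WeightTable":
        df = pd.read_csv(path)
        return cls(
            weights=dict(zip(df["codon"], df["w"])),
            reference_counts=dict(zip(df["codon"], df["reference_count"])),
            reference=reference or str(path),
        )


def reference_weights(
    pooled: CodonCounts, pseudocount: float = 0.5, reference: str | None = None
) -> WeightTable:
    """Relative adaptiveness from pooled reference codon counts.

    w = (count + pseudocount) / max over the synonymous family of
    (count + pseudocount); the family maximum maps to exactly 1.
    With ``pseudocount`` 0, a family with zero total has undefined
    weights and raises.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pooled.n_codons == 0:
        raise ValidationError("reference counts are empty")
    weights: dict[str, float] = {}
    for aa, family in FAMILIES.items():
        adjusted = {c: pooled.get(c) + pseudocount for c in family}
        top = max(adjusted.values())
        if top == 0:
            raise ValidationError(
                f"family {aa} has zero counts and zero pseudocount: weights undefined"
            )
        for c in family:
            weights[c] = adjusted[c] / top
    return WeightTable(
        weights=weights,
        reference_counts={c: pooled.get(c) for c in SENSE_CODONS},
        pseudocount=pseudocount,
        reference=reference if reference is not None else pooled.label,
    )


@dataclass(frozen=True)
class CaiResult:
    transcript_id: str
    cai: float
    n_scored: int


def scored_codons(cds: CdsRecord | str) -> list[str]:
    """Codons of a CDS that enter CAI: sense, synonymous-family, no N."""
    seq = cds.sequence if isinstance(cds, CdsRecord) else cds
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in AA_OF and codon not in NON_SCORED_SENSE:
            out.append(codon)
    return out


def cai_score(cds: CdsRecord | str, weights: WeightTable) -> CaiResult:
    """Geometric-mean CAI of one coding sequence.

    Computed as exp(mean of ln w) over the scored codons, which is
    numerically stable for long genes.
    """
    tid = cds.transcript_id if isinstance(cds, CdsRecord) else "sequence"
    codons = scored_codons(cds)
    if not codons:
        raise ValidationError(f"{tid}: no scorable codons")
    log_sum = sum(math.log(weights[c]) for c in codons)
    return CaiResult(tid, math.exp(log_sum / len(codons)), len(codons))


@dataclass(frozen=True)
class CaiDistribution:
    """CAI scores of a gene set with summary and rank queries."""

    label: str
    results: tuple[CaiResult, ...]

    def __post_init__(self) -> None:
        if not self.results:
            raise ValidationError("empty CAI distribution")

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.cai for r in self.results])

    def summary(self) -> dict[str, float]:
        s = self.scores
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        return {
            "n": int(s.size),
            "min": float(s.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(s.max()),
        }


def cai_distribution(
    genes: Sequence[CdsRecord], weights: WeightTable, label: str = "gene set"
) -> CaiDistribution:
    """Score every gene; genes that cannot be scored are logged and skipped."""
    if not genes:
        raise ValidationError("cai_distribution requires a non-empty gene list")
    results = []
    for g in genes:
        try:
            results.append(cai_score(g, weights))
        except ValidationError as exc:
            logger.info("skipping %s: %s", g.transcript_id, exc)
    if not results:
        raise ValidationError("no gene could be scored")
    return CaiDistribution(label, tuple(results))


def percentile_rank(dist: CaiDistribution | np.ndarray, score: float) -> float:
    """Midrank percentile of ``score`` within a distribution, in [0, 100].

    percentile = 100 * (count below + 0.5 * count equal) / N. The share
    of genes scoring strictly higher is 100 minus this value in the
    absence of ties and converges to it with ties split evenly.
    """
    scores = dist.scores if isinstance(dist, CaiDistribution) else np.asarray(dist)
    below = int(np.sum(scores < score))
    equal = int(np.sum(scores == score))
    return 100.0 * (below + 0.5 * equal) / scores.size


def rare_codon_profile(
    cds: CdsRecord | str,
    weights: WeightTable,
    window: int = 30,
    rare_w: float = 0.3,
    extreme_w: float = 0.1,
) -> pd.DataFrame:
    """Sliding-window rarity profile along the scored codons of a CDS.

    Non-overlapping windows of ``window`` scored codons; per window the
    geometric-mean w (so a single full-length window reproduces the
    gene's CAI), the count of rare codons (w < rare_w) and of extremely
    rare codons (w < extreme_w). Extremely rare codons are included in
    the rare count's threshold logic separately: ``n_rare`` counts
    codons with extreme_w <= w < rare_w, ``n_extreme`` those below
    extreme_w.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    codons = scored_codons(cds)
    if not codons:
        raise ValidationError("no scorable codons")
    rows = []
    for start in range(0, len(codons), window):
        chunk = codons[start : start + window]
        ws = [weights[c] for c in chunk]
        log_mean = sum(math.log(w) for w in ws) / len(ws)
        rows.append(
            {
                "window": start // window,
                "start_codon": start,
                "n_codons": len(chunk),
                "mean_w": math.exp(log_mean),
                "n_rare": sum(1 for w in ws if extreme_w <= w < rare_w),
                "n_extreme": sum(1 for w in ws if w < extreme_w),
            }
        )
    return pd.DataFrame(rows)


def gene_level_cai(
    records: Sequence[CdsRecord], weights: WeightTable
) -> pd.DataFrame:
    """Per-gene CAI: score each transcript, take the median per symbol.

    Transcripts without a gene symbol are kept as their own 'gene'
    under their transcript id.
    """
    rows = []
    for rec in records:
        try:
            res = cai_score(rec, weights)
        except ValidationError as exc:
            logger.info("skipping %s: %s", rec.transcript_id, exc)
            continue
        rows.append(
            {
                "gene_symbol": rec.gene_symbol or rec.transcript_id,
                "transcript_id": rec.transcript_id,
                "cai": res.cai,
                "n_scored": res.n_scored,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no transcript could be scored")
    return (
        df.groupby("gene_symbol", sort=False)
        .agg(cai=("cai", "median"), n_transcripts=("transcript_id", "size"))
        .reset_index()
    )
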