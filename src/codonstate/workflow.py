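"""End-to-end reports: codon-usage ranking and translation-state shifts.

`run_codon_report` reproduces the transcriptome-wide codon analysis:
restrict to expressed transcripts, pool their codon counts into a
reference, derive relative-adaptiveness weights, score every gene's
CAI (median across isoforms per gene symbol), and rank a gene of
interest against the all-gene and keyword-subset (e.g. kinase)
distributions, plus a windowed rare-codon profile of that gene.

`run_translation_report` turns per-fraction ddPCR tables into the
polysome share P per gene and condition and labels the
between-condition shift; optionally it also summarizes A254 trace
region areas.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cai import (
    CaiDistribution,
    CaiResult,
    gene_level_cai,
    percentile_rank,
    rare_codon_profile,
    reference_weights,
)
from .codon_metrics import count_codons, pool_counts
from .errors import ValidationError
from .polysome import (
    MONO_FRACTIONS,
    POLY_FRACTIONS,
    PolysomeTrace,
    RegionBoundaries,
    baseline_correct,
    condition_shift,
    integrate_regions,
    normalize_fraction_counts,
    polysome_statistic,
)
from .sequence_io import (
    CdsRecord,
    filter_expressed,
    records_by_id,
    select_by_keyword,
    validate_expression_table,
)


def _summary(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
    }


def run_codon_report(
    records: Sequence[CdsRecord],
    expression: pd.DataFrame,
    gene_of_interest: str,
    min_expression: float = 0.0,
    keyword: str = "kinase",
    pseudocount: float = 0.5,
    rare_w: float = 0.3,
    extreme_w: float = 0.1,
    window: int = 30,
    expression_weighted: bool = False,
) -> dict:
    """Codon-adaptation report for one gene against a transcriptome.

    Raises :class:`ValidationError` (listing near-matches) when
    ``gene_of_interest`` is not an expressed gene symbol.
    """
    expression = validate_expression_table(expression)
    expressed = filter_expressed(expression, min_expression)
    by_id = records_by_id(records)
    expressed_ids = [t for t in expressed["transcript_id"] if t in by_id]
    if not expressed_ids:
        raise ValidationError("no expressed transcript has a CDS record")
    expressed_records = [by_id[t] for t in expressed_ids]

    per_transcript = [count_codons(r) for r in expressed_records]
    if expression_weighted:
        level = dict(zip(expressed["transcript_id"], expressed["expression"]))
        weighted: dict[str, float] = {}
        for rec, counts in zip(expressed_records, per_transcript):
            w = level[rec.transcript_id]
            for codon, n in counts.counts.items():
                weighted[codon] = weighted.get(codon, 0.0) + w * n
        from .codon_metrics import CodonCounts

        pooled = CodonCounts("expression-weighted pool", weighted)
    else:
        pooled = pool_counts(per_transcript, label="expressed-transcript pool")
    weights = reference_weights(pooled, pseudocount=pseudocount)

    gene_cai = gene_level_cai(expressed_records, weights)
    subset_symbols = set(select_by_keyword(expressed, keyword)["gene_symbol"])
    subset_cai = gene_cai[gene_cai["gene_symbol"].isin(subset_symbols)]

    match = gene_cai[gene_cai["gene_symbol"] == gene_of_interest]
    if match.empty:
        near = difflib.get_close_matches(
            gene_of_interest, list(gene_cai["gene_symbol"]), n=5
        )
        raise ValidationError(
            f"gene {gene_of_interest!r} not among expressed genes; "
            f"near matches: {near}"
        )
    goi_cai = float(match["cai"].iloc[0])

    all_scores = gene_cai["cai"].to_numpy()
    pct_all = percentile_rank(all_scores, goi_cai)
    report: dict = {
        "package_version": __version__,
        "parameters": {
            "gene_of_interest": gene_of_interest,
            "min_expression": min_expression,
            "keyword": keyword,
            "pseudocount": pseudocount,
            "rare_w": rare_w,
            "extreme_w": extreme_w,
            "window": window,
            "expression_weighted": expression_weighted,
        },
        "n_expressed_transcripts": len(expressed_records),
        "n_genes": int(gene_cai.shape[0]),
        "n_subset_genes": int(subset_cai.shape[0]),
        "gene": gene_of_interest,
        "cai_median": goi_cai,
        "percentile_all": pct_all,
        "pct_genes_higher": 100.0 - pct_all,
        "distribution_summaries": {"all_genes": _summary(all_scores)},
    }
    if not subset_cai.empty:
        sub_scores = subset_cai["cai"].to_numpy()
        pct_sub = percentile_rank(sub_scores, goi_cai)
        report["percentile_subset"] = pct_sub
        report["pct_subset_higher"] = 100.0 - pct_sub
        report["distribution_summaries"][f"{keyword}_subset"] = _summary(sub_scores)

    goi_transcripts = [
        r for r in expressed_records if r.gene_symbol == gene_of_interest
    ]
    profile = rare_codon_profile(
        goi_transcripts[0], weights, window=window, rare_w=rare_w, extreme_w=extreme_w
    )
    report["rare_codon_profile"] = profile.to_dict(orient="records")
    report["_weights"] = weights  # stripped before JSON serialization
    report["_gene_cai"] = gene_cai
    return report


def run_translation_report(
    counts: Mapping[str, Mapping[str, pd.DataFrame]],
    control: str = "control",
    mono_fractions: frozenset[int] = MONO_FRACTIONS,
    poly_fractions: frozenset[int] = POLY_FRACTIONS,
    tolerance: float = 0.01,
    traces: Mapping[str, PolysomeTrace] | None = None,
    regions: RegionBoundaries | None = None,
    baseline_method: str = "linear_endpoints",
) -> dict:
    """Polysome share per gene/condition and the shift vs control.

    ``counts`` maps gene -> condition -> fraction-count table. Each
    gene must include the ``control`` condition.
    """
    report: dict = {
        "package_version": __version__,
        "parameters": {
            "control": control,
            "mono_fractions": sorted(mono_fractions),
            "poly_fractions": sorted(poly_fractions),
            "tolerance": tolerance,
            "baseline_method": baseline_method,
        },
        "genes": {},
    }
    for gene, by_condition in counts.items():
        if control not in by_condition:
            raise ValidationError(f"gene {gene!r}: control condition missing")
        stats = {
            cond: polysome_statistic(
                normalize_fraction_counts(df), mono_fractions, poly_fractions
            )
            for cond, df in by_condition.items()
        }
        entry: dict = {
            "P": {cond: s.P for cond, s in stats.items()},
            "mono_sum": {cond: s.mono_sum for cond, s in stats.items()},
            "poly_sum": {cond: s.poly_sum for cond, s in stats.items()},
            "shifts": {},
        }
        for cond, s in stats.items():
            if cond == control:
                continue
            delta, label = condition_shift(stats[control], s, tolerance)
            entry["shifts"][cond] = {"delta": delta, "label": label}
        report["genes"][gene] = entry
    if traces:
        if regions is None:
            raise ValidationError("trace region boundaries required with traces")
        areas = {}
        for cond, trace in traces.items():
            corrected = baseline_correct(trace, method=baseline_method)
            areas[cond] = integrate_regions(corrected, regions)
        report["trace_region_areas"] = areas
    return report


# ---------------------------------------------------------------------------
# provenance helpers

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    parameters: Mapping,
    inputs: Sequence[str | Path],
) -> Path:
    """Machine-readable run manifest (no timestamps: reruns are
    byte-identical)."""
    manifest = {
        "command": command,
        "package_version": __version__,
        "parameters": dict(parameters),
        "inputs": {str(p): sha256_of(p) for p in inputs},
    }
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def serializable_report(report: dict) -> dict:
    """Strip non-JSON members (weight tables, frames) from a report."""
    return {k: v for k, v in report.items() if not k.startswith("_")}
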