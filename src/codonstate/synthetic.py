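"""Seeded synthetic data for every pipeline stage, with ground truth.

Generators emulate the statistical structure of the real inputs:

* a transcriptome with shared synonymous-codon preferences and per-gene
  Dirichlet variation around them, an optional planted gene emitting
  from *inverted* preferences (a rare-codon-limited gene analogous to
  the HRI kinase), a keyword-taggable kinase subset and log-normal
  expression levels;
* per-fraction ddPCR copy counts with Poisson counting noise and
  per-fraction rRNA loadings;
* A254 gradient traces as sums of Gaussian peaks on a linear baseline
  with i.i.d. Gaussian noise;
* pulse-chase decay series with multiplicative log-normal noise.

Every generator takes an explicit seed (no global RNG state) and
returns machine-readable ground truth alongside the data, so every
analysis stage has a recovery test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .codon_metrics import CodonCounts
from .errors import ValidationError
from .genetic_code import FAMILIES, SENSE_CODONS, STOP_CODONS
from .polysome import (
    DEFAULT_RRNA_DILUTION,
    MONO_FRACTIONS,
    POLY_FRACTIONS,
    PolysomeTrace,
    RegionBoundaries,
)
from .sequence_io import CdsRecord

# ---------------------------------------------------------------------------
# transcriptome

#: geometric decay of shared within-family codon preference; 0.45 gives a
#: realistic spread of relative adaptiveness (second-ranked codon w ~ 0.45)
PREFERENCE_RATIO = 0.45

_KINASE_DESCRIPTIONS = (
    "serine/threonine-protein kinase",
    "receptor tyrosine kinase",
    "mitogen-activated protein kinase",
    "calcium/calmodulin-dependent protein kinase",
)
_BACKGROUND_DESCRIPTIONS = (
    "solute carrier family membrane transporter",
    "zinc finger transcription factor",
    "ribosomal protein, large subunit",
    "actin cytoskeleton regulator",
    "ubiquitin ligase complex subunit",
    "synaptic vesicle glycoprotein",
)
_PLANTED_DESCRIPTION = (
    "eukaryotic translation initiation factor 2-alpha kinase "
    "(heme-regulated inhibitor)"
)

_SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_STOPS = tuple(sorted(STOP_CODONS))


@dataclass(frozen=True)
class TranscriptomeSpec:
    """Conditions for a synthetic expressed-transcript set.

    Defaults mirror an expressed hippocampal gene list scaled to desk
    size: 2,000 genes, ~4.5% tagged as kinases (the real list had 566
    kinases among 12,643 expressed transcripts), one planted
    inverted-preference gene standing in for the rare-codon-limited
    kinase, and log-normal expression.
    """

    seed: int
    n_genes: int = 2000
    length_range: tuple[int, int] = (120, 600)
    concentration: float = 100.0
    planted: tuple[tuple[str, bool], ...] = (("Eif2ak1", True),)
    kinase_fraction: float = 0.045
    expression_mu: float = 1.0
    expression_sigma: float = 1.2

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not 0 <= self.kinase_fraction <= 1:
            raise ValidationError("kinase_fraction must lie in [0, 1]")
        lo, hi = self.length_range
        if not 3 <= lo <= hi:
            raise ValidationError("length_range must satisfy 3 <= lo <= hi")
        if self.concentration <= 0:
            raise ValidationError("concentration must be > 0")


def shared_preferences(rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-family shared codon preferences (geometric, shuffled order)."""
    prefs: dict[str, np.ndarray] = {}
    for aa in sorted(FAMILIES):
        family = FAMILIES[aa]
        ranks = rng.permutation(len(family))
        p = PREFERENCE_RATIO ** ranks.astype(float)
        prefs[aa] = p / p.sum()
    return prefs


def _invert(p: np.ndarray) -> np.ndarray:
    inv = 1.0 / p
    return inv / inv.sum()


def _gene_codon_distribution(
    rng: np.random.Generator,
    prefs: Mapping[str, np.ndarray],
    concentration: float,
    inverted: bool,
) -> np.ndarray:
    """Distribution over the 61 sense codons for one gene.

    Amino acids are used uniformly; within each family the codon
    distribution is a Dirichlet draw around the shared preferences
    (inverted genes emit from the exact inverted preferences).
    """
    p = np.zeros(len(SENSE_CODONS))
    n_aa = len(FAMILIES)
    for aa in sorted(FAMILIES):
        family = FAMILIES[aa]
        base = prefs[aa]
        if inverted:
            fam_p = _invert(base)
        elif len(family) == 1:
            fam_p = base
        else:
            fam_p = rng.dirichlet(concentration * base)
        for codon, pc in zip(family, fam_p):
            p[_SENSE_INDEX[codon]] = pc / n_aa
    return p


def generate_transcriptome(
    spec: TranscriptomeSpec,
) -> tuple[list[CdsRecord], pd.DataFrame, dict]:
    """Synthesize CDS records, an expression table and ground truth.

    Every sequence starts with ATG and ends with a stop codon; the body
    is drawn i.i.d. from the gene's codon distribution. The ground
    truth records each gene's construction class, its exact emission
    tally (equal to its codon counts), the kinase-tagged ids and the
    pooled global tally.
    """
    rng = np.random.default_rng(spec.seed)
    prefs = shared_preferences(rng)
    planted_names = [name for name, _ in spec.planted]
    if len(planted_names) > spec.n_genes:
        raise ValidationError("more planted genes than genes")

    n_background = spec.n_genes - len(planted_names)
    n_kinase = round(spec.kinase_fraction * spec.n_genes)
    n_kinase = min(n_kinase, n_background)
    kinase_rows = set(rng.choice(n_background, size=n_kinase, replace=False).tolist())

    lengths = rng.integers(
        spec.length_range[0], spec.length_range[1] + 1, size=spec.n_genes
    )
    stop_pref = np.array([0.5, 0.25, 0.25])  # TAA favored, as in mammals

    records: list[CdsRecord] = []
    rows = []
    gene_truth: dict[str, dict] = {}
    global_tally = np.zeros(len(SENSE_CODONS), dtype=int)
    global_stops = {s: 0 for s in _STOPS}
    expression = rng.lognormal(spec.expression_mu, spec.expression_sigma, spec.n_genes)

    planted_iter = iter(spec.planted)
    background_i = 0
    for g in range(spec.n_genes):
        if g < len(planted_names):
            symbol, inverted = next(planted_iter)
            desc = _PLANTED_DESCRIPTION
            cls = "inverted" if inverted else "planted"
            is_kinase = True
        else:
            symbol = f"Gene{background_i:04d}"
            is_kinase = background_i in kinase_rows
            desc = (
                _KINASE_DESCRIPTIONS[background_i % len(_KINASE_DESCRIPTIONS)]
                if is_kinase
                else _BACKGROUND_DESCRIPTIONS[
                    background_i % len(_BACKGROUND_DESCRIPTIONS)
                ]
            )
            cls = "background"
            background_i += 1
        inverted_flag = cls == "inverted"
        p = _gene_codon_distribution(rng, prefs, spec.concentration, inverted_flag)
        n_body = int(lengths[g]) - 2
        body_idx = rng.choice(len(SENSE_CODONS), size=n_body, p=p)
        stop = _STOPS[rng.choice(3, p=stop_pref)]
        seq = "ATG" + "".join(SENSE_CODONS[i] for i in body_idx) + stop

        tally = np.bincount(body_idx, minlength=len(SENSE_CODONS))
        tally[_SENSE_INDEX["ATG"]] += 1
        global_tally += tally
        global_stops[stop] += 1

        tid = f"SYNT{g:05d}.1"
        records.append(CdsRecord(tid, symbol, seq))
        rows.append(
            {
                "transcript_id": tid,
                "gene_symbol": symbol,
                "description": desc,
                "expression": float(expression[g]),
            }
        )
        tally_map = {
            SENSE_CODONS[i]: int(tally[i]) for i in np.nonzero(tally)[0]
        }
        tally_map[stop] = 1
        gene_truth[tid] = {
            "gene_symbol": symbol,
            "class": cls,
            "kinase": is_kinase,
            "n_codons": int(lengths[g]),
            "tally": tally_map,
        }

    table = pd.DataFrame(rows)
    pooled = {
        SENSE_CODONS[i]: int(global_tally[i]) for i in np.nonzero(global_tally)[0]
    }
    pooled.update({s: n for s, n in global_stops.items() if n})
    truth = {
        "spec": {
            "seed": spec.seed,
            "n_genes": spec.n_genes,
            "length_range": list(spec.length_range),
            "concentration": spec.concentration,
            "kinase_fraction": spec.kinase_fraction,
        },
        "planted": {name: flag for name, flag in spec.planted},
        "kinase_ids": [t for t, g in gene_truth.items() if g["kinase"]],
        "genes": gene_truth,
        "global_tally": pooled,
        "shared_preferences": {
            aa: {c: float(p) for c, p in zip(FAMILIES[aa], prefs[aa])}
            for aa in FAMILIES
        },
    }
    return records, table, truth


def global_counts_from_truth(truth: dict, label: str = "synthetic pool") -> CodonCounts:
    return CodonCounts(label, dict(truth["global_tally"]))


# ---------------------------------------------------------------------------
# ddPCR fraction counts

DEFAULT_RRNA_LOADINGS = tuple([2000.0] * 11)


def generate_fraction_counts(
    true_P: float,
    total_target_copies: float = 10_000.0,
    rrna_per_fraction: Sequence[float] = DEFAULT_RRNA_LOADINGS,
    rrna_dilution: float = DEFAULT_RRNA_DILUTION,
    seed: int = 0,
    noise: bool = True,
    mono_fractions: frozenset[int] = MONO_FRACTIONS,
    poly_fractions: frozenset[int] = POLY_FRACTIONS,
) -> tuple[pd.DataFrame, dict]:
    """Per-fraction target and rRNA ddPCR counts for one condition.

    Expected target copies split (1 - true_P) : true_P between the
    monosome and polysome fraction sets, equally within each set;
    fractions outside the two sets (free subunits, disome) carry no
    target signal. With ``noise`` both target and rRNA counts are
    Poisson-sampled; without, the exact expectations are returned, so
    the polysome statistic recovers ``true_P`` exactly.
    """
    if not 0 < true_P < 1:
        raise ValidationError("true_P must lie in (0, 1)")
    n_fractions = len(rrna_per_fraction)
    needed = max(mono_fractions | poly_fractions)
    if n_fractions < needed:
        raise ValidationError(
            f"{n_fractions} rRNA loadings but fraction sets reach {needed}"
        )
    rng = np.random.default_rng(seed)
    expected = np.zeros(n_fractions)
    for f in mono_fractions:
        expected[f - 1] = (1 - true_P) * total_target_copies / len(mono_fractions)
    for f in poly_fractions:
        expected[f - 1] = true_P * total_target_copies / len(poly_fractions)
    loadings = np.asarray(rrna_per_fraction, dtype=float)
    if noise:
        target = rng.poisson(expected).astype(float)
        rrna = rng.poisson(loadings).astype(float)
    else:
        target = expected.copy()
        rrna = loadings.copy()
    df = pd.DataFrame(
        {
            "fraction": np.arange(1, n_fractions + 1),
            "target_copies": target,
            "rrna_copies": rrna,
            "rrna_dilution": rrna_dilution,
        }
    )
    truth = {
        "true_P": true_P,
        "total_target_copies": total_target_copies,
        "expected_target": expected.tolist(),
        "rrna_loadings": loadings.tolist(),
        "analytic_se": polysome_estimator_se(
            true_P,
            total_target_copies,
            rrna_per_fraction,
            mono_fractions=mono_fractions,
            poly_fractions=poly_fractions,
        ),
    }
    return df, truth


def polysome_estimator_se(
    true_P: float,
    total_target_copies: float,
    rrna_per_fraction: Sequence[float] = DEFAULT_RRNA_LOADINGS,
    mono_fractions: frozenset[int] = MONO_FRACTIONS,
    poly_fractions: frozenset[int] = POLY_FRACTIONS,
) -> float:
    """Delta-method standard error of the estimated polysome share.

    Treats per-fraction target and rRNA counts as independent Poisson;
    for X = T / R, Var(X) ~ lambda / r^2 + lambda^2 / r^3 (the rRNA
    dilution factor cancels out of P). Then
    Var(P) ~ (mu_p^2 V_m + mu_m^2 V_p) / (mu_m + mu_p)^4.
    """
    loadings = np.asarray(rrna_per_fraction, dtype=float)

    def moments(fractions: frozenset[int], share: float) -> tuple[float, float]:
        mu = 0.0
        var = 0.0
        for f in fractions:
            lam = share * total_target_copies / len(fractions)
            r = loadings[f - 1]
            mu += lam / r
            var += lam / r**2 + lam**2 / r**3
        return mu, var

    mu_m, v_m = moments(mono_fractions, 1 - true_P)
    mu_p, v_p = moments(poly_fractions, true_P)
    var_P = (mu_p**2 * v_m + mu_m**2 * v_p) / (mu_m + mu_p) ** 4
    return math.sqrt(var_P)


# ---------------------------------------------------------------------------
# A254 traces

DEFAULT_PEAKS: tuple[tuple[str, float, float, float], ...] = (
    ("40S", 10.0, 0.35, 1.2),
    ("60S", 15.0, 0.5, 1.3),
    ("monosome", 23.0, 1.0, 2.2),
    ("disome", 32.0, 0.75, 2.2),
    ("polysome", 52.0, 0.9, 5.0),
)

DEFAULT_REGIONS = RegionBoundaries(
    {"monosome": (16.0, 27.5), "disome": (27.5, 39.0), "polysome": (39.0, 75.0)}
)


@dataclass(frozen=True)
class TraceSpec:
    """Recipe for a synthetic A254 gradient trace."""

    seed: int = 0
    peaks: tuple[tuple[str, float, float, float], ...] = DEFAULT_PEAKS
    baseline_slope: float = 0.002
    baseline_intercept: float = 0.05
    noise_sd: float = 0.0
    t_start: float = 0.0
    t_end: float = 80.0
    dt: float = 0.05
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        positions = [p for _, p, _, _ in self.peaks]
        if positions != sorted(positions):
            raise ValidationError("peak positions must be ordered")
        if self.dt <= 0 or self.t_end <= self.t_start:
            raise ValidationError("invalid sampling grid")


def pi_trace_spec(base: TraceSpec, mono_gain: float = 1.8, poly_gain: float = 0.45,
                  seed: int | None = None) -> TraceSpec:
    """A proteasome-inhibition variant of a trace spec.

    Global translation shuts down: the monosome peak grows and the
    polysome mass shrinks.
    """
    peaks = tuple(
        (
            name,
            pos,
            amp * (mono_gain if name == "monosome" else poly_gain if name == "polysome" else 1.0),
            sigma,
        )
        for name, pos, amp, sigma in base.peaks
    )
    return TraceSpec(
        seed=base.seed if seed is None else seed,
        peaks=peaks,
        baseline_slope=base.baseline_slope,
        baseline_intercept=base.baseline_intercept,
        noise_sd=base.noise_sd,
        t_start=base.t_start,
        t_end=base.t_end,
        dt=base.dt,
        condition="PI",
    )


def _gaussian_region_area(
    amplitude: float, mu: float, sigma: float, a: float, b: float
) -> float:
    """Exact integral of a Gaussian peak over [a, b]."""
    z = lambda x: (x - mu) / (sigma * math.sqrt(2))  # noqa: E731
    return amplitude * sigma * math.sqrt(2 * math.pi) * 0.5 * (erf(z(b)) - erf(z(a)))


def generate_polysome_trace(
    spec: TraceSpec, regions: RegionBoundaries = DEFAULT_REGIONS
) -> tuple[PolysomeTrace, dict]:
    """Gaussian peaks + linear baseline + i.i.d. noise, with area truth.

    Truth carries both the total area of each component
    (amplitude * sigma * sqrt(2 pi)) and the exact analytic area of the
    summed peaks inside each named region, so integration accuracy can
    be judged without any 'peak fully inside region' assumption.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.arange(spec.t_start, spec.t_end + spec.dt / 2, spec.dt)
    y = spec.baseline_intercept + spec.baseline_slope * x
    for _, pos, amp, sigma in spec.peaks:
        y = y + amp * np.exp(-0.5 * ((x - pos) / sigma) ** 2)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=x.size)
    trace = PolysomeTrace(x, y, condition=spec.condition)
    component_areas = {
        name: amp * sigma * math.sqrt(2 * math.pi)
        for name, _, amp, sigma in spec.peaks
    }
    region_areas = {
        rname: sum(
            _gaussian_region_area(amp, pos, sigma, a, b)
            for _, pos, amp, sigma in spec.peaks
        )
        for rname, (a, b) in regions.regions.items()
    }
    truth = {
        "component_areas": component_areas,
        "region_areas": region_areas,
        "regions": {n: list(v) for n, v in regions.regions.items()},
        "baseline": [spec.baseline_slope, spec.baseline_intercept],
        "noise_sd": spec.noise_sd,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# pulse-chase decay

def generate_pulse_chase(
    t_half: float,
    timepoints: Sequence[float] = (0.0, 2.0, 4.0),
    cv: float = 0.1,
    replicates: int = 4,
    seed: int = 0,
    condition: str = "control",
    s0: float = 100.0,
) -> pd.DataFrame:
    """Pulse-chase signal table with multiplicative log-normal noise.

    signal = s0 * 2^(-t / t_half) * exp(eps), eps ~ N(0, sigma) with
    sigma chosen so the multiplicative coefficient of variation equals
    ``cv``. ``t_half`` may be ``inf`` (no decay).
    """
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    if not (t_half > 0):
        raise ValidationError("t_half must be positive (or inf)")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv**2))
    rows = []
    for rep in range(1, replicates + 1):
        for t in timepoints:
            mean = s0 if math.isinf(t_half) else s0 * 2.0 ** (-t / t_half)
            eps = rng.normal(0.0, sigma) if cv > 0 else 0.0
            rows.append(
                {
                    "time_h": float(t),
                    "signal": mean * math.exp(eps),
                    "replicate": rep,
                    "condition": condition,
                }
            )
    return pd.DataFrame(rows)


def generate_pulse_chase_pair(
    t_half_control: float = 4.2,
    t_half_treated: float = 40.0,
    timepoints: Sequence[float] = (0.0, 2.0, 4.0),
    cv: float = 0.1,
    replicates: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Control + proteasome-inhibited series in one table.

    Defaults emulate a short-lived protein (t1/2 = 4.2 h) whose
    degradation is largely blocked by proteasome inhibition.
    """
    control = generate_pulse_chase(
        t_half_control, timepoints, cv, replicates, seed=seed, condition="control"
    )
    treated = generate_pulse_chase(
        t_half_treated, timepoints, cv, replicates, seed=seed + 1, condition="PI"
    )
    return pd.concat([control, treated], ignore_index=True)
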