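"""Polysome-profile quantification and the ddPCR translation statistic.

Two independent read-outs of a transcript's translational engagement:

* A254 gradient traces — baseline-corrected and integrated (trapezoid
  rule) over named gradient regions (monosome / disome / polysome).
* Per-fraction ddPCR copy counts — target-mRNA copies normalized to the
  rRNA content of the same fraction (rRNA measured on diluted cDNA, so
  counts are rescaled by the dilution factor), then summarized as

      P = sum(polysome fractions) / (sum(monosome) + sum(polysome))

  with the disome fractions excluded. Fractions are 1-based; defaults
  are monosome {2,3,4}, disome {5,6}, polysome {7..11}.

A between-condition shift is the difference in P: a positive delta is
a rightward shift (into polysomes, increased translation), a negative
one leftward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

MONO_FRACTIONS = frozenset({2, 3, 4})
DISOME_FRACTIONS = frozenset({5, 6})
POLY_FRACTIONS = frozenset({7, 8, 9, 10, 11})
DEFAULT_RRNA_DILUTION = 10_000.0


@dataclass(frozen=True)
class PolysomeTrace:
    """A sampled A254 absorbance trace across a sucrose gradient."""

    positions: np.ndarray
    absorbance: np.ndarray
    condition: str = ""
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "absorbance", a)
        if pos.shape != a.shape:
            raise ValidationError("positions and absorbance differ in length")
        if pos.size < 10:
            raise ValidationError("trace needs at least 10 points")
        if not np.all(np.diff(pos) > 0):
            raise ValidationError("positions must be strictly increasing")


@dataclass(frozen=True)
class RegionBoundaries:
    """Named half-open position intervals [start, stop) on a trace."""

    regions: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (a, b) in self.regions.items():
            if not a < b:
                raise ValidationError(f"region {name}: start {a} not below stop {b}")
        order = [n for n in ("monosome", "disome", "polysome") if n in self.regions]
        starts = [self.regions[n][0] for n in order]
        if starts != sorted(starts):
            raise ValidationError("regions must be ordered monosome < disome < polysome")
        spans = sorted(self.regions.values())
        for (a1, b1), (a2, _) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValidationError("regions overlap")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.regions[name]


def baseline_correct(
    trace: PolysomeTrace,
    method: str = "linear_endpoints",
    anchor_frac: float = 0.05,
    window: int | None = None,
) -> PolysomeTrace:
    """Subtract an estimated baseline from a trace.

    ``linear_endpoints`` fits a straight line by least squares through
    the first and last ``anchor_frac`` of the samples (assumed free of
    peaks) and subtracts it; ``rolling_min`` subtracts a smoothed
    rolling minimum (window default: a tenth of the trace) for
    gradients whose drift is not linear.
    """
    x = trace.positions
    y = trace.absorbance
    if method == "linear_endpoints":
        k = max(2, int(round(anchor_frac * x.size)))
        anchor = np.zeros(x.size, dtype=bool)
        anchor[:k] = True
        anchor[-k:] = True
        slope, intercept = np.polyfit(x[anchor], y[anchor], 1)
        baseline = slope * x + intercept
    elif method == "rolling_min":
        from scipy.ndimage import minimum_filter1d, uniform_filter1d

        size = window if window is not None else max(3, x.size // 10)
        baseline = uniform_filter1d(
            minimum_filter1d(y, size=size, mode="nearest"), size=size, mode="nearest"
        )
    else:
        raise ValidationError(f"unknown baseline method {method!r}")
    meta = dict(trace.meta)
    meta["baseline_method"] = method
    return replace(trace, absorbance=y - baseline, meta=meta)


def integrate_regions(
    trace: PolysomeTrace, regions: RegionBoundaries
) -> dict[str, float]:
    """Trapezoidal area under the trace per named region.

    Region boundaries are half-open for *assignment*, but integration
    runs over the closed sampled span [start, stop]: adjacent regions
    then share their boundary sample and trapezoidal areas stay exactly
    additive when a region is split.
    """
    x = trace.positions
    y = trace.absorbance
    out: dict[str, float] = {}
    for name, (a, b) in regions.regions.items():
        if a < x[0] or b > x[-1] + (x[-1] - x[-2]):
            raise ValidationError(
                f"region {name} [{a}, {b}) outside trace range [{x[0]}, {x[-1]}]"
            )
        mask = (x >= a) & (x <= b)
        if mask.sum() < 2:
            raise ValidationError(f"region {name} covers fewer than 2 samples")
        out[name] = float(np.trapezoid(y[mask], x[mask]))
    return out


def validate_fraction_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a ddPCR fraction-count table.

    Columns: ``fraction`` (1-based int, unique), ``target_copies``,
    ``rrna_copies`` (>= 0) and optional ``rrna_dilution`` (> 0,
    default 10000 — rRNA ddPCR is run on diluted cDNA).
    """
    required = {"fraction", "target_copies", "rrna_copies"}
    missing = required - set(counts.columns)
    if missing:
        raise ValidationError(f"fraction counts missing columns {sorted(missing)}")
    counts = counts.copy()
    if counts["fraction"].duplicated().any():
        raise ValidationError("duplicate fraction indices")
    if (counts["target_copies"] < 0).any() or (counts["rrna_copies"] < 0).any():
        raise ValidationError("negative copy counts")
    if "rrna_dilution" not in counts.columns:
        counts["rrna_dilution"] = DEFAULT_RRNA_DILUTION
    if (counts["rrna_dilution"] <= 0).any():
        raise ValidationError("rrna_dilution must be > 0")
    return counts


def read_fraction_counts(path) -> pd.DataFrame:
    return validate_fraction_counts(pd.read_csv(path, comment="#"))


def normalize_fraction_counts(counts: pd.DataFrame) -> dict[int, float]:
    """Target copies per fraction divided by undiluted-scale rRNA copies.

    normalized_f = target_f / (rrna_f * dilution); raises naming the
    fraction(s) whose rRNA count is zero, since their loading is
    unknowable.
    """
    counts = validate_fraction_counts(counts)
    zero = counts.loc[counts["rrna_copies"] == 0, "fraction"].tolist()
    if zero:
        raise ValidationError(f"zero rRNA copies in fraction(s) {zero}")
    return {
        int(row.fraction): row.target_copies / (row.rrna_copies * row.rrna_dilution)
        for row in counts.itertuples()
    }


@dataclass(frozen=True)
class PolysomeStat:
    """The polysome share P = poly / (mono + poly) of a transcript."""

    P: float
    mono_sum: float
    poly_sum: float
    mono_fractions: frozenset[int]
    poly_fractions: frozenset[int]


def polysome_statistic(
    normalized: Mapping[int, float],
    mono_fractions: frozenset[int] | set[int] = MONO_FRACTIONS,
    poly_fractions: frozenset[int] | set[int] = POLY_FRACTIONS,
) -> PolysomeStat:
    """P = sum(poly) / (sum(mono) + sum(poly)) over normalized counts.

    Disome fractions are excluded simply by never being listed in
    either set.
    """
    mono = frozenset(mono_fractions)
    poly = frozenset(poly_fractions)
    if mono & poly:
        raise ValidationError(f"fraction sets overlap: {sorted(mono & poly)}")
    missing = (mono | poly) - set(normalized)
    if missing:
        raise ValidationError(f"fractions missing from counts: {sorted(missing)}")
    mono_sum = float(sum(normalized[f] for f in mono))
    poly_sum = float(sum(normalized[f] for f in poly))
    denom = mono_sum + poly_sum
    if denom == 0:
        raise ValidationError("monosome + polysome signal is zero")
    return PolysomeStat(poly_sum / denom, mono_sum, poly_sum, mono, poly)


def condition_shift(
    control: PolysomeStat, treated: PolysomeStat, tolerance: float = 0.01
) -> tuple[float, str]:
    """Between-condition change in P and its direction label.

    ``rightward`` (toward polysomes) if delta > tolerance, ``leftward``
    if delta < -tolerance, else ``none``. Default tolerance 0.01 sits
    below ddPCR counting noise at typical copy numbers.
    """
    if (
        control.mono_fractions != treated.mono_fractions
        or control.poly_fractions != treated.poly_fractions
    ):
        raise ValidationError("conditions use different fraction schemes")
    delta = treated.P - control.P
    if delta > tolerance:
        label = "rightward"
    elif delta < -tolerance:
        label = "leftward"
    else:
        label = "none"
    return delta, label
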