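"""Pulse-chase decay kinetics: half-life estimation and comparison.

A pulse-chase time course (metabolic label at t = 0, signal measured
at chase times) is modeled as first-order decay with multiplicative
error, so ln(signal) is linear in time and the half-life is estimated
by ordinary least squares of ln(signal) on time with replicates pooled
into one regression:

    ln S(t) = intercept - k * t,    t_half = ln 2 / k.

Growth (positive slope) is clipped to k = 0 and reported as an
infinite half-life with a warning — a chase signal cannot physically
increase, so an upward trend is noise or label re-incorporation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

DECAY_COLUMNS = ("time_h", "signal", "replicate", "condition")


def validate_decay_series(data: pd.DataFrame) -> pd.DataFrame:
    missing = set(DECAY_COLUMNS) - set(data.columns)
    if missing:
        raise ValidationError(f"decay series missing columns {sorted(missing)}")
    if (data["signal"] <= 0).any():
        raise ValidationError("signals must be positive (log-linear fit)")
    if (data["time_h"] < 0).any():
        raise ValidationError("negative chase times")
    return data


def read_decay_series(path) -> pd.DataFrame:
    return validate_decay_series(pd.read_csv(path, comment="#"))


@dataclass(frozen=True)
class HalfLifeFit:
    """Fitted first-order decay for one condition.

    ``t_half`` is in hours (may be ``inf`` when no decay is detected),
    ``k`` the decay rate per hour, ``intercept`` the fitted ln-signal
    at t = 0 and ``r_squared`` the usual coefficient of determination
    of the log-linear regression.
    """

    condition: str
    t_half: float
    k: float
    intercept: float
    r_squared: float
    n_obs: int

    def predicted_fraction(self, t: float) -> float:
        """Predicted fraction of the t = 0 signal remaining at time t."""
        if t < 0:
            raise ValidationError("negative time")
        if math.isinf(self.t_half):
            return 1.0
        return 2.0 ** (-t / self.t_half)

    def summary(self) -> str:
        lines = [
            f"Half-life fit ({self.condition})",
            "-" * 32,
            f"n observations   {self.n_obs}",
            f"k (per hour)     {self.k:.4f}",
            f"t_half (hours)   "
            + ("inf" if math.isinf(self.t_half) else f"{self.t_half:.3f}"),
            f"ln-intercept     {self.intercept:.4f}",
            f"R-squared        {self.r_squared:.4f}",
        ]
        return "\n".join(lines)


class HalfLifeModel:
    """Log-linear decay model over a pulse-chase table.

    Parameters
    ----------
    data : DataFrame with columns ``time_h, signal, replicate,
        condition``; replicates are pooled into a single regression.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = validate_decay_series(data)

    @classmethod
    def from_csv(cls, path) -> "HalfLifeModel":
        return cls(read_decay_series(path))

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))

    def fit(self, condition: str | None = None) -> HalfLifeFit:
        if condition is None:
            conds = self.conditions()
            if len(conds) != 1:
                raise ValidationError(
                    f"multiple conditions present {conds}; name one to fit"
                )
            condition = conds[0]
        sub = self.data[self.data["condition"] == condition]
        if sub.empty:
            raise ValidationError(f"condition {condition!r} absent from series")
        t = sub["time_h"].to_numpy(dtype=float)
        y = np.log(sub["signal"].to_numpy(dtype=float))
        if np.unique(t).size < 2:
            raise ValidationError("need at least 2 distinct timepoints")
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (slope * t + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r_squared = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        k = max(0.0, -float(slope))
        if slope > 0:
            logger.warning(
                "condition %r: signal increases over the chase (slope %.3g); "
                "reporting t_half = inf",
                condition,
                slope,
            )
        t_half = math.inf if k == 0 else math.log(2) / k
        return HalfLifeFit(
            condition=condition,
            t_half=t_half,
            k=k,
            intercept=float(intercept),
            r_squared=max(0.0, min(1.0, r_squared)),
            n_obs=int(sub.shape[0]),
        )


def fit_half_life(series: pd.DataFrame, condition: str) -> HalfLifeFit:
    """OLS half-life of one condition (replicates pooled)."""
    return HalfLifeModel(series).fit(condition)


def remaining_fraction_table(
    fit: HalfLifeFit, times: Iterable[float]
) -> dict[float, float]:
    """Predicted remaining signal fraction 2^(-t / t_half) per time."""
    return {float(t): fit.predicted_fraction(float(t)) for t in times}


@dataclass(frozen=True)
class ConditionComparison:
    fit_control: HalfLifeFit
    fit_treated: HalfLifeFit
    stabilization_ratio: float


def compare_conditions(
    series: pd.DataFrame, control: str = "control", treated: str = "PI"
) -> ConditionComparison:
    """Fit both conditions and report t_half(treated) / t_half(control).

    An infinite treated half-life (fully blocked degradation)
    propagates to an infinite ratio.
    """
    model = HalfLifeModel(series)
    present = set(model.conditions())
    for cond in (control, treated):
        if cond not in present:
            raise ValidationError(f"condition {cond!r} missing (have {sorted(present)})")
    fit_c = model.fit(control)
    fit_t = model.fit(treated)
    if math.isinf(fit_t.t_half) and math.isinf(fit_c.t_half):
        ratio = math.nan
    else:
        ratio = fit_t.t_half / fit_c.t_half
    return ConditionComparison(fit_c, fit_t, ratio)


def comparison_report(cmp: ConditionComparison) -> Mapping[str, object]:
    def fit_dict(f: HalfLifeFit) -> dict[str, object]:
        return {
            "condition": f.condition,
            "t_half_h": None if math.isinf(f.t_half) else f.t_half,
            "k_per_h": f.k,
            "intercept": f.intercept,
            "r_squared": f.r_squared,
            "n_obs": f.n_obs,
        }

    ratio = cmp.stabilization_ratio
    return {
        "control": fit_dict(cmp.fit_control),
        "treated": fit_dict(cmp.fit_treated),
        "stabilization_ratio": None if not math.isfinite(ratio) else ratio,
    }
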