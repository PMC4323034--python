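"""Retained lung-burden kinetics with overload-dependent clearance retardation.

The lung is treated as a single compartment.  Alveolar-macrophage (AM)
mediated clearance of retained particles is first order with a half-time
that is constant (60-90 days band, default anchor 80 days) as long as the
retained volumetric burden stays below the adaptive threshold of ~1 ul per
rat lung.  Above that threshold the clearance progressively slows
("overload"), reaching exhaustion — a half-time of one year — at a burden of
~10 ul/lung.  Dissolution, where present, acts as a parallel first-order
elimination pathway and simply adds to the rate constant.

The daily simulation uses operator splitting: each exposure day deposits its
dose as a bolus and the burden decays by exp(-ln2/t_half(V)) per day using
the current burden's half-time.  Printed half-times are tens to hundreds of
days, so daily resolution is ample.  The recorded burden for day *n* is the
value immediately after that day's deposition (having decayed over all
previous days); with a constant daily dose *d* and fixed half-time this
converges to the geometric-series steady state d / (1 - exp(-ln2/t_half)).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    ShortFitWindowWarning,
)
from .params import ExposureRegimen, ParticleSpec, SpeciesDosimetry

__all__ = [
    "ClearanceRegime",
    "RetardationModel",
    "ClearanceParams",
    "BurdenTimeSeries",
    "HalfTimeEstimate",
    "retarded_half_time",
    "simulate_burden",
    "simulate_decay",
    "steady_state_burden",
    "estimate_elimination_half_time",
    "classify_clearance_regime",
]

LN2 = math.log(2)

#: Normal AM-mediated clearance band for poorly soluble particles, days.
NORMAL_HALF_TIME_BAND = (60.0, 90.0)
#: Half-time at which physiological clearance is considered exhausted (MTD).
MTD_HALF_TIME_DAYS = 365.0


class ClearanceRegime(str, enum.Enum):
    """Interpretation bands for an observed elimination half-time."""

    DISSOLUTION_DOMINATED = "dissolution_dominated"  # < 60 d
    NORMAL_AM_CLEARANCE = "normal_am_clearance"  # 60-90 d
    OVERLOAD_ONSET = "overload_onset"  # > 90 d, < 1 year
    MTD_EXCEEDED = "mtd_exceeded"  # >= 1 year


@dataclass(frozen=True)
class RetardationModel:
    """Burden-dependent elimination half-time t_half(V).

    Anchored at (v_noael_anchor, t_half_base) and (v_mtd_anchor,
    t_half_mtd); below the first anchor the half-time is the constant
    baseline, between the anchors it is interpolated (linearly in V, or
    linearly in log V and log t for ``loglinear``), and above the second
    anchor the terminal slope of the interpolation is continued.

    Modes
    -----
    none
        Constant half-time ``t_half_base`` at any burden (``math.inf``
        allowed, expressing absent clearance).
    linear / loglinear
        Two-anchor interpolation as above; ``loglinear`` is the default
        because it is smooth, monotone and respects both printed anchors.
    custom
        Piecewise-linear over user anchors sorted by burden.
    """

    mode: str = "loglinear"
    v_noael_anchor: float = 1.0  # ul/lung
    t_half_base: float = 80.0  # days
    v_mtd_anchor: float = 10.0  # ul/lung
    t_half_mtd: float = MTD_HALF_TIME_DAYS  # days; 400 d also printed, selectable
    custom_anchors: Optional[Sequence[Tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "linear", "loglinear", "custom"):
            raise InvalidParameterError(f"unknown retardation mode {self.mode!r}")
        if not self.t_half_base > 0:
            raise InvalidParameterError("t_half_base must be positive")
        if self.mode in ("linear", "loglinear"):
            if not self.t_half_mtd > self.t_half_base:
                raise InvalidParameterError("t_half_mtd must exceed t_half_base")
            if not self.v_mtd_anchor > self.v_noael_anchor > 0:
                raise InvalidParameterError(
                    "anchors must satisfy v_mtd_anchor > v_noael_anchor > 0"
                )
        if self.mode == "custom":
            anchors = list(self.custom_anchors or [])
            if len(anchors) < 2:
                raise InvalidParameterError("custom mode needs >= 2 anchors")
            burdens = [a[0] for a in anchors]
            halves = [a[1] for a in anchors]
            if sorted(burdens) != burdens or len(set(burdens)) != len(burdens):
                raise InvalidParameterError("custom anchors must be sorted by burden")
            if any(h <= 0 for h in halves) or any(
                h2 < h1 for h1, h2 in zip(halves, halves[1:])
            ):
                raise InvalidParameterError(
                    "custom anchor half-times must be positive and non-decreasing"
                )


@dataclass(frozen=True)
class ClearanceParams:
    """Clearance configuration: retardation model plus optional dissolution."""

    retardation: RetardationModel = field(default_factory=RetardationModel)
    k_dissolution: float = 0.0  # parallel first-order rate, per day
    normal_band: Tuple[float, float] = NORMAL_HALF_TIME_BAND

    def __post_init__(self) -> None:
        if self.k_dissolution < 0:
            raise InvalidParameterError("k_dissolution must be >= 0")


def retarded_half_time(v: float, model: RetardationModel) -> float:
    """Elimination half-time (days) at retained burden ``v`` (ul/lung)."""
    if v < 0:
        raise InvalidParameterError("burden must be >= 0")
    if model.mode == "none":
        return model.t_half_base
    if model.mode == "custom":
        burdens = np.array([a[0] for a in model.custom_anchors], dtype=float)
        halves = np.array([a[1] for a in model.custom_anchors], dtype=float)
        if v <= burdens[0]:
            return float(halves[0])
        if v >= burdens[-1]:
            # continue the terminal slope
            slope = (halves[-1] - halves[-2]) / (burdens[-1] - burdens[-2])
            return float(halves[-1] + slope * (v - burdens[-1]))
        return float(np.interp(v, burdens, halves))
    if v <= model.v_noael_anchor:
        return model.t_half_base
    if model.mode == "linear":
        slope = (model.t_half_mtd - model.t_half_base) / (
            model.v_mtd_anchor - model.v_noael_anchor
        )
        return model.t_half_base + slope * (v - model.v_noael_anchor)
    # loglinear: log t linear in log V between the anchors, extended beyond
    frac = math.log(v / model.v_noael_anchor) / math.log(
        model.v_mtd_anchor / model.v_noael_anchor
    )
    return model.t_half_base * (model.t_half_mtd / model.t_half_base) ** frac


@dataclass
class BurdenTimeSeries:
    """Daily retained volumetric lung burden of a simulated study.

    Wraps a DataFrame with columns ``day`` (int, from study start), ``phase``
    ("exposure" or "postexposure"), ``burden_ul`` and ``burden_mg``.
    """

    frame: pd.DataFrame
    rho: float = 1.0

    def __post_init__(self) -> None:
        required = {"day", "phase", "burden_ul", "burden_mg"}
        if not required.issubset(self.frame.columns):
            raise InvalidParameterError(f"frame must have columns {sorted(required)}")
        if (self.frame["burden_ul"] < 0).any():
            raise InvalidParameterError("burdens must be >= 0")
        if not self.frame["day"].is_monotonic_increasing:
            raise InvalidParameterError("days must be increasing")

    @property
    def final_burden(self) -> float:
        return float(self.frame["burden_ul"].iloc[-1])

    def burden_at(self, day: int) -> float:
        row = self.frame.loc[self.frame["day"] == day, "burden_ul"]
        if row.empty:
            raise InvalidParameterError(f"day {day} not in series")
        return float(row.iloc[0])

    def postexposure(self) -> pd.DataFrame:
        return self.frame[self.frame["phase"] == "postexposure"]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _daily_rate(v: float, clearance: ClearanceParams) -> float:
    t_half = retarded_half_time(v, clearance.retardation)
    k_am = 0.0 if math.isinf(t_half) else LN2 / t_half
    return k_am + clearance.k_dissolution


def simulate_burden(
    regimen: ExposureRegimen,
    particle: Optional[ParticleSpec],
    species: Optional[SpeciesDosimetry],
    clearance: ClearanceParams,
    dose_rate_per_day: float,
    initial_burden: float = 0.0,
) -> BurdenTimeSeries:
    """Simulate the retained volumetric lung burden on a daily grid.

    ``dose_rate_per_day`` is the deposited volume per exposure day
    (ul/lung/day), supplied by the caller — typically derived through the
    accumulation-factor formalism of the thresholds module.  Exposure days
    are the first ``days_per_week`` consecutive days of each week for
    ``duration_weeks`` weeks, followed by ``postexposure_days`` of clearance
    only.  ``particle`` supplies rho for the mass column (1 g/cm^3 when
    None); ``species`` is carried for provenance and not used by the daily
    update itself.
    """
    if dose_rate_per_day < 0:
        raise InvalidParameterError("dose_rate_per_day must be >= 0")
    if initial_burden < 0:
        raise InvalidParameterError("initial_burden must be >= 0")
    rho = particle.rho_apparent if particle is not None else 1.0

    exposure_days_total = int(round(regimen.duration_weeks * 7))
    total_days = exposure_days_total + int(regimen.postexposure_days)
    days = np.arange(total_days + 1)
    burden = np.empty(total_days + 1)
    phase = np.where(days <= exposure_days_total, "exposure", "postexposure")

    v = initial_burden
    burden[0] = v
    for d in range(1, total_days + 1):
        v *= math.exp(-_daily_rate(v, clearance))
        if d <= exposure_days_total and (d - 1) % 7 < regimen.days_per_week:
            v += dose_rate_per_day
        burden[d] = v

    frame = pd.DataFrame(
        {"day": days, "phase": phase, "burden_ul": burden, "burden_mg": burden * rho}
    )
    return BurdenTimeSeries(frame=frame, rho=rho)


def simulate_decay(
    initial_burden: float, days: int, clearance: ClearanceParams
) -> np.ndarray:
    """Post-exposure decay of a burden over ``days`` days (values for day 0..days)."""
    if initial_burden < 0:
        raise InvalidParameterError("initial_burden must be >= 0")
    out = np.empty(days + 1)
    v = initial_burden
    out[0] = v
    for d in range(1, days + 1):
        v *= math.exp(-_daily_rate(v, clearance))
        out[d] = v
    return out


def steady_state_burden(dose_per_day: float, t_half: float) -> float:
    """Closed-form steady state of daily dosing at a fixed half-time.

    The post-deposition burden of the daily bolus-decay recursion converges
    to ``d / (1 - exp(-ln2/t_half))``.
    """
    if not t_half > 0:
        raise InvalidParameterError("t_half must be positive")
    return dose_per_day / (1.0 - math.exp(-LN2 / t_half))


@dataclass(frozen=True)
class HalfTimeEstimate:
    """Log-linear first-order fit of post-exposure burden decay."""

    t_half: float  # days
    stderr: float  # standard error of t_half (delta method)
    slope: float  # per day, fitted on ln(burden)
    n_obs: int
    window_days: float

    def __float__(self) -> float:
        return self.t_half


def estimate_elimination_half_time(
    observations: pd.DataFrame,
    fit_phase: str = "postexposure",
    burden_column: Optional[str] = None,
) -> HalfTimeEstimate:
    """Estimate the elimination half-time from (day, burden) observations.

    Performs an unweighted least-squares fit of ln(burden) against day over
    the rows whose ``phase`` matches ``fit_phase`` (all rows when no phase
    column is present) and returns ``t_half = ln2 / |slope|`` with its
    standard error propagated by the delta method.  Emits
    :class:`ShortFitWindowWarning` when the observation window is shorter
    than the estimated half-time.
    """
    df = observations
    if "phase" in df.columns:
        df = df[df["phase"] == fit_phase]
    if burden_column is None:
        candidates = [c for c in ("burden_ul", "burden", "observed_burden") if c in df.columns]
        if not candidates:
            raise InsufficientDataError("no burden column found in observations")
        burden_column = candidates[0]
    df = df[["day", burden_column]].dropna()
    if len(df) < 3:
        raise InsufficientDataError("need >= 3 post-exposure observations")
    burdens = df[burden_column].to_numpy(dtype=float)
    if np.any(burdens <= 0):
        raise InsufficientDataError("all observed burdens must be positive")
    days = df["day"].to_numpy(dtype=float)
    if np.ptp(days) == 0:
        raise InsufficientDataError("observations must span more than one day")

    fit = stats.linregress(days, np.log(burdens))
    slope = fit.slope
    if slope == 0:
        raise InsufficientDataError("flat burden profile: half-time not identifiable")
    t_half = LN2 / abs(slope)
    stderr = LN2 * fit.stderr / slope**2 if fit.stderr is not None else math.nan
    window = float(np.ptp(days))
    if window < t_half:
        warnings.warn(
            f"fit window ({window:.0f} d) is shorter than the estimated "
            f"half-time ({t_half:.0f} d); the estimate may be imprecise",
            ShortFitWindowWarning,
            stacklevel=2,
        )
    return HalfTimeEstimate(
        t_half=t_half, stderr=stderr, slope=slope, n_obs=len(df), window_days=window
    )


def classify_clearance_regime(t_half: float) -> ClearanceRegime:
    """Classify an elimination half-time into the clearance-regime bands.

    < 60 d: dissolution-dominated; 60-90 d: normal AM-mediated clearance;
    > 90 d and < 1 year: overload onset; >= 1 year: exhausted clearance
    (maximum tolerated dose exceeded).
    """
    if not t_half > 0:
        raise InvalidParameterError("t_half must be positive")
    low, high = NORMAL_HALF_TIME_BAND
    if t_half < low:
        return ClearanceRegime.DISSOLUTION_DOMINATED
    if t_half <= high:
        return ClearanceRegime.NORMAL_AM_CLEARANCE
    if t_half < MTD_HALF_TIME_DAYS:
        return ClearanceRegime.OVERLOAD_ONSET
    return ClearanceRegime.MTD_EXCEEDED
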