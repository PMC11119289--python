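"""Calibration curves and fermentation time-series summaries.

Covers the quantitative wet-lab arithmetic of the study design: the
phenol–sulfuric total-sugar standard curve with inverse prediction, the
size-exclusion (SEC) retention-time → log10(Mw) calibration, growth-phase
summarization of OD600 curves, and degradation metrics (percent drop,
steepest-decline interval) over residual-sugar / molecular-weight series.

The SEC relation is implemented as affine log-linear (slope + intercept):
a pure proportionality cannot fit a realistic dextran standard ladder, and
"proportional to the logarithm" is universally operationalised as a
straight-line fit of log10(Mw) on retention time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUGAR_STANDARD = "sugar_standard"
SEC_MW = "sec_mw"

#: glucose standards of the phenol–sulfuric assay, mg/mL
GLUCOSE_STANDARDS_MG_ML = (0.0, 0.02, 0.04, 0.06, 0.08, 0.1)
#: dextran SEC standards, Da
SEC_STANDARDS_DA = (4.66e3, 12.6e3, 50.0e3, 63.3e3, 126e3, 496e3)
#: default sampling grid of the fermentation experiments, hours
DEFAULT_TIMES_H = (0.0, 12.0, 24.0, 48.0, 72.0)


class DegenerateFitError(ValueError):
    """All x identical, or a zero-slope curve used for calibration."""


class ExtrapolationError(ValueError):
    """Query outside the calibrated domain (plus allowed margin)."""


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted linear map y = slope*x + intercept."""

    kind: str                    # SUGAR_STANDARD or SEC_MW
    slope: float
    intercept: float
    r2: float
    x_domain: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in (SUGAR_STANDARD, SEC_MW):
            raise ValueError(f"unknown calibration kind {self.kind!r}")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must be in [0, 1]")

    @property
    def accepted(self) -> bool:
        return self.slope != 0.0


@dataclass(frozen=True)
class TimeSeries:
    """One measured trajectory: (time h, value) with strictly increasing times."""

    analyte: str                 # 'OD600', 'total_sugar', 'Mw'
    substrate: str
    points: tuple[tuple[float, float], ...]
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if any(t < 0 for t in times):
            raise ValueError("times must be >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(v < 0 for _, v in self.points):
            raise ValueError("values must be >= 0")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.points)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.points)


@dataclass(frozen=True)
class GrowthSummary:
    lag_end: float
    max_value: float
    time_of_max: float
    stationary_start: float
    no_growth: bool = False
    no_plateau: bool = False


@dataclass(frozen=True)
class DegradationMetrics:
    absolute_drop: float
    percent_drop: float
    steepest_interval: tuple[float, float]


@dataclass(frozen=True)
class Prediction:
    value: float
    clipped: bool = False


# ---------------------------------------------------------------------------
# calibration


def fit_line(x: Sequence[float], y: Sequence[float], kind: str = SUGAR_STANDARD) -> CalibrationCurve:
    """Ordinary least squares y on x.

    r2 = 1 − SSres/SStot, defined as 1.0 in the degenerate SStot = 0 case
    when the fit is also exact.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-d arrays with >= 2 points")
    if np.unique(x).size < 2:
        raise DegenerateFitError("all x values identical; cannot fit a line")
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    else:
        r2 = 1.0 if math.isclose(ss_res, 0.0, abs_tol=1e-30) else 0.0
    return CalibrationCurve(
        kind=kind,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        x_domain=(float(x.min()), float(x.max())),
    )


def fit_sugar_standard(
    concentrations: Sequence[float] = GLUCOSE_STANDARDS_MG_ML,
    absorbances: Sequence[float] = (),
) -> CalibrationCurve:
    """Absorbance-vs-concentration standard curve (OD490 on mg/mL)."""
    return fit_line(concentrations, absorbances, kind=SUGAR_STANDARD)


def fit_sec_calibration(
    retention_times: Sequence[float],
    molecular_weights: Sequence[float] = SEC_STANDARDS_DA,
) -> CalibrationCurve:
    """log10(Mw) on retention time; slope < 0 expected (big molecules elute first)."""
    mw = np.asarray(molecular_weights, dtype=float)
    if np.any(mw <= 0):
        raise ValueError("molecular weights must be > 0")
    return fit_line(retention_times, np.log10(mw), kind=SEC_MW)


def sugar_concentration(
    absorbance: float,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
) -> Prediction:
    """Invert the standard curve; negative predictions clip to 0 (flagged)."""
    if curve.kind != SUGAR_STANDARD:
        raise TypeError(f"need a {SUGAR_STANDARD} curve, got {curve.kind}")
    if not curve.accepted:
        raise DegenerateFitError("zero-slope curve rejected for calibration use")
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    conc = dilution_factor * (absorbance - curve.intercept) / curve.slope
    if conc < 0:
        # flag only physically meaningful negatives, not fp noise at the
        # exact zero crossing
        return Prediction(0.0, clipped=conc < -1e-12)
    return Prediction(conc)


def mw_from_rt(
    retention_time: float,
    curve: CalibrationCurve,
    extrapolation_margin: float = 0.1,
) -> float:
    """Mw (Da) from retention time via the log-linear SEC calibration."""
    if curve.kind != SEC_MW:
        raise TypeError(f"need a {SEC_MW} curve, got {curve.kind}")
    if not curve.accepted:
        raise DegenerateFitError("zero-slope curve rejected for calibration use")
    lo, hi = curve.x_domain
    margin = extrapolation_margin * (hi - lo)
    if not (lo - margin <= retention_time <= hi + margin):
        raise ExtrapolationError(
            f"retention time {retention_time} outside calibrated domain "
            f"[{lo}, {hi}] ± {margin:g}"
        )
    return 10.0 ** (curve.slope * retention_time + curve.intercept)


# ---------------------------------------------------------------------------
# time-series summaries


def degradation_metrics(series: TimeSeries) -> DegradationMetrics:
    """Total drop, percent drop, and the consecutive interval of steepest decline.

    The steepest interval maximizes (v_i − v_{i+1})/(t_{i+1} − t_i); ties
    resolve to the earliest interval.
    """
    if len(series.points) < 2:
        raise ValueError("need at least 2 points")
    v = series.values
    t = series.times
    if v[0] == 0:
        raise ValueError("percent drop undefined: first value is 0")
    absolute = v[0] - v[-1]
    percent = 100.0 * absolute / v[0]
    best = None
    best_rate = -math.inf
    for i in range(len(v) - 1):
        rate = (v[i] - v[i + 1]) / (t[i + 1] - t[i])
        if rate > best_rate:  # strict: ties keep the earliest interval
            best_rate = rate
            best = (t[i], t[i + 1])
    return DegradationMetrics(absolute, percent, best)


def summarize_growth(
    series: TimeSeries,
    baseline_delta: float = 0.05,
    plateau_eps: float = 0.02,
) -> GrowthSummary:
    """Lag end, maximum, and stationary-phase onset of an OD600 curve.

    lag_end: last sampled time before the value first exceeds
    value(0) + baseline_delta.  stationary_start: earliest time after which
    every successive increase is < plateau_eps.
    """
    if len(series.points) < 3:
        raise ValueError("need at least 3 points")
    t = series.times
    v = series.values
    threshold = v[0] + baseline_delta
    exceed = next((i for i, val in enumerate(v) if val > threshold), None)
    no_growth = exceed is None
    lag_end = t[-1] if no_growth else t[max(exceed - 1, 0)]
    imax = int(np.argmax(v))
    # walk back from the end while increases stay below plateau_eps
    j = len(v) - 1
    while j > 0 and v[j] - v[j - 1] < plateau_eps:
        j -= 1
    no_plateau = j == len(v) - 1
    return GrowthSummary(
        lag_end=lag_end,
        max_value=v[imax],
        time_of_max=t[imax],
        stationary_start=t[j],
        no_growth=no_growth,
        no_plateau=no_plateau,
    )


def mean_series(replicates: Sequence[TimeSeries]) -> TimeSeries:
    """Mean across replicates sharing a time grid (triplicate summarization)."""
    if not replicates:
        raise ValueError("need at least one replicate")
    grids = {r.times for r in replicates}
    if len(grids) != 1:
        raise ValueError("replicates must share one time grid")
    times = replicates[0].times
    means = np.mean([r.values for r in replicates], axis=0)
    return TimeSeries(
        analyte=replicates[0].analyte,
        substrate=replicates[0].substrate,
        points=tuple(zip(times, (float(m) for m in means))),
        replicate_id="mean",
    )


# ---------------------------------------------------------------------------
# CSV I/O

TIMESERIES_COLUMNS = ["analyte", "substrate", "replicate", "time_h", "value"]


def read_timeseries_csv(path: str | Path) -> list[TimeSeries]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(TIMESERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    out = []
    for (analyte, substrate, rep), grp in df.groupby(
        ["analyte", "substrate", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        out.append(TimeSeries(
            analyte=str(analyte),
            substrate=str(substrate),
            points=tuple(zip(grp["time_h"].astype(float), grp["value"].astype(float))),
            replicate_id=str(rep),
        ))
    return out


def write_timeseries_csv(series: Sequence[TimeSeries], path: str | Path) -> None:
    rows = [
        {"analyte": s.analyte, "substrate": s.substrate,
         "replicate": s.replicate_id or "1", "time_h": t, "value": v}
        for s in series for t, v in s.points
    ]
    pd.DataFrame(rows, columns=TIMESERIES_COLUMNS).to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> dict[str, CalibrationCurve]:
    """Read 'x,y,kind' rows and fit one curve per kind."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = {"x", "y", "kind"} - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    curves = {}
    for kind, grp in df.groupby("kind"):
        curves[str(kind)] = fit_line(
            grp["x"].astype(float), grp["y"].astype(float), kind=str(kind)
        )
    return curves
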