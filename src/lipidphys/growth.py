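"""Growth-curve parameter estimation and physiological time-point selection.

Estimates the three quantities classically read off a microbial batch growth
curve — the lag phase :math:`\\lambda`, the maximum specific growth rate
:math:`\\mu_{max}` (maximum slope of ln OD600 versus time) and the maximum
cell density — and selects the three sampling times used for lipid analysis:
the times at which the culture first reaches one fifth of OD max, half of
OD max, and OD max.

The estimator is model-free: :math:`\\mu_{max}` comes from a sliding-window
log-linear regression, and the lag is the intersection of the tangent at the
maximum-slope window with the pre-growth baseline level, the standard
graphical lag construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ODTimeSeries",
    "GrowthParameters",
    "TimepointSelection",
    "fit_growth",
    "generation_time",
    "select_timepoints",
]


@dataclass(frozen=True)
class ODTimeSeries:
    """One strain x medium growth record.

    Parameters
    ----------
    strain_label, medium_label
        Free-text identifiers (e.g. ``"YAHI"``, ``"oleic"``).
    times
        Sampling times in hours, strictly increasing, >= 5 points.
    od
        OD600 readings, all positive.
    replicate
        Replicate identifier.
    """

    strain_label: str
    medium_label: str
    times: np.ndarray
    od: np.ndarray
    replicate: str = "1"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)
        if t.ndim != 1 or od.shape != t.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if t.size < 5:
            raise ValueError("a growth record needs at least 5 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(od > 0):
            raise ValueError("all OD600 values must be positive")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class GrowthParameters:
    """Estimated growth parameters with fit diagnostics.

    ``lag`` is ``None`` when no lag phase is detectable (the convention for
    cultures that start growing immediately, e.g. on oleic acid medium).
    ``no_growth`` flags series whose maximum log-slope is indistinguishable
    from zero; all other fields are then best-effort.
    """

    strain_label: str
    medium_label: str
    mu_max: float
    lag: float | None
    od_max: float
    generation_time: float | None
    window_start: float
    window_end: float
    r2: float
    no_growth: bool = False


@dataclass(frozen=True)
class TimepointSelection:
    """The three physiological sampling times (1/5, 1/2 and 1 x OD max).

    Fields are ``None`` with an entry in ``warnings`` when the smoothed curve
    never reaches the corresponding target.
    """

    t_fifth: float | None
    t_half: float | None
    t_max: float | None
    od_fifth: float | None
    od_half: float | None
    od_max_reached: float | None
    warnings: tuple[str, ...] = field(default=())

    def as_tuple(self) -> tuple[float | None, float | None, float | None]:
        return (self.t_fifth, self.t_half, self.t_max)


def _rolling_median(x: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered rolling median with edge replication (keeps monotone ends)."""
    half = window // 2
    padded = np.pad(np.asarray(x, dtype=float), half, mode="edge")
    out = np.empty(x.size, dtype=float)
    for i in range(x.size):
        out[i] = np.median(padded[i : i + 2 * half + 1])
    return out


def generation_time(mu_max: float) -> float:
    """Population doubling time ln(2)/mu_max in hours.

    Raises ``ValueError`` for non-positive growth rates.
    """
    if mu_max <= 0:
        raise ValueError(f"generation time undefined for mu_max={mu_max!r} <= 0")
    return math.log(2.0) / mu_max


def fit_growth(
    series: ODTimeSeries,
    window: int = 5,
    lag_threshold: float = 0.10,
    min_growth_rate: float = 0.01,
    smooth_window: int = 3,
) -> GrowthParameters:
    """Estimate mu_max, lag and OD max from an OD600 time series.

    mu_max is the largest least-squares slope of ln(OD) over all windows of
    ``window`` consecutive points (ties broken by the earliest window). The
    lag is where the tangent line of that window meets the baseline ln(OD)
    level, the baseline being the mean over the initial plateau — the leading
    run of points with OD <= od0*(1 + lag_threshold). The lag is reported
    absent when the intersection is at or before t=0 or when the plateau is
    shorter than one sampling interval. OD max is the maximum of the
    median-smoothed series.

    Parameters
    ----------
    window
        Sliding-window length in points, >= 3 and <= len(series).
    lag_threshold
        Relative OD rise over the first reading that ends the baseline.
    min_growth_rate
        Log-slope (h^-1) below which the series is flagged no-growth.
    """
    if window < 3:
        raise ValueError("window must span at least 3 points")
    n = len(series)
    if window > n:
        raise ValueError(f"window ({window}) exceeds series length ({n})")

    t = series.times
    ln_od = np.log(series.od)
    smoothed = _rolling_median(series.od, smooth_window)
    od_max = float(np.max(smoothed))

    best = None  # (slope, start_idx, intercept, r2)
    for i in range(n - window + 1):
        sl = slice(i, i + window)
        res = stats.linregress(t[sl], ln_od[sl])
        if best is None or res.slope > best[0] + 1e-15:
            best = (res.slope, i, res.intercept, res.rvalue ** 2)
    slope, i0, intercept, r2 = best
    w_start, w_end = float(t[i0]), float(t[i0 + window - 1])

    if slope < min_growth_rate:
        return GrowthParameters(
            strain_label=series.strain_label,
            medium_label=series.medium_label,
            mu_max=max(slope, 0.0),
            lag=None,
            od_max=od_max,
            generation_time=None,
            window_start=w_start,
            window_end=w_end,
            r2=r2,
            no_growth=True,
        )

    # Baseline: leading run of near-initial OD readings.
    od0 = series.od[0]
    plateau = 0
    while plateau < n and series.od[plateau] <= od0 * (1.0 + lag_threshold):
        plateau += 1
    lag: float | None = None
    if plateau >= 2:  # plateau spans at least one sampling interval
        baseline = float(np.mean(ln_od[:plateau]))
        lam = (baseline - intercept) / slope
        if 0.0 < lam < w_start:
            lag = float(lam)

    return GrowthParameters(
        strain_label=series.strain_label,
        medium_label=series.medium_label,
        mu_max=float(slope),
        lag=lag,
        od_max=od_max,
        generation_time=generation_time(slope),
        window_start=w_start,
        window_end=w_end,
        r2=float(r2),
    )


def _first_crossing(t: np.ndarray, y: np.ndarray, target: float) -> float | None:
    """Earliest time at which linearly interpolated y first reaches target."""
    if y[0] >= target:
        return float(t[0])
    above = np.nonzero(y >= target)[0]
    if above.size == 0:
        return None
    j = above[0]
    # linear interpolation between (j-1, j)
    t0, t1, y0, y1 = t[j - 1], t[j], y[j - 1], y[j]
    if y1 == y0:
        return float(t1)
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))


def select_timepoints(
    series: ODTimeSeries,
    params: GrowthParameters,
    delta: float = 0.02,
    smooth_window: int = 3,
) -> TimepointSelection:
    """Earliest times at which the smoothed curve reaches OD max/5, OD max/2
    and (1 - delta) x OD max.

    The slight shave ``delta`` on the final target makes the OD-max crossing
    well defined on curves that approach their plateau asymptotically.
    Requires a series with detectable growth.
    """
    if params.no_growth:
        raise ValueError("cannot select timepoints on a no-growth series")
    t = series.times
    sm = _rolling_median(series.od, smooth_window)
    od_max = params.od_max
    targets = {
        "fifth": od_max / 5.0,
        "half": od_max / 2.0,
        "max": (1.0 - delta) * od_max,
    }
    times: dict[str, float | None] = {}
    warns: list[str] = []
    for name, target in targets.items():
        tc = _first_crossing(t, sm, target)
        if tc is None:
            warns.append(f"target {name} ({target:.3g} OD) never reached")
        times[name] = tc

    def od_at(tc: float | None) -> float | None:
        return None if tc is None else float(np.interp(tc, t, sm))

    sel = TimepointSelection(
        t_fifth=times["fifth"],
        t_half=times["half"],
        t_max=times["max"],
        od_fifth=od_at(times["fifth"]),
        od_half=od_at(times["half"]),
        od_max_reached=od_at(times["max"]),
        warnings=tuple(warns),
    )
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return sel
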