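"""Growth-rate estimators for distributed cell division counting.

Under faithful particle segregation the fraction of bright ('on') cells
halves once per generation, so the slope of log2(on-fraction) against time
is -1/tau_ON with tau_ON the population doubling time.  This module fits
that decay (in vitro and for in-vivo red/green faecal time series), applies
the alpha correction relating optical-density and particle-based doubling
times, implements the turbidostat photodiode calibration chain
(% transmittance -> raw OD -> origin-forced quadratic calibration ->
log-linear fit), and estimates gut transit time from the GFP+ pulse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cytometry import on_fraction as _on_fraction_ci

__all__ = [
    "OnFractionSeries",
    "GrowthFit",
    "ODCalibration",
    "AlphaCorrection",
    "fit_on_fraction_decay",
    "fit_red_green",
    "alpha_correction",
    "percent_transmittance",
    "raw_od_from_transmittance",
    "calibrated_od",
    "fit_quadratic_calibration",
    "generation_time_from_od",
    "generation_times_from_trace",
    "median_transit_time",
    "fold_spread_per_slowest_generation",
]

LN2 = math.log(2.0)


class EstimationError(RuntimeError):
    """A fit could not produce a meaningful estimate."""


@dataclass
class OnFractionSeries:
    """Timestamped on/off counts; the estimator input everywhere.

    For in-vivo red/green data, ``n_on`` is the count of RFP+ & GFP+ events
    and ``n_total`` the count of GFP+ events.
    """

    time_h: np.ndarray
    n_on: np.ndarray
    n_total: np.ndarray
    source: str = "in_vitro"

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.n_on = np.asarray(self.n_on, dtype=np.int64)
        self.n_total = np.asarray(self.n_total, dtype=np.int64)
        if not (len(self.time_h) == len(self.n_on) == len(self.n_total)):
            raise ValueError("column length mismatch")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.n_on < 0) or np.any(self.n_on > self.n_total):
            raise ValueError("need 0 <= n_on <= n_total at every point")
        if np.any(self.n_total < 1):
            raise ValueError("n_total must be >= 1 at every point")

    def __len__(self) -> int:
        return len(self.time_h)

    @property
    def fraction(self) -> np.ndarray:
        return self.n_on / self.n_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.time_h, "n_on": self.n_on, "n_total": self.n_total}
        )


@dataclass(frozen=True)
class GrowthFit:
    """OLS fit of log2(on-fraction) vs time."""

    slope: float  # log2 units per hour (negative for decay)
    doubling_time: float  # tau_ON, hours
    stderr: float  # standard error of the slope
    r_squared: float
    window: tuple[int, int]  # [first, last] point indices used (inclusive)
    n_points: int


@dataclass(frozen=True)
class ODCalibration:
    """Origin-forced quadratic mapping raw device OD to reference OD.

    reference_od = C1 * raw + C2 * raw**2; the curve passes through the
    origin by construction.  ``blank`` is the raw photodiode reading of a
    cell-free blank (the 100%-transmittance reference).
    """

    c1: float
    c2: float
    blank: float = 1.0


@dataclass(frozen=True)
class AlphaCorrection:
    """Spurious-production correction: alpha + 1/tau_ON = 1/tau_OD."""

    alpha: float  # h^-1
    tau_od: float  # hours
    tau_on: float  # hours


def fit_on_fraction_decay(
    series: OnFractionSeries,
    exclude_lag: int = 2,
    min_on_events: int = 10,
    floor: Optional[float] = 1e-3,
) -> GrowthFit:
    """Doubling time from the log2 decay of the on-fraction.

    Ordinary least squares on (time, log2(n_on/n_total)) after excluding
    the first ``exclude_lag`` points (cells take one or two generations to
    adapt to fresh conditions), points with fewer than ``min_on_events``
    on-counts, and points whose Wilson 95% lower bound overlaps the
    false-production ``floor`` (the decay flattens near the floor, biasing
    the slope).  Set ``exclude_lag=0`` and ``floor=None`` to fit all points.
    """
    usable = np.ones(len(series), dtype=bool)
    usable[: min(exclude_lag, len(series))] = False
    zero = series.n_on == 0
    if np.any(zero & usable):
        warnings.warn(
            f"excluding {int(np.count_nonzero(zero & usable))} points with "
            "zero on-counts",
            RuntimeWarning,
        )
    usable &= ~zero
    usable &= series.n_on >= min_on_events
    if floor is not None:
        for i in np.nonzero(usable)[0]:
            _, (lo, _) = _on_fraction_ci(
                int(series.n_on[i]), int(series.n_total[i])
            )
            if lo <= floor:
                usable[i] = False
    idx = np.nonzero(usable)[0]
    if len(idx) < 3:
        raise ValueError(
            f"only {len(idx)} usable points after exclusions; need >= 3"
        )
    t = series.time_h[idx]
    y = np.log2(series.fraction[idx])
    res = stats.linregress(t, y)
    # require a statistically meaningful decay, not just a negative point
    # estimate: a flat series with counting noise scatters around zero
    if res.slope >= 0 or res.slope + 2.0 * res.stderr >= 0:
        raise EstimationError(
            f"no decay detected: fitted slope {res.slope:.4g} "
            f"(se {res.stderr:.2g}) is not significantly negative"
        )
    return GrowthFit(
        slope=float(res.slope),
        doubling_time=-1.0 / float(res.slope),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        window=(int(idx[0]), int(idx[-1])),
        n_points=len(idx),
    )


def fit_red_green(
    series_by_mouse: dict[str, OnFractionSeries],
    exclude_lag: int = 0,
    min_on_events: int = 10,
    floor: Optional[float] = 1e-3,
) -> tuple[dict[str, GrowthFit], float, float]:
    """Per-mouse fits of the log2 red/green fraction, pooled across mice.

    Returns (per-mouse fits, pooled doubling time as the unweighted mean,
    its standard deviation across mice).  Mice whose series show no decay
    are dropped with a warning; if all fail, estimation fails.
    """
    fits: dict[str, GrowthFit] = {}
    for mouse, series in series_by_mouse.items():
        try:
            fits[mouse] = fit_on_fraction_decay(
                series,
                exclude_lag=exclude_lag,
                min_on_events=min_on_events,
                floor=floor,
            )
        except EstimationError as exc:
            warnings.warn(f"mouse {mouse}: {exc}", RuntimeWarning)
    if not fits:
        raise EstimationError(
            "no decay detected in any mouse; pooled estimate undefined"
        )
    taus = np.array([f.doubling_time for f in fits.values()])
    return fits, float(np.mean(taus)), float(np.std(taus, ddof=1)) if len(taus) > 1 else 0.0


def alpha_correction(tau_od: float, tau_on: float) -> AlphaCorrection:
    """Residual particle-production rate alpha = 1/tau_OD - 1/tau_ON.

    Leaky expression or splitting after washout slows the apparent
    on-fraction decay, so tau_ON exceeds tau_OD; alpha quantifies the
    discrepancy as a rate.  A negative alpha is allowed with a warning.
    """
    if tau_od <= 0 or tau_on <= 0:
        raise ValueError("doubling times must be positive")
    alpha = 1.0 / tau_od - 1.0 / tau_on
    if alpha < 0:
        warnings.warn(
            f"alpha = {alpha:.4g} h^-1 < 0: particle-based doubling time is "
            "shorter than the OD-based one",
            RuntimeWarning,
        )
    return AlphaCorrection(alpha=alpha, tau_od=tau_od, tau_on=tau_on)


def percent_transmittance(raw: float, reference: float) -> float:
    """%T = 100 * raw / reference (photodiode reading over blank)."""
    if reference <= 0:
        raise ValueError("reference reading must be > 0")
    if raw <= 0:
        raise ValueError("raw reading must be > 0")
    if raw > reference:
        warnings.warn(
            "raw reading exceeds the blank reference (%T > 100)", RuntimeWarning
        )
    return 100.0 * raw / reference


def raw_od_from_transmittance(pct_t: float, od_cap: float = 4.0) -> float:
    """Raw device OD = -log10(%T / 100), capped for near-opaque samples."""
    if pct_t <= 0:
        return od_cap
    return min(-math.log10(pct_t / 100.0), od_cap)


def calibrated_od(raw_od: float, cal: ODCalibration) -> float:
    """Spectrophotometer-equivalent OD via the origin-forced quadratic."""
    if raw_od < 0:
        raise ValueError("raw_od must be >= 0")
    od = cal.c1 * raw_od + cal.c2 * raw_od**2
    if od < 0:
        raise ValueError(
            f"calibration produced negative OD {od:.4g} at raw {raw_od:.4g}"
        )
    return od


def fit_quadratic_calibration(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Least-squares fit of y = C1*x + C2*x**2 (forced through the origin)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    design = np.column_stack([x, x**2])
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("rank-deficient design: x values do not span a curve")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def generation_time_from_od(
    od_series: Sequence[tuple[float, float]]
) -> float:
    """Generation time tau_OD = ln 2 / slope of ln(OD) vs time (hours).

    The series must lie within a single inter-dilution growth interval.
    """
    arr = np.asarray(od_series, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (time_h, OD) points")
    if np.any(arr[:, 1] <= 0):
        raise ValueError("all OD values must be > 0")
    res = stats.linregress(arr[:, 0], np.log(arr[:, 1]))
    if res.slope <= 0:
        raise EstimationError(
            f"no growth detected: ln(OD) slope {res.slope:.4g} <= 0"
        )
    return LN2 / float(res.slope)


def generation_times_from_trace(
    trace: pd.DataFrame,
    cal: ODCalibration,
    min_points: int = 3,
) -> list[float]:
    """Per-dilution generation times from a turbidostat photodiode trace.

    ``trace`` columns: time_h, raw_reading, valve_state (1 marks a dilution
    event).  Each inter-dilution segment is calibrated (raw reading ->
    %T -> raw OD -> quadratic calibration) and fitted log-linearly.
    Segments with fewer than ``min_points`` readings are skipped.
    """
    required = {"time_h", "raw_reading", "valve_state"}
    if not required.issubset(trace.columns):
        raise ValueError(f"trace must have columns {sorted(required)}")
    od = np.array(
        [
            calibrated_od(
                raw_od_from_transmittance(percent_transmittance(r, cal.blank)),
                cal,
            )
            for r in trace["raw_reading"]
        ]
    )
    t = trace["time_h"].to_numpy(dtype=float)
    # a valve row carries the post-dilution reading: it starts a new segment
    boundaries = np.nonzero(trace["valve_state"].to_numpy() != 0)[0]
    edges = [0, *boundaries, len(t)]
    out: list[float] = []
    for start, stop in zip(edges[:-1], edges[1:]):
        seg = slice(start, stop)
        if stop - start < min_points:
            continue
        out.append(generation_time_from_od(list(zip(t[seg], od[seg]))))
    if not out:
        raise EstimationError("no inter-dilution segment had enough points")
    return out


def median_transit_time(
    gfp_series: dict[str, Sequence[tuple[float, float]]]
) -> tuple[float, float, dict[str, float]]:
    """Gut transit time from the GFP+ faecal pulse, per mouse and pooled.

    Per mouse, the transit time is the sampled time at which the GFP+
    fraction peaks (the pulse first rises, then declines as gavaged cells
    wash out).  Returns (median across mice, removal rate = 1/median,
    per-mouse peak times).
    """
    peaks: dict[str, float] = {}
    for mouse, series in gfp_series.items():
        arr = np.asarray(series, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 3:
            raise ValueError(f"mouse {mouse}: need >= 3 time points")
        frac = arr[:, 1]
        if np.any(frac < 0) or np.any(frac > 1):
            raise ValueError(f"mouse {mouse}: fractions must be in [0, 1]")
        if np.all(np.diff(frac) >= 0):
            raise EstimationError(
                f"mouse {mouse}: no transit peak observed (fraction never "
                "declines)"
            )
        peaks[mouse] = float(arr[np.argmax(frac), 0])
    med = float(np.median(list(peaks.values())))
    if med <= 0:
        raise EstimationError("median peak time is not positive")
    return med, 1.0 / med, peaks


def fold_spread_per_slowest_generation(
    tau_fast: float, tau_slow: float
) -> float:
    """Population-size fold difference accrued over one slowest generation.

    In one generation of the slowest grower (``tau_slow`` hours) the
    fastest grower (``tau_fast``) doubles tau_slow/tau_fast times while the
    slowest doubles once, so the spread is 2**(tau_slow/tau_fast) / 2.
    For the 0.5-5 h doubling-time range this is 2**10 / 2**1 = 512.
    """
    if tau_fast <= 0 or tau_slow <= 0:
        raise ValueError("doubling times must be positive")
    if tau_slow < tau_fast:
        raise ValueError("tau_slow must be >= tau_fast")
    return 2.0 ** (tau_slow / tau_fast) / 2.0
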