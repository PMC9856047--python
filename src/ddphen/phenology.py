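"""Seasonal activity curves and phenology metrics from trap captures.

Adult activity over a breeding year is observed as counts aggregated over
trap-emptying intervals of unequal length.  A penalized-spline Poisson
regression (a GAM with a single smooth of season day, interval length as
multiplicative exposure) turns these into a smooth daily capture-rate
curve; the onset, peak and end of the activity season are then the days at
which the cumulative area under that curve reaches 10%, 50% and 90% of the
season total.

Years are excluded when flies were present in fewer than two distinct ISO
weeks, when no captures occurred, when the trap was closed, or when the
fitted curve is clearly bimodal (suggesting a second generation, which the
unimodal metric definitions do not describe).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

EXCLUSION_REASONS = ("none", "too_few_weeks", "bimodal", "no_captures",
                     "trap_closed")


class UnfittableSeasonError(ValueError):
    """Too few informative intervals to fit an activity curve."""


@dataclass
class CaptureSeries:
    """Trap counts for one breeding year, aggregated per emptying interval.

    Intervals are [start, end) with trap-day exposure equal to their length
    in days; they must be ordered and non-overlapping.  ``trap_closed``
    marks years with no trap operation, distinct from a year of genuine
    zero captures.
    """

    season: int
    data: pd.DataFrame
    trap_closed: bool = False

    def __post_init__(self) -> None:
        df = self.data.copy()
        if self.trap_closed and len(df) == 0:
            self.data = df
            return
        df["interval_start"] = pd.to_datetime(df["interval_start"])
        df["interval_end"] = pd.to_datetime(df["interval_end"])
        lengths = (df["interval_end"] - df["interval_start"]).dt.total_seconds() / 86400.0
        if (lengths <= 0).any():
            raise ValueError("zero- or negative-length interval")
        if not df["interval_start"].is_monotonic_increasing:
            raise ValueError("intervals must be ordered by start date")
        if (df["interval_start"].iloc[1:].to_numpy()
                < df["interval_end"].iloc[:-1].to_numpy()).any():
            raise ValueError("overlapping intervals")
        counts = df["count"].to_numpy()
        if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        df["count"] = counts.astype(int)
        df["trap_days"] = lengths
        self.data = df.reset_index(drop=True)

    @property
    def start_date(self) -> dt.date:
        return self.data["interval_start"].iloc[0].date()

    def midpoint_days(self, origin: Optional[dt.date] = None) -> np.ndarray:
        """Interval midpoints as fractional days from ``origin`` (default:
        first interval start)."""
        origin = pd.Timestamp(origin or self.start_date)
        mid = (self.data["interval_start"]
               + (self.data["interval_end"] - self.data["interval_start"]) / 2)
        return ((mid - origin).dt.total_seconds() / 86400.0).to_numpy()


def rate_per_trap_day(series: CaptureSeries) -> pd.DataFrame:
    """Empirical capture rate per trap day at each interval midpoint."""
    df = series.data
    return pd.DataFrame({
        "midpoint_day": series.midpoint_days(),
        "rate": df["count"].to_numpy(float) / df["trap_days"].to_numpy(float),
    })


@dataclass
class ActivityCurve:
    """Fitted daily activity curve for one breeding year.

    ``grid_days`` are integer days from the season origin; ``rate`` is the
    fitted captures per trap day (non-negative by the log link).
    """

    season: int
    grid_days: np.ndarray
    rate: np.ndarray
    origin: dt.date
    edf: float
    deviance_explained: float
    alpha: float

    def __post_init__(self) -> None:
        if np.any(self.rate < 0):
            raise ValueError("fitted rates must be non-negative")


# penalty-weight grid for the Poisson smooth; spans near-unpenalized to
# effectively-constant fits (an explicit intercept keeps the heavy-penalty
# limit at the mean rate rather than at rate 1)
_ALPHA_GRID = np.logspace(-2, 8, 21)


def fit_activity_curve(series: CaptureSeries, *,
                       max_basis_df: int = 10,
                       min_nonzero_intervals: int = 4,
                       origin: Optional[dt.date] = None) -> ActivityCurve:
    """Fit the penalized Poisson smooth of counts over season days.

    Interval length (trap days) enters as multiplicative exposure so that
    unequal emptying schedules do not bias the curve.  The basis dimension
    is capped at ``min(max_basis_df, n_intervals - 1)`` and the penalty
    weight chosen by AIC over a fixed grid.
    """
    if series.trap_closed:
        raise UnfittableSeasonError(f"season {series.season}: trap closed")
    df = series.data
    n_nonzero = int((df["count"] > 0).sum())
    if n_nonzero < min_nonzero_intervals:
        raise UnfittableSeasonError(
            f"season {series.season}: only {n_nonzero} non-zero intervals "
            f"(need {min_nonzero_intervals})")

    origin = origin or series.start_date
    x = series.midpoint_days(origin)
    counts = df["count"].to_numpy(int)
    exposure = df["trap_days"].to_numpy(float)

    span_lo = float((df["interval_start"].iloc[0] - pd.Timestamp(origin))
                    .total_seconds() / 86400.0)
    span_hi = float((df["interval_end"].iloc[-1] - pd.Timestamp(origin))
                    .total_seconds() / 86400.0)
    basis_df = max(4, min(max_basis_df, len(df) - 1))
    smoother = BSplines(x, df=[basis_df], degree=[3],
                        knot_kwds=[{"lower_bound": span_lo, "upper_bound": span_hi}])

    intercept = np.ones((len(counts), 1))
    best = None
    for alpha in _ALPHA_GRID:
        model = GLMGam(counts, exog=intercept, smoother=smoother, alpha=alpha,
                       family=sm.families.Poisson(), exposure=exposure)
        try:
            # extreme penalties transiently produce 0/0 in the IRLS weights;
            # those fits either recover or are discarded by the AIC check
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore", RuntimeWarning)
                res = model.fit()
        except (np.linalg.LinAlgError, ValueError):
            continue
        if not np.isfinite(res.aic):
            continue
        if best is None or res.aic < best[0]:
            best = (res.aic, alpha, res)
    if best is None:
        raise UnfittableSeasonError(f"season {series.season}: smooth fit failed")
    _, alpha, res = best

    grid = np.arange(np.ceil(span_lo), np.floor(span_hi) + 1)
    rate = np.asarray(res.predict(exog=np.ones((len(grid), 1)), exog_smooth=grid,
                                  exposure=np.ones(len(grid))))
    null_dev = sm.GLM(counts, np.ones_like(counts, dtype=float),
                      family=sm.families.Poisson(), exposure=exposure).fit().deviance
    dev_expl = 1.0 - res.deviance / null_dev if null_dev > 0 else 1.0
    return ActivityCurve(season=series.season, grid_days=grid, rate=rate,
                         origin=origin, edf=float(np.sum(res.edf)),
                         deviance_explained=float(dev_expl), alpha=float(alpha))


@dataclass
class PhenologyMetrics:
    """Onset/peak/end of one activity season, with inclusion status.

    Days count from the curve origin; dates are the corresponding calendar
    days.  ``included=False`` rows keep their exclusion reason and carry no
    metric values.
    """

    season: int
    onset_day: Optional[float] = None
    peak_day: Optional[float] = None
    end_day: Optional[float] = None
    onset_date: Optional[dt.date] = None
    peak_date: Optional[dt.date] = None
    end_date: Optional[dt.date] = None
    included: bool = True
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.included and None not in (self.onset_day, self.peak_day, self.end_day):
            if not self.onset_day <= self.peak_day <= self.end_day:
                raise ValueError("metrics must satisfy onset <= peak <= end")


def auc_quantile_days(curve: ActivityCurve,
                      fractions: Sequence[float] = (0.10, 0.50, 0.90)
                      ) -> PhenologyMetrics:
    """Days at which the cumulative area under the curve crosses ``fractions``.

    The crossing is the first grid day at or above each fraction of the
    total area (daily summation, no sub-day interpolation).
    """
    if list(fractions) != sorted(fractions) or not all(0 < f < 1 for f in fractions):
        raise ValueError("fractions must be increasing and in (0, 1)")
    cum = np.cumsum(curve.rate)
    total = cum[-1]
    if total <= 0:
        raise ValueError(f"season {curve.season}: zero total area under the curve")
    days = [float(curve.grid_days[int(np.argmax(cum / total >= q))])
            for q in fractions]
    dates = [curve.origin + dt.timedelta(days=d) for d in days]
    return PhenologyMetrics(season=curve.season,
                            onset_day=days[0], peak_day=days[1], end_day=days[2],
                            onset_date=dates[0], peak_date=dates[1],
                            end_date=dates[2])


def _local_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict-or-plateau local maxima of a 1-d array."""
    idx = []
    n = len(y)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left = y[i - 1] if i > 0 else -np.inf
        right = y[j + 1] if j + 1 < n else -np.inf
        if y[i] > left and y[i] > right:
            idx.append(i + (j - i) // 2)
        i = j + 1
    return idx


def is_bimodal(curve: ActivityCurve, *, rel_height: float = 0.10,
               trough_frac: float = 0.50) -> bool:
    """Detect a clearly two-peaked activity curve.

    True when at least two local maxima each exceed ``rel_height`` of the
    global maximum and some pair of them is separated by a trough below
    ``trough_frac`` of the smaller of the two peaks.  This automates what is
    in practice a visual judgement, so both thresholds are configurable and
    the flag can be overridden by the caller.
    """
    y = curve.rate
    peaks = [i for i in _local_maxima(y) if y[i] >= rel_height * y.max()]
    for a in range(len(peaks)):
        for b in range(a + 1, len(peaks)):
            i, j = peaks[a], peaks[b]
            trough = y[i:j + 1].min()
            if trough < trough_frac * min(y[i], y[j]):
                return True
    return False


def year_inclusion(series: CaptureSeries,
                   curve: Optional[ActivityCurve] = None, *,
                   min_weeks: int = 2,
                   rel_height: float = 0.10,
                   trough_frac: float = 0.50) -> tuple[bool, str]:
    """Apply the year-inclusion rules; returns (included, exclusion_reason).

    A year is excluded when the trap was closed, when there were no
    captures, when non-zero counts fall in fewer than ``min_weeks`` distinct
    ISO weeks, or when the fitted curve (if supplied) is clearly bimodal.
    """
    if series.trap_closed:
        return False, "trap_closed"
    df = series.data
    nonzero = df[df["count"] > 0]
    if len(nonzero) == 0:
        return False, "no_captures"
    mid = (nonzero["interval_start"]
           + (nonzero["interval_end"] - nonzero["interval_start"]) / 2)
    iso = mid.dt.isocalendar()
    weeks = set(zip(iso["year"], iso["week"]))
    if len(weeks) < min_weeks:
        return False, "too_few_weeks"
    if curve is not None and is_bimodal(curve, rel_height=rel_height,
                                        trough_frac=trough_frac):
        return False, "bimodal"
    return True, "none"


def season_metrics(series: CaptureSeries, *,
                   fractions: Sequence[float] = (0.10, 0.50, 0.90),
                   min_weeks: int = 2) -> PhenologyMetrics:
    """Fit, check inclusion and extract metrics for one season.

    Excluded or unfittable seasons come back as a metrics row with
    ``included=False`` and the reason set, never as a missing row.
    """
    included, reason = year_inclusion(series)
    if not included:
        return PhenologyMetrics(season=series.season, included=False,
                                exclusion_reason=reason)
    try:
        curve = fit_activity_curve(series)
    except UnfittableSeasonError:
        return PhenologyMetrics(season=series.season, included=False,
                                exclusion_reason="too_few_weeks")
    included, reason = year_inclusion(series, curve, min_weeks=min_weeks)
    if not included:
        return PhenologyMetrics(season=series.season, included=False,
                                exclusion_reason=reason)
    return auc_quantile_days(curve, fractions)
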