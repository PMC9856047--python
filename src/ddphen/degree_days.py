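"""Thresholded degree-day accumulation over southern-hemisphere breeding seasons.

The daily degree-day contribution is ``max(0, min(T, t_max) - t_min)`` using
the daily mean temperature (no sub-daily sine interpolation); hourly records
contribute the same quantity divided by 24.  Seasons run from a fixed
day-of-year in austral mid-winter (default day 200) to the end of February
of the following calendar year and are labelled by their starting year.

Adult emergence is predicted as the first day of the season on which the
cumulative degree days reach the egg-to-adult requirement.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .thermal import ThermalThresholds


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


@dataclass
class TemperatureSeries:
    """Dated mean air temperatures at daily or hourly resolution.

    ``data`` has columns ``date`` (datetime64), ``temp_c`` and, for hourly
    series, ``hour`` (0-23).  Timestamps must be strictly increasing with at
    most one record per resolution unit.
    """

    data: pd.DataFrame
    resolution: str = "daily"  # "daily" | "hourly"
    station: str = ""

    def __post_init__(self) -> None:
        if self.resolution not in ("daily", "hourly"):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        df = self.data.copy()
        df["date"] = pd.to_datetime(df["date"])
        if not np.isfinite(df["temp_c"].to_numpy(float)).all():
            raise ValueError("temperatures must be finite")
        if self.resolution == "hourly":
            if "hour" not in df.columns:
                raise ValueError("hourly series needs an 'hour' column")
            ts = df["date"] + pd.to_timedelta(df["hour"], unit="h")
        else:
            ts = df["date"]
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing and unique")
        self.data = df.reset_index(drop=True)

    def daily_dd(self, thresholds: ThermalThresholds) -> pd.Series:
        """Degree days contributed per calendar day, indexed by date."""
        contrib = unit_dd(self.data["temp_c"].to_numpy(float), thresholds)
        if self.resolution == "hourly":
            contrib = contrib / 24.0
        return pd.Series(contrib, index=self.data["date"].dt.normalize()).groupby(level=0).sum()

    def daily_mean(self) -> pd.Series:
        """Daily mean temperature, indexed by date."""
        return (self.data.set_index(self.data["date"].dt.normalize())["temp_c"]
                .groupby(level=0).mean())


def unit_dd(temperature, thresholds: ThermalThresholds):
    """Degree days per day at a given daily-mean temperature (vectorized).

    ``max(0, min(T, t_max) - t_min)``: zero below the lower threshold,
    capped horizontally at the upper threshold.
    """
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    out = np.clip(np.minimum(t, thresholds.t_max) - thresholds.t_min, 0.0, None)
    return float(out) if np.isscalar(temperature) else out


@dataclass(frozen=True)
class BreedingSeasonWindow:
    """Accumulation window: day-of-year ``start_doy`` to a season-end rule.

    The default (start day 200, end of February of the following year) is
    the austral breeding season; the window deliberately spans the calendar
    year boundary.  ``start_doy`` is a calendar day-of-year in both leap and
    non-leap years, and "end of February" is leap-aware (Feb 28 or 29).
    """

    start_doy: int = 200
    end_rule: str = "end_of_february"  # or "fixed_doy"
    end_doy: Optional[int] = None      # used when end_rule == "fixed_doy"

    def __post_init__(self) -> None:
        if not 1 <= self.start_doy <= 365:
            raise ValueError("start_doy must be in 1..365")
        if self.end_rule not in ("end_of_february", "fixed_doy"):
            raise ValueError(f"unknown end_rule {self.end_rule!r}")
        if self.end_rule == "fixed_doy" and self.end_doy is None:
            raise ValueError("fixed_doy end rule needs end_doy")

    def start_date(self, year: int) -> dt.date:
        return dt.date(year, 1, 1) + dt.timedelta(days=self.start_doy - 1)

    def end_date(self, year: int) -> dt.date:
        """Inclusive end date of the season labelled by starting year."""
        if self.end_rule == "end_of_february":
            nxt = year + 1
            last = 29 if (nxt % 4 == 0 and (nxt % 100 != 0 or nxt % 400 == 0)) else 28
            return dt.date(nxt, 2, last)
        end = dt.date(year + 1, 1, 1) + dt.timedelta(days=self.end_doy - 1)
        return end


@dataclass
class SeasonDDResult:
    """Degree-day outcome for one breeding season (labelled by start year)."""

    season: int
    total_dd: Optional[float]
    complete: bool
    cumulative: Optional[pd.Series] = field(default=None, repr=False)
    emergence_date: Optional[dt.date] = None
    emergence_doy_from_start: Optional[int] = None


def _season_daily_dd(series: TemperatureSeries, window: BreedingSeasonWindow,
                     thresholds: ThermalThresholds, year: int,
                     max_gap_days: int) -> Optional[pd.Series]:
    """Daily DD over one season, gap-filled, or None if unfillable."""
    start = pd.Timestamp(window.start_date(year))
    end = pd.Timestamp(window.end_date(year))
    idx = pd.date_range(start, end, freq="D")
    if series.resolution == "daily":
        temp = series.daily_mean().reindex(idx)
        filled = temp.interpolate(method="linear", limit=max_gap_days,
                                  limit_area="inside")
        if filled.isna().any():
            return None
        return pd.Series(unit_dd(filled.to_numpy(), thresholds), index=idx)
    # hourly: per-day DD from the hourly clip; whole missing days are
    # bridged by interpolating the daily DD totals across the gap
    daily = series.daily_dd(thresholds).reindex(idx)
    filled = daily.interpolate(method="linear", limit=max_gap_days,
                               limit_area="inside")
    if filled.isna().any():
        return None
    return filled


def accumulate_season(series: TemperatureSeries, window: BreedingSeasonWindow,
                      thresholds: ThermalThresholds, *,
                      max_gap_days: int = 7,
                      years: Optional[Iterable[int]] = None) -> list[SeasonDDResult]:
    """Accumulate degree days for every breeding season the series covers.

    Seasons whose window is not fully bridgeable (a gap longer than
    ``max_gap_days``, or a window extending past the record) are reported
    with ``complete=False`` and no total, never silently dropped.
    """
    dates = pd.to_datetime(series.data["date"])
    first, last = dates.min(), dates.max()
    if years is None:
        years = range(first.year, last.year + 1)
    results: list[SeasonDDResult] = []
    for year in years:
        start = pd.Timestamp(window.start_date(year))
        end = pd.Timestamp(window.end_date(year))
        if start < first or end > last:
            results.append(SeasonDDResult(season=year, total_dd=None, complete=False))
            continue
        daily = _season_daily_dd(series, window, thresholds, year, max_gap_days)
        if daily is None:
            results.append(SeasonDDResult(season=year, total_dd=None, complete=False))
            continue
        cum = daily.cumsum()
        res = SeasonDDResult(season=year, total_dd=float(cum.iloc[-1]),
                             complete=True, cumulative=cum)
        emergence_day(res, thresholds.dd_req)
        results.append(res)
    return results


def emergence_day(result: SeasonDDResult, dd_req: float) -> Optional[dt.date]:
    """First day whose cumulative DD reaches ``dd_req``; None if never.

    Fills ``emergence_date`` and ``emergence_doy_from_start`` on the result
    (0 = the season's first day) and returns the date.
    """
    if result.cumulative is None:
        raise ValueError("no cumulative trace available for emergence search")
    cum = result.cumulative
    reached = cum.to_numpy() >= dd_req
    if not reached.any():
        result.emergence_date = None
        result.emergence_doy_from_start = None
        return None
    i = int(np.argmax(reached))
    result.emergence_date = cum.index[i].date()
    result.emergence_doy_from_start = i
    return result.emergence_date


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def ttest_pooled(a: Sequence[float], b: Sequence[float], *,
                 welch: bool = False) -> TTestResult:
    """Two-sample t-test of ``a`` minus ``b`` (pooled variance by default)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    res = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


def pre_post_ttest(season_totals: dict[int, float] | pd.Series, split_year: int,
                   *, welch: bool = False) -> TTestResult:
    """Compare seasonal DD totals after vs before a split year.

    Seasons starting in ``split_year`` or later form the "post" group; the
    statistic is post minus pre, so a warming-driven increase gives t > 0.
    Student's pooled-variance test by default (df = n1 + n2 - 2); Welch
    available behind the flag.
    """
    s = pd.Series(season_totals).dropna()
    pre = s[s.index < split_year].to_numpy(float)
    post = s[s.index >= split_year].to_numpy(float)
    if len(pre) < 2 or len(post) < 2:
        raise InsufficientDataError(
            f"need >=2 seasons on each side of {split_year} "
            f"(got {len(pre)} pre, {len(post)} post)")
    return ttest_pooled(post, pre, welch=welch)
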