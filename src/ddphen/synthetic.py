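"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (degree-day accumulation, phenology
extraction, trend statistics) is testable without external downloads via
three generators:

* :func:`gen_temperature` — a daily air-temperature series with a sinusoidal
  seasonal cycle, a linear warming trend and AR(1) daily noise, emulating a
  multi-decadal sub-Antarctic station record.
* :func:`gen_rearing_table` — constant-temperature rearing durations derived
  by inverting the linear degree-day model from known stage requirements.
* :func:`gen_captures` — interval-aggregated Poisson trap counts drawn from
  a Gaussian-mixture seasonal activity rate, with the analytic 10/50/90%
  activity quantiles returned alongside as ground truth.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .degree_days import TemperatureSeries
from .phenology import CaptureSeries
from .thermal import STAGES, DevelopmentUndefinedError, StageDurationTable, \
    StageRow, ThermalThresholds


@dataclass(frozen=True)
class TemperatureScenario:
    """Parameters of a synthetic multi-year daily temperature series.

    The daily mean is
    ``mean_temp + warming_rate * years_elapsed - seasonal_amplitude * cos(phase)
    + AR(1) noise``, with the phase anchored so the coldest day falls on
    day-of-year 200 (austral mid-winter) for ``hemisphere="south"`` and in
    mid-January for ``"north"``.  ``noise_sd`` is the stationary standard
    deviation of the AR(1) daily residual.
    """

    n_years: int = 70
    start_year: int = 1951
    mean_temp: float = 4.5
    seasonal_amplitude: float = 3.0
    warming_rate: float = 0.0
    noise_sd: float = 1.5
    ar1_coef: float = 0.6
    hemisphere: str = "south"
    seed: int = 0

    def __post_init__(self) -> None:
        vals = (self.mean_temp, self.seasonal_amplitude, self.warming_rate,
                self.noise_sd, self.ar1_coef)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("scenario parameters must be finite")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.hemisphere not in ("south", "north"):
            raise ValueError("hemisphere must be 'south' or 'north'")


# coldest day-of-year by hemisphere: austral mid-winter day 200, or boreal
# mid-January (day 15)
_COLD_DOY = {"south": 200, "north": 15}


def gen_temperature(scenario: TemperatureScenario) -> TemperatureSeries:
    """Generate a daily temperature series, one record per calendar day."""
    start = dt.date(scenario.start_year, 1, 1)
    end = dt.date(scenario.start_year + scenario.n_years - 1, 12, 31)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy(float)
    days_in_year = np.where(dates.is_leap_year, 366.0, 365.0)
    phase = 2 * np.pi * (doy - _COLD_DOY[scenario.hemisphere]) / days_in_year
    seasonal = -scenario.seasonal_amplitude * np.cos(phase)
    years_elapsed = (dates - dates[0]).days.to_numpy(float) / 365.25
    mean = scenario.mean_temp + scenario.warming_rate * years_elapsed + seasonal

    rng = np.random.default_rng(scenario.seed)
    n = len(dates)
    if scenario.noise_sd > 0:
        z = rng.standard_normal(n)
        eps = np.empty(n)
        phi = scenario.ar1_coef
        eps[0] = scenario.noise_sd * z[0]
        innov_sd = scenario.noise_sd * np.sqrt(1 - phi ** 2)
        for i in range(1, n):
            eps[i] = phi * eps[i - 1] + innov_sd * z[i]
    else:
        eps = np.zeros(n)

    df = pd.DataFrame({"date": dates, "temp_c": mean + eps})
    return TemperatureSeries(data=df, resolution="daily", station="synthetic")


def gen_rearing_table(thresholds: ThermalThresholds,
                      stage_dd: Sequence[float],
                      temps: Sequence[float],
                      noise_cv: float = 0.0,
                      seed: int = 0) -> StageDurationTable:
    """Invert the degree-day model into a constant-temperature rearing table.

    ``stage_dd`` gives the cumulative degree-day requirement of each of the
    six stages (strictly increasing).  Days to each stage at temperature T
    are ``stage_dd / (min(T, t_max) - t_min)``; multiplicative lognormal
    noise with coefficient of variation ``noise_cv`` is applied to the
    inter-stage increments (not the cumulative days) so the generated
    durations stay positive and non-decreasing across stages.  With
    ``noise_cv=0`` the inversion is exact.
    """
    stage_dd = np.asarray(stage_dd, float)
    if len(stage_dd) != len(STAGES):
        raise ValueError(f"stage_dd needs {len(STAGES)} values")
    if not np.all(np.diff(stage_dd) > 0) or stage_dd[0] <= 0:
        raise ValueError("stage_dd must be positive and strictly increasing")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    for t in temps:
        if t <= thresholds.t_min:
            raise DevelopmentUndefinedError(
                f"rearing at {t} degC is at/below the {thresholds.t_min} degC "
                "threshold: development undefined")

    rng = np.random.default_rng(seed)
    # lognormal multipliers with mean 1 and sd = noise_cv
    if noise_cv > 0:
        sigma2 = math.log(1 + noise_cv ** 2)
        mu = -sigma2 / 2

    rows = []
    increments_dd = np.diff(np.concatenate([[0.0], stage_dd]))
    for t in temps:
        k = min(t, thresholds.t_max) - thresholds.t_min
        inc_days = increments_dd / k
        if noise_cv > 0:
            inc_days = inc_days * rng.lognormal(mu, math.sqrt(sigma2), len(inc_days))
        days = np.cumsum(inc_days)
        rows.append(StageRow(temperature=float(t),
                             days=dict(zip(STAGES, days.tolist()))))
    return StageDurationTable(rows=rows)


@dataclass(frozen=True)
class ActivityScenario:
    """Seasonal adult-activity scenario for the trap-count generator.

    The activity rate over the season is a mixture of Gaussians in
    days-from-season-start; trap counts per collection interval are Poisson
    with mean proportional to the exact integral of the rate over the
    interval, normalised so the expected season total is
    ``total_expected``.  ``trap_interval_days`` is either a single interval
    length or a mapping from calendar month to length (emulating emptying
    every five days in the warm months and every seven to ten otherwise).
    """

    season_start_doy: int = 200
    season_length_days: int = 320
    peak_offsets: tuple[float, ...] = (150.0,)
    peak_widths: tuple[float, ...] = (15.0,)
    mode_weights: tuple[float, ...] = (1.0,)
    total_expected: float = 500.0
    trap_interval_days: int | dict[int, int] = 5
    year: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.peak_offsets)
        if not (len(self.peak_widths) == len(self.mode_weights) == k):
            raise ValueError("peak_offsets, peak_widths, mode_weights must align")
        if abs(sum(self.mode_weights) - 1.0) > 1e-9:
            raise ValueError("mode_weights must sum to 1")
        if any(w <= 0 for w in self.peak_widths):
            raise ValueError("peak_widths must be positive")
        if self.total_expected <= 0 or self.season_length_days < 1:
            raise ValueError("total_expected and season_length_days must be positive")


@dataclass(frozen=True)
class ActivityTruth:
    """Analytic ground truth of an activity scenario.

    ``onset/peak/end`` are the 10/50/90% quantiles (days from season start)
    of the Gaussian-mixture rate restricted to the season window.  They
    describe the generating rate itself and are therefore independent of the
    trap-emptying schedule.
    """

    onset_day: float
    peak_day: float
    end_day: float
    scenario: ActivityScenario = field(repr=False, default=None)


def _mixture_cdf(x, scenario: ActivityScenario):
    c = np.zeros_like(np.asarray(x, float))
    for w, m, s in zip(scenario.mode_weights, scenario.peak_offsets,
                       scenario.peak_widths):
        c = c + w * stats.norm.cdf(x, m, s)
    return c


def activity_truth(scenario: ActivityScenario,
                   fractions=(0.10, 0.50, 0.90)) -> ActivityTruth:
    """Analytic AUC quantiles of the season-restricted activity rate."""
    L = scenario.season_length_days
    lo, hi = _mixture_cdf(0.0, scenario), _mixture_cdf(float(L), scenario)
    days = []
    for q in fractions:
        target = lo + q * (hi - lo)
        d = optimize.brentq(lambda x: _mixture_cdf(x, scenario) - target, 0.0, L)
        days.append(float(d))
    return ActivityTruth(onset_day=days[0], peak_day=days[1], end_day=days[2],
                         scenario=scenario)


def _interval_edges(scenario: ActivityScenario, start_date: dt.date) -> np.ndarray:
    """Collection-day offsets tiling [0, season_length] without gaps."""
    edges = [0]
    while edges[-1] < scenario.season_length_days:
        if isinstance(scenario.trap_interval_days, dict):
            month = (start_date + dt.timedelta(days=edges[-1])).month
            step = scenario.trap_interval_days.get(month, 7)
        else:
            step = scenario.trap_interval_days
        edges.append(min(edges[-1] + int(step), scenario.season_length_days))
    return np.asarray(edges, float)


def gen_captures(scenario: ActivityScenario) -> tuple[CaptureSeries, ActivityTruth]:
    """Sample one season of interval-aggregated Poisson trap counts.

    Expected interval counts are exact integrals of the mixture rate
    (differences of normal CDFs), normalised to sum to ``total_expected``
    over the season before Poisson sampling.
    """
    start_date = (dt.date(scenario.year, 1, 1)
                  + dt.timedelta(days=scenario.season_start_doy - 1))
    edges = _interval_edges(scenario, start_date)
    cdf = _mixture_cdf(edges, scenario)
    mass = np.diff(cdf)
    total_mass = cdf[-1] - cdf[0]
    expected = scenario.total_expected * mass / total_mass

    rng = np.random.default_rng(scenario.seed)
    counts = rng.poisson(expected)

    starts = [start_date + dt.timedelta(days=int(e)) for e in edges[:-1]]
    ends = [start_date + dt.timedelta(days=int(e)) for e in edges[1:]]
    df = pd.DataFrame({
        "interval_start": pd.to_datetime(starts),
        "interval_end": pd.to_datetime(ends),
        "count": counts.astype(int),
    })
    series = CaptureSeries(season=scenario.year, data=df)
    return series, activity_truth(scenario)
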