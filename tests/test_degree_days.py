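"""Seasonal degree-day accumulation, emergence prediction, pre/post t-test."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from ddphen import (BreedingSeasonWindow, TemperatureSeries, ThermalThresholds,
                    accumulate_season, pre_post_ttest, ttest_pooled, unit_dd)
from ddphen.degree_days import InsufficientDataError
from ddphen.synthetic import TemperatureScenario, gen_temperature

from conftest import constant_series


@pytest.mark.parametrize("temp, expected", [
    (8.0, 6.0),     # the worked-example rate behind the 556.8 total
    (1.0, 0.0),     # below the lower threshold: clipped at zero
    (30.0, 26.0),   # above the upper threshold: capped at 28
    (2.0, 0.0),     # exactly at threshold contributes nothing
])
def test_unit_dd(thresholds, temp, expected):
    assert unit_dd(temp, thresholds) == expected


def test_unit_dd_vectorized(thresholds):
    out = unit_dd(np.array([8.0, 1.0, 30.0]), thresholds)
    assert np.allclose(out, [6.0, 0.0, 26.0])


def test_constant_5c_totals(thresholds):
    """Constant 5 degC accumulates exactly 3 DD/day over any window."""
    assert unit_dd(5.0, thresholds) * 100 == 300.0  # 100-day window
    series = constant_series(5.0)
    res = accumulate_season(series, BreedingSeasonWindow(), thresholds)
    full = [r for r in res if r.complete]
    assert full and all(
        r.total_dd == pytest.approx(3.0 * len(r.cumulative)) for r in full)


def test_all_cold_season_no_emergence(thresholds, window):
    series = constant_series(1.0)
    res = [r for r in accumulate_season(series, window, thresholds) if r.complete]
    assert res and all(r.total_dd == 0.0 for r in res)
    assert all(r.emergence_date is None for r in res)


def test_emergence_day_brute_force(thresholds, window):
    """First day with cumulative DD >= 439 matches an explicit scan."""
    for temp, rate in [(5.0, 3.0), (28.0, 26.0)]:
        series = constant_series(temp)
        res = [r for r in accumulate_season(series, window, thresholds)
               if r.complete][0]
        cum = np.cumsum([rate] * len(res.cumulative))
        expected_idx = int(np.argmax(cum >= 439.0))
        assert res.emergence_doy_from_start == expected_idx
    # constant 5 C: day 147 of the season (index 146), i.e. calendar DOY 346
    series = constant_series(5.0)
    r = [x for x in accumulate_season(series, window, thresholds) if x.complete][0]
    assert r.emergence_doy_from_start == 146
    assert r.emergence_date.timetuple().tm_yday == 346


def test_emergence_at_28c_is_day_17(thresholds, window):
    series = constant_series(28.0)
    r = [x for x in accumulate_season(series, window, thresholds) if x.complete][0]
    # first d with 26 * d >= 439 -> d = 17 (index 16)
    assert r.emergence_doy_from_start == 16


def test_sinusoid_total_matches_quadrature(thresholds, window):
    """Season total of a noiseless sinusoid equals the clipped-cosine integral."""
    scn = TemperatureScenario(n_years=3, start_year=1999, mean_temp=4.0,
                              seasonal_amplitude=3.0, warming_rate=0.0,
                              noise_sd=0.0, seed=0)
    series = gen_temperature(scn)
    res = [r for r in accumulate_season(series, window, thresholds)
           if r.complete][0]
    # oracle: sum the generating function day by day (the accumulator sees
    # daily means, so the "integral" is the daily Riemann sum of the clipped
    # generating sinusoid)
    days = res.cumulative.index
    doy = days.dayofyear.to_numpy(float)
    diy = np.where(days.is_leap_year, 366.0, 365.0)
    t = 4.0 - 3.0 * np.cos(2 * np.pi * (doy - 200) / diy)
    expected = np.clip(np.minimum(t, 28.0) - 2.0, 0, None).sum()
    assert res.total_dd == pytest.approx(expected, abs=0.5)


def test_additivity_over_window_split(thresholds, window):
    """Summing daily DD over any split of the window equals the whole total."""
    scn = TemperatureScenario(n_years=3, start_year=1999, noise_sd=1.0, seed=5)
    series = gen_temperature(scn)
    res = [r for r in accumulate_season(series, window, thresholds)
           if r.complete][0]
    daily = np.diff(np.concatenate([[0.0], res.cumulative.to_numpy()]))
    for cut in (1, 50, 117, len(daily) - 1):
        assert daily[:cut].sum() + daily[cut:].sum() == pytest.approx(
            res.total_dd, rel=1e-12)


def test_cumulative_trace_non_decreasing(thresholds, window):
    scn = TemperatureScenario(n_years=3, start_year=1999, noise_sd=2.0, seed=6)
    series = gen_temperature(scn)
    for r in accumulate_season(series, window, thresholds):
        if r.complete:
            assert (np.diff(r.cumulative.to_numpy()) >= -1e-12).all()


def test_warming_never_delays_emergence(thresholds, window):
    """Raising any single day's temperature cannot postpone emergence."""
    rng = np.random.default_rng(7)
    dates = pd.date_range("1999-01-01", "2000-12-31", freq="D")
    base = 5.0 + rng.normal(0, 2, len(dates))
    series = TemperatureSeries(data=pd.DataFrame({"date": dates, "temp_c": base}))
    r0 = [x for x in accumulate_season(series, window, thresholds)
          if x.complete][0]
    for bump_idx in rng.integers(0, len(dates), size=20):
        temps = base.copy()
        temps[bump_idx] += 5.0
        series2 = TemperatureSeries(
            data=pd.DataFrame({"date": dates, "temp_c": temps}))
        r1 = [x for x in accumulate_season(series2, window, thresholds)
              if x.complete][0]
        if r0.emergence_doy_from_start is not None:
            assert r1.emergence_doy_from_start is not None
            assert r1.emergence_doy_from_start <= r0.emergence_doy_from_start


def test_hourly_daily_consistency(thresholds, window):
    """Hourly records equal to the daily mean accumulate identically."""
    dates = pd.date_range("1999-01-01", "2000-12-31", freq="D")
    rng = np.random.default_rng(8)
    daily_temp = 5.0 + rng.normal(0, 2, len(dates))
    daily = TemperatureSeries(
        data=pd.DataFrame({"date": dates, "temp_c": daily_temp}))
    hourly_df = pd.DataFrame({
        "date": np.repeat(dates, 24),
        "hour": np.tile(np.arange(24), len(dates)),
        "temp_c": np.repeat(daily_temp, 24),
    })
    hourly = TemperatureSeries(data=hourly_df, resolution="hourly")
    rd = [r for r in accumulate_season(daily, window, thresholds) if r.complete][0]
    rh = [r for r in accumulate_season(hourly, window, thresholds) if r.complete][0]
    assert rh.total_dd == pytest.approx(rd.total_dd, rel=1e-9)


def test_gap_policy(thresholds, window):
    """Short gaps are interpolated; long gaps flag the season incomplete."""
    dates = pd.date_range("1999-01-01", "2000-12-31", freq="D")
    df = pd.DataFrame({"date": dates, "temp_c": 5.0})
    short_gap = df[~df["date"].between("1999-09-01", "1999-09-05")]
    long_gap = df[~df["date"].between("1999-09-01", "1999-10-15")]
    ok = accumulate_season(TemperatureSeries(data=short_gap), window, thresholds)
    bad = accumulate_season(TemperatureSeries(data=long_gap), window, thresholds)
    assert [r for r in ok if r.season == 1999][0].complete
    season_bad = [r for r in bad if r.season == 1999][0]
    assert not season_bad.complete and season_bad.total_dd is None


def test_season_totals_exceed_requirement_under_mild_climate(thresholds, window):
    """Scenarios with mean >= 5 degC and 3 degC amplitude clear 439 DD."""
    scn = TemperatureScenario(n_years=5, start_year=2000, mean_temp=5.0,
                              seasonal_amplitude=3.0, noise_sd=1.5, seed=9)
    series = gen_temperature(scn)
    totals = [r.total_dd for r in accumulate_season(series, window, thresholds)
              if r.complete]
    assert totals and all(t > 439.0 for t in totals)


# ---------------------------------------------------------------------------
# t-test


def pooled_t_oracle(a, b):
    """Closed-form pooled-variance two-sample t (independent of scipy)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = (((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
           / (n1 + n2 - 2))
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2


def test_ttest_identical_groups():
    res = ttest_pooled([5, 6, 7], [5, 6, 7])
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_ttest_hand_example():
    res = ttest_pooled([1, 2, 3], [3, 4, 5])
    assert res.t == pytest.approx(-2.449, abs=5e-4)
    assert res.df == 4


def test_ttest_matches_closed_form_on_random_inputs():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        n1, n2 = rng.integers(2, 12, size=2)
        a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n1)
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n2)
        res = ttest_pooled(a, b)
        t_ref, df_ref = pooled_t_oracle(a, b)
        assert res.t == pytest.approx(t_ref, rel=1e-9)
        assert res.df == df_ref


def test_pre_post_orientation_and_split():
    """Post-split minus pre-split: an increase gives a positive t."""
    totals = {y: 300.0 for y in range(1970, 1978)}
    totals.update({y: 500.0 for y in range(1978, 1986)})
    res = pre_post_ttest(totals, 1978)
    assert res.t > 0
    assert res.df == 14


def test_pre_post_insufficient_data():
    with pytest.raises(InsufficientDataError):
        pre_post_ttest({1977: 1.0, 1978: 2.0, 1979: 3.0}, 1978)
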