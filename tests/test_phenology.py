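"""Activity-curve fitting, AUC quantile metrics and year-inclusion rules."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ddphen.phenology import (ActivityCurve, CaptureSeries, PhenologyMetrics,
                              UnfittableSeasonError, auc_quantile_days,
                              fit_activity_curve, is_bimodal,
                              rate_per_trap_day, season_metrics,
                              year_inclusion)
from ddphen.synthetic import ActivityScenario, gen_captures


def make_series(counts, interval_days=5, start="2000-07-18", season=2000):
    start = pd.Timestamp(start)
    starts = [start + pd.Timedelta(days=interval_days * i)
              for i in range(len(counts))]
    ends = [s + pd.Timedelta(days=interval_days) for s in starts]
    return CaptureSeries(season=season, data=pd.DataFrame(
        {"interval_start": starts, "interval_end": ends, "count": counts}))


def make_curve(rates, season=2000):
    return ActivityCurve(season=season, grid_days=np.arange(len(rates), dtype=float),
                         rate=np.asarray(rates, float),
                         origin=dt.date(2000, 7, 18), edf=1.0,
                         deviance_explained=1.0, alpha=1.0)


# ---------------------------------------------------------------------------
# rates


def test_rate_per_trap_day_examples():
    s = make_series([10, 0], interval_days=5)
    rates = rate_per_trap_day(s)["rate"]
    assert rates.iloc[0] == 2.0 and rates.iloc[1] == 0.0


def test_rate_respects_interval_length():
    df = pd.DataFrame({
        "interval_start": pd.to_datetime(["2000-01-01", "2000-01-06"]),
        "interval_end": pd.to_datetime(["2000-01-06", "2000-01-16"]),
        "count": [10, 10],
    })
    s = CaptureSeries(season=2000, data=df)
    assert rate_per_trap_day(s)["rate"].tolist() == [2.0, 1.0]


def test_zero_length_interval_rejected():
    df = pd.DataFrame({
        "interval_start": pd.to_datetime(["2000-01-01"]),
        "interval_end": pd.to_datetime(["2000-01-01"]),
        "count": [1],
    })
    with pytest.raises(ValueError, match="length"):
        CaptureSeries(season=2000, data=df)


def test_overlapping_intervals_rejected():
    df = pd.DataFrame({
        "interval_start": pd.to_datetime(["2000-01-01", "2000-01-04"]),
        "interval_end": pd.to_datetime(["2000-01-06", "2000-01-09"]),
        "count": [1, 1],
    })
    with pytest.raises(ValueError, match="overlap"):
        CaptureSeries(season=2000, data=df)


# ---------------------------------------------------------------------------
# curve fitting


def test_fit_recovers_gaussian_rate():
    """Fitted daily rate correlates > 0.9 with the generating rate."""
    scn = ActivityScenario(total_expected=500.0, peak_offsets=(150.0,),
                           peak_widths=(15.0,), season_length_days=300, seed=2)
    cap, _ = gen_captures(scn)
    curve = fit_activity_curve(cap)
    # grid days count from the first interval start = season start
    true = 500.0 * stats.norm.pdf(curve.grid_days, 150.0, 15.0)
    r = np.corrcoef(curve.rate, true)[0, 1]
    assert r > 0.9


def test_all_zero_counts_unfittable():
    s = make_series([0] * 20)
    with pytest.raises(UnfittableSeasonError):
        fit_activity_curve(s)


def test_constant_rate_fits_flat():
    """Equal counts at equal intervals fit within 10% of the empirical mean."""
    rng = np.random.default_rng(5)
    counts = rng.poisson(10.0, size=40)  # 2 per trap day over 5-day intervals
    s = make_series(counts.tolist())
    curve = fit_activity_curve(s)
    mle = counts.sum() / (len(counts) * 5.0)
    interior = curve.rate[5:-5]  # spline edges are unconstrained by data
    assert np.all(np.abs(interior - mle) / mle < 0.10)


def test_fitted_rates_nonnegative_and_cover_season():
    cap, _ = gen_captures(ActivityScenario(seed=6))
    curve = fit_activity_curve(cap)
    assert (curve.rate >= 0).all()
    assert np.all(np.diff(curve.grid_days) == 1.0)
    assert curve.grid_days[-1] - curve.grid_days[0] >= 300


# ---------------------------------------------------------------------------
# AUC quantiles


def test_uniform_rate_quantiles():
    curve = make_curve([1.0] * 100)
    m = auc_quantile_days(curve)
    assert (m.onset_day, m.peak_day, m.end_day) == (9.0, 49.0, 89.0)


def test_symmetric_curve_peak_at_center():
    grid = np.arange(200.0)
    curve = make_curve(stats.norm.pdf(grid, 100.0, 12.0))
    m = auc_quantile_days(curve)
    assert m.peak_day == pytest.approx(100.0, abs=1.0)


def test_stepwise_curve_matches_bruteforce_scan():
    rates = [0, 0, 4, 4, 2, 0, 0, 0]
    curve = make_curve(rates)
    m = auc_quantile_days(curve)
    cum = np.cumsum(rates) / np.sum(rates)
    for got, q in [(m.onset_day, 0.10), (m.peak_day, 0.50), (m.end_day, 0.90)]:
        expected = next(i for i, c in enumerate(cum) if c >= q)
        assert got == float(expected)


def test_quantiles_invariant_to_count_scaling():
    """Multiplying all counts by a constant leaves the metrics unchanged."""
    scn = ActivityScenario(seed=8)
    cap, _ = gen_captures(scn)
    m1 = auc_quantile_days(fit_activity_curve(cap))
    scaled = CaptureSeries(season=cap.season, data=cap.data.assign(
        count=cap.data["count"] * 3)[["interval_start", "interval_end", "count"]])
    m2 = auc_quantile_days(fit_activity_curve(scaled))
    for a, b in [(m1.onset_day, m2.onset_day), (m1.peak_day, m2.peak_day),
                 (m1.end_day, m2.end_day)]:
        assert abs(a - b) <= 1.0


def test_zero_area_curve_rejected():
    with pytest.raises(ValueError, match="zero total area"):
        auc_quantile_days(make_curve([0.0] * 10))


def test_metric_ordering_enforced():
    with pytest.raises(ValueError, match="onset <= peak <= end"):
        PhenologyMetrics(season=2000, onset_day=50.0, peak_day=40.0,
                         end_day=60.0)


# ---------------------------------------------------------------------------
# inclusion rules


def test_single_week_excluded():
    # 2000-07-17 is a Monday; the non-zero intervals' midpoints fall on the
    # Wednesday and Thursday of that same ISO week
    s = make_series([0, 0, 5, 3, 0, 0], interval_days=1, start="2000-07-17")
    included, reason = year_inclusion(s)
    assert not included and reason == "too_few_weeks"


def test_no_captures_excluded():
    s = make_series([0] * 10)
    included, reason = year_inclusion(s)
    assert not included and reason == "no_captures"


def test_trap_closed_distinct_from_zero():
    s = CaptureSeries(season=2003, data=pd.DataFrame(
        columns=["interval_start", "interval_end", "count"]), trap_closed=True)
    included, reason = year_inclusion(s)
    assert not included and reason == "trap_closed"


def test_unimodal_spanning_many_weeks_included():
    cap, _ = gen_captures(ActivityScenario(seed=10))
    curve = fit_activity_curve(cap)
    included, reason = year_inclusion(cap, curve)
    assert included and reason == "none"


def test_bimodal_season_excluded():
    scn = ActivityScenario(peak_offsets=(60.0, 160.0), peak_widths=(12.0, 12.0),
                           mode_weights=(0.5, 0.5), total_expected=1000.0,
                           season_length_days=250, seed=12)
    cap, _ = gen_captures(scn)
    curve = fit_activity_curve(cap)
    assert is_bimodal(curve)
    included, reason = year_inclusion(cap, curve)
    assert not included and reason == "bimodal"


def test_season_metrics_ordering_on_included_fits():
    for seed in range(5):
        cap, _ = gen_captures(ActivityScenario(seed=seed))
        m = season_metrics(cap)
        if m.included:
            assert m.onset_day <= m.peak_day <= m.end_day
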