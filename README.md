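# ddphen

Degree-day accumulation and trap-capture phenology analysis for insect
populations at their cold range margin, built around the invasion of the
blowfly *Calliphora vicina* on the sub-Antarctic Kerguelen Islands.

The question the pipeline addresses: does a warming climate now supply
enough heat for an introduced ectotherm to complete its life cycle in the
wild, and has the seasonal timing of its adult activity shifted?  It is
aimed at invasion ecologists and biometeorologists working with three
everyday data types — constant-temperature rearing tables, long daily (or
hourly) weather-station records, and baited-trap count series with uneven
emptying intervals.

## The models

**Thermal requirement.**  Under the linear degree-day (DD) model, one day
at temperature *T* contributes

    max(0, min(T, T_max) − T_min)   degree days,

with a lower developmental threshold *T*<sub>min</sub> = 2 °C and an upper
threshold *T*<sub>max</sub> = 28 °C.  A stage reached after *d* days of
constant-temperature rearing therefore requires (min(*T*, *T*<sub>max</sub>)
− *T*<sub>min</sub>) · *d* degree days; averaging the egg-to-adult total
over the rearing gradient (including one ambient-temperature run) gives the
mean requirement of **439 DD**.

**Seasonal accumulation.**  Degree days are summed from day-of-year 200
(austral mid-winter) to the end of February of the following calendar year.
The predicted adult emergence day is the first day on which the cumulative
sum reaches the 439 DD requirement; a Student pooled-variance *t*-test
compares seasonal totals before and after a split year.

**Phenology.**  Per breeding year, trap counts are modelled with a
penalized-spline Poisson GAM of season day with the interval length (trap
days) as multiplicative exposure.  The onset, peak and end of the activity
season are the days at which the cumulative area under the fitted daily
curve reaches 10 %, 50 % and 90 % of its total.  Years with captures in
fewer than two ISO weeks, with a closed trap, or with a clearly bimodal
curve are flagged and excluded.

**Trends.**  Annual mean temperature is smoothed with a penalized B-spline
on year (GCV-selected penalty; permutation p-value for the trend), and the
phenology metrics are regressed on year or on climate covariates by OLS
with the usual R², F(1, n−2) and p reporting.

Every stage has a synthetic twin with analytic ground truth
(`ddphen.synthetic`), so the whole chain is testable offline: a sinusoid +
AR(1) temperature generator, an exact inversion of the rearing-table
computation, and Poisson trap counts drawn from a Gaussian-mixture activity
rate whose 10/50/90 % quantiles are known in closed form.

## Worked example

```python
from ddphen import (ThermalThresholds, kerguelen_rearing_table,
                    dd_to_stage, interstage_dd, mean_required_dd)

thr = ThermalThresholds()          # 2 °C, 28 °C, 439 DD
table = kerguelen_rearing_table()  # built-in rearing medians

row8 = next(r for r in table.constant_rows() if r.temperature == 8.0)
print(dd_to_stage(row8, thr, "adult"))        # 556.8  (= (8−2) × 92.8)
print(interstage_dd(row8, thr, "l2", "l3"))   # 57.0   (= 6 × 9.5)
print(mean_required_dd(table, thr))           # 439.0
```

The printed numbers are degree days: 556.8 DD to adulthood at 8 °C, 57 DD
to pass from the second to the third larval instar, and a 439 DD mean
requirement across the gradient — the threshold used by the emergence
search.

The end-to-end pipeline runs from the shell:

```bash
ddphen run-all --seed 3 --n-years 12 --out-dir pipeline_out
```

which simulates a warming climate and capture record, then writes
`season_dd.csv` (seasonal totals and emergence dates), `metrics.csv`
(onset/peak/end per year with exclusion reasons) and `trends.csv`
(regression table).  The numbered scripts under `analysis/` run the same
stages as narrated analyses and write their tables to `results/`.

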