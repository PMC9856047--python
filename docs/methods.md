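# Methods

## Degree-day model

Development is assumed linear in temperature between a lower threshold
T_min and an upper threshold T_max: a day at mean temperature T contributes
`max(0, min(T, T_max) − T_min)` degree days (DD), and an hourly record
contributes the same quantity divided by 24.  Defaults are T_min = 2 °C (a
conservative lower limit for a cold-adapted blowfly), T_max = 28 °C (never
reached at sub-Antarctic stations but kept for symmetry with warmer
climates), and a mean egg-to-adult requirement of 439 DD.  Daily means with
a horizontal upper cutoff are used directly; no sine-interpolated
within-day method is applied, because the input records are daily (or
hourly) station means and the thresholds are far from the daily extremes at
the latitudes of interest.

Constant-temperature rearing converts directly: days-to-stage × the daily
rate.  The rearing table's ambient run cannot be converted this way — its
realized DD total (computed from the ambient trace at rearing time) is
accepted as a supplied number and enters only the mean requirement.  The
built-in table's ambient row is also non-monotone across its first two
stages because the hatch column is a first-10%-hatch time while the others
are medians; monotonicity is therefore enforced only for
constant-temperature rows.  The abandoned 4 °C treatment is representable
(hatch only, trailing gap) but never enters the mean.

## Breeding-season accumulation

Seasons are labelled by starting calendar year and run from calendar
day-of-year 200 (austral mid-winter; the same day number in leap years) to
the last day of February of the following year, leap-aware.  Gaps of at
most 7 days in the daily record are bridged by linear interpolation of
temperature (of daily DD totals for hourly records); longer gaps mark the
season incomplete rather than silently dropping it.  Seven days keeps the
worst-case interpolation error small relative to seasonal totals of several
hundred DD.  Emergence is the first day whose cumulative DD reaches the
requirement — monotone accumulation guarantees warming can only advance it.

The pre/post comparison of seasonal totals uses the Student pooled-variance
two-sample t-test (df = n1 + n2 − 2) with the post-minus-pre sign
convention, so a warming-driven increase yields t > 0; a Welch option is
exposed behind a flag.

## Activity curves and phenology metrics

Counts per trap-emptying interval are modelled as Poisson with a log link:
a cubic B-spline smooth of the interval midpoint day (basis dimension
min(10, n_intervals − 1), knots spanning the full season so the curve is
defined on every day) plus an explicit intercept, with interval length in
days as multiplicative exposure.  The exposure term is what makes the
five-day summer and seven-to-ten-day winter emptying schedules comparable
on a per-trap-day scale.  The penalty weight is selected by AIC over a
fixed logarithmic grid spanning near-unpenalized to effectively-constant
fits; the explicit intercept matters in the heavy-penalty limit, where the
smooth shrinks toward the mean rate rather than toward rate 1.

Onset, peak and end are the first grid days at which the cumulative fitted
rate reaches 10 %, 50 % and 90 % of the season total, by daily summation
with no sub-day interpolation — 1-day resolution matches how such metrics
are reported.  Inclusion rules: at least two distinct ISO weeks with
non-zero captures; a closed trap is recorded as its own exclusion reason,
distinct from a zero-capture year.  Bimodality (a possible second
generation) is auto-flagged when two local maxima each exceed 10 % of the
curve maximum and are separated by a trough below 50 % of the smaller one;
because "clearly bimodal" is ultimately a visual judgement, both thresholds
are configurable and the flag can be overridden.

## Trend statistics

The annual-temperature smooth is a penalized cubic B-spline on year
(P-spline with a second-order difference penalty, 8 basis functions, lambda
by GCV).  The second-order penalty leaves straight lines unpenalized, so
the heavy-smoothing limit is the linear fit and a noiseless linear warming
series is explained essentially perfectly.  The significance of the trend
is assessed by permutation: the deviance explained of the GCV-selected fit
is compared with its distribution over 199 re-orderings of the annual
values, re-selecting lambda each time.  This accounts for the adaptive
smoothing — a naive F-test using the selected fit's effective degrees of
freedom was measurably anti-conservative (about 11 % rejections at nominal
5 % in a 200-replicate white-noise simulation), while the permutation test
is exact under an exchangeable null by construction.

Metric trends are simple OLS regressions (slope, R², F(1, n−2), two-sided
p), one per metric and predictor, matching the per-predictor reporting
style of such analyses; no multiple-testing correction is applied across
the three metrics, and this is deliberate — the three tests are reported,
not selected.  Climate association uses per-year covariates aligned by
year; the averaging window for "seasonal temperature" is configurable and
defaults to the breeding-season window.

## Synthetic data

The temperature generator produces one record per calendar day: an annual
cosine with its minimum anchored at day 200 (southern hemisphere) or
mid-January (northern), a linear warming ramp in years elapsed, and AR(1)
daily residuals (default autocorrelation 0.6, stationary SD 1.5 °C — daily
temperature residuals are strongly autocorrelated in practice, and a
white-noise option remains for analytic tests).  Defaults emulate a
maritime sub-Antarctic climate: annual mean 4.5 °C, seasonal half-amplitude
3 °C.

The rearing-table generator inverts the degree-day computation from a known
cumulative stage-DD vector; multiplicative lognormal noise (mean 1, CV set
by `noise_cv`) is applied to the inter-stage increments rather than to the
cumulative durations so that generated tables always satisfy the
monotonicity invariant, and the inversion is exact when the noise is off.

The capture generator draws interval counts as Poisson with means equal to
exact integrals (differences of normal CDFs) of a Gaussian-mixture activity
rate, normalised so the expected season total matches `total_expected`
(default 500 adults over a 320-day season starting day 200, 15-day peak
SD — a season of a few hundred trapped flies).  The analytic 10/50/90 %
quantiles of the season-restricted rate are returned with every draw and
are, by construction, independent of the trap-emptying schedule.

What the generators do **not** emulate: trap efficiency or its relation to
true abundance (counts are direct Poisson draws from relative activity),
weather-dependent capture probability, mid-season trap outages, observation
gaps at season edges, and the sensor-height change of long station records.
Passing recovery tests therefore demonstrates that the estimation chain is
unbiased and calibrated under a correctly specified sampling model, not
that real trap data meet those assumptions.

## Problem sizes and numerical choices

Simulation-based checks use 100 synthetic seasons for phenology recovery
(expected total 400, peak SD 18 d) and 200 replicates for the type-I-error
calibrations with 199 permutations per smooth test; these sizes give
Monte-Carlo standard errors comfortably inside the asserted bands (about
1.5 points on a 5 % rejection rate).  Quantile crossings use
first-day-at-or-above scans; ties in flat stretches resolve to the earliest
day.  Degenerate inputs (all-zero counts, sub-threshold rearing
temperatures, seasons with unfillable gaps, groups of fewer than two
seasons in the t-test) raise typed errors rather than producing numbers.

## Known limitations

* The emergence search uses whichever resolution the input record has;
  daily and hourly records can legitimately differ by up to a day.
* The bimodality detector is a stand-in for expert visual judgement; its
  thresholds were chosen to trip on well-separated equal modes, not tuned
  to any labelled corpus.
* The permutation trend test assumes exchangeability under the null, which
  white-noise annual series satisfy; strongly autocorrelated annual series
  would need a block or residual-based scheme.
* The degree-day model is linear by design; no curvilinear development-rate
  alternatives (Briere, Sharpe–Schoolfield) are offered.
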