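"""Long-term trend statistics for annual temperature and phenology metrics.

Two model kinds cover the analyses:

* a penalized cubic B-spline smooth of annual mean temperature on year
  (second-order difference penalty, smoothing weight chosen by generalized
  cross-validation), reported with its deviance explained and a permutation
  p-value for the trend; and
* ordinary least-squares simple regressions of a phenology metric (onset,
  peak or end day) on year or on a climate covariate, reported with slope,
  R-squared, F(1, n-2) and the two-sided p-value.

The permutation test for the smooth re-selects the smoothing weight on
every permuted series, so the p-value accounts for the adaptive smoothing
and is exactly calibrated under an exchangeable (no-trend) null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.interpolate import BSpline
import statsmodels.api as sm

from .degree_days import InsufficientDataError


@dataclass(frozen=True)
class TrendFit:
    """Result of one trend model.

    ``kind`` is "smooth" or "linear".  Linear fits fill slope/se and the
    F(1, n-2) test; smooth fits fill edf and use ``r_squared`` for deviance
    explained (identical for a Gaussian fit).  ``p`` is two-sided for the
    linear slope and the permutation tail probability for the smooth trend.
    """

    kind: str
    n: int
    r_squared: float
    p: float
    slope: Optional[float] = None
    slope_se: Optional[float] = None
    f_stat: Optional[float] = None
    df1: Optional[float] = None
    df2: Optional[float] = None
    edf: Optional[float] = None


# ---------------------------------------------------------------------------
# Gaussian P-spline smooth (Eilers-Marx): cubic B-spline basis, second-order
# difference penalty on the coefficients, lambda by GCV.


def _bspline_basis(x: np.ndarray, n_basis: int = 8, degree: int = 3) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    inner = np.linspace(lo, hi, n_basis - degree + 1)
    knots = np.concatenate([[lo] * degree, inner, [hi] * degree])
    return BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()


def _pspline_paths(B: np.ndarray, Y: np.ndarray,
                   lambdas: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the P-spline for every lambda and every column of Y at once.

    Returns (edf[lam], rss[lam, col], fitted[lam, :, col]).  The second-order
    difference penalty leaves constants and linear trends unpenalized, so
    lambda -> inf recovers the straight-line fit (edf -> 2).
    """
    n, k = B.shape
    D = np.diff(np.eye(k), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    BtY = B.T @ Y
    edf = np.empty(len(lambdas))
    rss = np.empty((len(lambdas), Y.shape[1]))
    fitted = np.empty((len(lambdas), n, Y.shape[1]))
    for i, lam in enumerate(lambdas):
        A = BtB + lam * P
        coef = np.linalg.solve(A, BtY)
        H_diag_sum = np.trace(np.linalg.solve(A, BtB))
        f = B @ coef
        edf[i] = H_diag_sum
        rss[i] = np.sum((Y - f) ** 2, axis=0)
        fitted[i] = f
    return edf, rss, fitted


_LAMBDA_GRID = np.logspace(-3, 8, 23)


def _smooth_r2(x: np.ndarray, Y: np.ndarray,
               n_basis: int = 8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GCV-selected P-spline R-squared for each column of Y.

    Returns (r2[col], edf[col], fitted[:, col] at the selected lambda).
    """
    n = len(x)
    B = _bspline_basis(x, n_basis=n_basis)
    edf, rss, fitted = _pspline_paths(B, Y, _LAMBDA_GRID)
    gcv = n * rss / (n - edf[:, None]) ** 2
    best = np.argmin(gcv, axis=0)
    cols = np.arange(Y.shape[1])
    tss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    r2 = 1.0 - rss[best, cols] / np.where(tss > 0, tss, np.inf)
    return r2, edf[best], fitted[best, :, cols].T


def temperature_trend(years: Sequence[int], values: Sequence[float], *,
                      n_basis: int = 8, n_perm: int = 199,
                      seed: int = 0) -> TrendFit:
    """Penalized smooth of an annual series on year with a trend test.

    Reports deviance explained by the GCV-selected smooth and a permutation
    p-value: the observed deviance explained is compared with its null
    distribution over ``n_perm`` random re-orderings of the values, with
    the smoothing weight re-selected by GCV on each permutation.
    """
    x = np.asarray(years, float)
    y = np.asarray(values, float)
    if len(x) < 10:
        raise InsufficientDataError(f"need >=10 years, got {len(x)}")
    if len(x) != len(y) or not np.all(np.isfinite(y)):
        raise ValueError("years and values must align and be finite")

    r2_obs, edf_obs, _ = _smooth_r2(x, y[:, None], n_basis=n_basis)
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    r2_null, _, _ = _smooth_r2(x, perms, n_basis=n_basis)
    p = (1 + int(np.sum(r2_null >= r2_obs[0]))) / (1 + n_perm)
    return TrendFit(kind="smooth", n=len(x), r_squared=float(r2_obs[0]),
                    p=float(p), edf=float(edf_obs[0]))


def smooth_fitted_values(years: Sequence[int], values: Sequence[float], *,
                         n_basis: int = 8) -> np.ndarray:
    """Fitted values of the GCV-selected smooth (for plots and shape checks)."""
    x = np.asarray(years, float)
    y = np.asarray(values, float)[:, None]
    _, _, fitted = _smooth_r2(x, y, n_basis=n_basis)
    return fitted[:, 0]


# ---------------------------------------------------------------------------
# simple linear regressions


def metric_trend(years: Sequence[int], values: Sequence[float], *,
                 min_years: int = 5) -> TrendFit:
    """OLS regression of a phenology metric on year."""
    x = np.asarray(years, float)
    y = np.asarray(values, float)
    if len(x) < min_years:
        raise InsufficientDataError(f"need >={min_years} included years, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all years identical")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendFit(kind="linear", n=len(x),
                    r_squared=float(res.rsquared),
                    p=float(res.pvalues[1]),
                    slope=float(res.params[1]),
                    slope_se=float(res.bse[1]),
                    f_stat=float(res.fvalue),
                    df1=1.0, df2=float(res.df_resid))


def metric_vs_climate(metrics: pd.DataFrame, covariates: pd.DataFrame, *,
                      min_years: int = 5) -> pd.DataFrame:
    """Per-predictor OLS of each phenology metric on each climate covariate.

    ``metrics`` has a ``year`` column plus metric columns (onset_day,
    peak_day, end_day); ``covariates`` has ``year`` plus covariate columns
    (e.g. mean breeding-season temperature, total precipitation).  Years
    present in the metrics but absent from the covariates are an alignment
    error.  Returns a tidy frame with one row per (metric, predictor).
    """
    missing = set(metrics["year"]) - set(covariates["year"])
    if missing:
        raise ValueError(f"covariates missing for years: {sorted(missing)}")
    merged = metrics.merge(covariates, on="year", how="inner")
    metric_cols = [c for c in metrics.columns if c != "year"]
    cov_cols = [c for c in covariates.columns if c != "year"]
    rows = []
    for m in metric_cols:
        for c in cov_cols:
            sub = merged[[m, c]].dropna()
            fit = metric_trend(sub[c], sub[m], min_years=min_years)
            rows.append({"metric": m, "predictor": c, "n": fit.n,
                         "slope": fit.slope, "se": fit.slope_se,
                         "r_squared": fit.r_squared, "f_stat": fit.f_stat,
                         "df1": fit.df1, "df2": fit.df2, "p": fit.p})
    return pd.DataFrame(rows)
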