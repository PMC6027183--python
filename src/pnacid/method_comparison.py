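"""Method-comparison statistics: Passing-Bablok, cusum, Bland-Altman, KS.

These are the standard tools for deciding whether a predicted quantity
agrees with a bench measurement when *both* carry error:

- Passing-Bablok regression estimates slope and intercept as the shifted
  median of all pairwise slopes, is symmetric in x and y, scale-equivariant,
  and free of distributional assumptions on the errors.  Agreement holds
  when the 95% CI of the slope contains 1 and that of the intercept 0.
- The cusum linearity test validates the linearity assumption behind
  Passing-Bablok from the pattern of residual signs along x.
- Bland-Altman analysis summarises agreement as the mean difference (bias)
  and its 1.96-SD limits of agreement.
- A Kolmogorov-Smirnov normality check (Lilliefors-corrected, since the
  normal parameters are estimated from the sample) guards the normal-theory
  parts of the workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

__all__ = [
    "PassingBablokResult",
    "BlandAltmanResult",
    "CusumResult",
    "NormalityResult",
    "PassingBablokRegression",
    "passing_bablok",
    "cusum_linearity",
    "bland_altman",
    "ks_normality",
]


@dataclass(frozen=True)
class PassingBablokResult:
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    intercept_ci_low: float
    intercept_ci_high: float
    n_pairs: int
    cusum_p: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_ci_low: float
    bias_ci_high: float
    n: int


@dataclass(frozen=True)
class CusumResult:
    statistic: float  # max |cusum path|
    p_value: float
    degenerate: bool  # all residuals zero (or one-sided): no test possible


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    method: str  # "lilliefors" or "ks"


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    return x, y


class PassingBablokRegression(RegressorMixin, BaseEstimator):
    """Nonparametric method-comparison regression y = a + b*x.

    The slope estimate is the shifted median of the N pairwise slopes
    S_ij = (y_j - y_i)/(x_j - x_i): slopes of exactly -1 are discarded, the
    median index is shifted by K = #{S_ij < -1}, which makes the estimate
    invariant under exchange of x and y (slope -> 1/slope).  Pairs with
    x_i = x_j are dropped.  Confidence bounds come from the rank-based
    normal approximation; the intercept is median(y - b*x) with its CI
    evaluated at the slope bounds.
    """

    def __init__(self, ci_level: float = 0.95):
        self.ci_level = ci_level

    def fit(self, x, y):
        x, y = _as_xy(x, y)
        n = x.size
        if n < 3:
            raise ValueError(f"Passing-Bablok requires n >= 3 pairs, got {n}")
        if np.all(x == x[0]):
            raise ValueError("x is degenerate (all values identical)")

        i, j = np.triu_indices(n, k=1)
        dx = x[j] - x[i]
        dy = y[j] - y[i]
        keep = dx != 0
        slopes = dy[keep] / dx[keep]
        slopes = slopes[slopes != -1.0]  # exactly -1: discarded by convention
        N = slopes.size
        if N == 0:
            raise ValueError("no valid pairwise slopes (degenerate data)")
        slopes.sort()
        K = int(np.count_nonzero(slopes < -1.0))

        if N % 2:
            b = slopes[(N + 1) // 2 + K - 1]
        else:
            b = 0.5 * (slopes[N // 2 + K - 1] + slopes[N // 2 + K])

        z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        C = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
        M1 = int(round((N - C) / 2.0))
        M2 = N - M1 + 1
        lo_idx = min(max(M1 + K, 1), N) - 1
        hi_idx = min(max(M2 + K, 1), N) - 1
        b_low = slopes[lo_idx]
        b_high = slopes[hi_idx]

        a = float(np.median(y - b * x))
        a_low = float(np.median(y - b_high * x))
        a_high = float(np.median(y - b_low * x))

        self.slope_ = float(b)
        self.intercept_ = a
        self.slope_ci_ = (float(b_low), float(b_high))
        self.intercept_ci_ = (a_low, a_high)
        self.n_pairs_ = n
        cus = cusum_linearity(x, y, slope=self.slope_, intercept=self.intercept_)
        self.cusum_ = cus
        self.cusum_p_ = cus.p_value
        return self

    def predict(self, x):
        if not hasattr(self, "slope_"):
            raise RuntimeError("model is not fitted")
        return self.intercept_ + self.slope_ * np.asarray(x, dtype=float)

    def result(self) -> PassingBablokResult:
        return PassingBablokResult(
            slope=self.slope_,
            intercept=self.intercept_,
            slope_ci_low=self.slope_ci_[0],
            slope_ci_high=self.slope_ci_[1],
            intercept_ci_low=self.intercept_ci_[0],
            intercept_ci_high=self.intercept_ci_[1],
            n_pairs=self.n_pairs_,
            cusum_p=self.cusum_p_,
        )


def passing_bablok(x, y, ci_level: float = 0.95) -> PassingBablokResult:
    """Fit a Passing-Bablok regression and return its summary."""
    return PassingBablokRegression(ci_level=ci_level).fit(x, y).result()


def cusum_linearity(
    x, y, slope: float | None = None, intercept: float | None = None, fit=None
) -> CusumResult:
    """Cusum test of the linearity assumption of Passing-Bablok.

    Points above the fitted line score +sqrt(M/L), points below -sqrt(L/M)
    (L above, M below; on-line points score 0).  Scores are accumulated in
    order of increasing x; under linearity the path is a bridge and its
    maximum absolute excursion, scaled by 1/sqrt(L+M), follows the
    Kolmogorov distribution asymptotically.  Curvature concentrates one sign
    of residual in a contiguous x-range and inflates the excursion.
    """
    if fit is not None:
        slope, intercept = fit.slope, fit.intercept
    if slope is None or intercept is None:
        raise ValueError("provide slope and intercept (or a fit result)")
    x, y = _as_xy(x, y)
    resid = y - (intercept + slope * x)
    pos = resid > 0
    neg = resid < 0
    L = int(pos.sum())
    M = int(neg.sum())
    if L == 0 or M == 0:
        # all residuals on one side (typically all zero for exact fits):
        # the sign path carries no linearity information
        return CusumResult(statistic=0.0, p_value=1.0, degenerate=True)
    order = np.argsort(x, kind="stable")
    scores = np.zeros_like(resid)
    scores[pos] = math.sqrt(M / L)
    scores[neg] = -math.sqrt(L / M)
    path = np.cumsum(scores[order])
    h = float(np.max(np.abs(path)))
    lam = h / math.sqrt(L + M)
    p = float(special.kolmogorov(lam))
    return CusumResult(statistic=h, p_value=p, degenerate=False)


def bland_altman(x, y, ci_level: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman agreement: bias and 1.96-SD limits of the differences.

    Differences are y - x; the bias CI uses the t distribution on n-1 df.
    """
    x, y = _as_xy(x, y)
    n = x.size
    if n < 2:
        raise ValueError(f"Bland-Altman requires n >= 2, got {n}")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    se = sd / math.sqrt(n)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        bias_ci_low=bias - tcrit * se,
        bias_ci_high=bias + tcrit * se,
        n=n,
    )


def ks_normality(values, lilliefors: bool = True) -> NormalityResult:
    """One-sample KS test against a normal with sample mean and SD.

    With ``lilliefors=True`` (default) the p-value accounts for the
    parameters having been estimated from the sample, matching the output of
    common clinical statistics software; ``lilliefors=False`` gives the
    plain KS p-value, which is conservative in this situation.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 5:
        raise ValueError(f"normality test requires n >= 5, got {v.size}")
    if np.all(v == v[0]):
        raise ValueError("values are degenerate (all identical); SD is zero")
    if lilliefors:
        stat, p = _sm_lilliefors(v, dist="norm")
        return NormalityResult(statistic=float(stat), p_value=float(p), method="lilliefors")
    stat, p = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return NormalityResult(statistic=float(stat), p_value=float(p), method="ks")
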