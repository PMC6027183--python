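"""Passing-Bablok, cusum linearity, Bland-Altman, and KS normality."""

import math

import numpy as np
import pytest
from scipy import stats

from pnacid import (
    PassingBablokRegression,
    bland_altman,
    cusum_linearity,
    ks_normality,
    passing_bablok,
)


def brute_force_pb(x, y):
    """Independent shifted-median-of-pairwise-slopes enumeration."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] != x[i]:
                s = (y[j] - y[i]) / (x[j] - x[i])
                if s != -1.0:
                    slopes.append(s)
    slopes.sort()
    N = len(slopes)
    K = sum(s < -1.0 for s in slopes)
    if N % 2:
        b = slopes[(N + 1) // 2 + K - 1]
    else:
        b = 0.5 * (slopes[N // 2 + K - 1] + slopes[N // 2 + K])
    a = float(np.median(np.asarray(y) - b * np.asarray(x)))
    return b, a


class TestPassingBablok:
    def test_identity_data(self):
        x = np.arange(10.0)
        r = passing_bablok(x, x)
        assert r.slope == 1.0
        assert r.intercept == 0.0

    def test_exact_affine_data(self):
        x = np.array([1.0, 2.0, 4.0, 5.5, 7.0, 9.0])
        r = passing_bablok(x, 2.0 * x + 1.0)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_matches_brute_force_enumeration(self, n):
        for seed in range(50):
            rng = np.random.default_rng(1000 * n + seed)
            x = rng.uniform(0, 10, size=n)
            y = 1.5 * x + rng.normal(0, 1, size=n)
            r = passing_bablok(x, y)
            b, a = brute_force_pb(x, y)
            assert r.slope == pytest.approx(b, rel=1e-12)
            assert r.intercept == pytest.approx(a, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("n", [6, 7, 10, 11])  # odd slope counts: exact symmetry
    def test_symmetry_under_axis_exchange(self, n):
        rng = np.random.default_rng(n)
        x = rng.uniform(1, 10, size=n)
        y = 2.0 * x + rng.normal(0, 0.5, size=n)
        fwd = passing_bablok(x, y).slope
        rev = passing_bablok(y, x).slope
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_scale_equivariance(self):
        # monotone data (all pairwise slopes positive) so that the K offset,
        # which counts slopes below -1, is unaffected by positive scaling
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.uniform(0.5, 2.0, size=15))
        y = 0.9 * x + rng.normal(0, 0.1, size=15)
        base = passing_bablok(x, y)
        scaled = passing_bablok(x, 3.5 * y)
        assert scaled.slope == pytest.approx(3.5 * base.slope, rel=1e-12)
        assert scaled.intercept == pytest.approx(3.5 * base.intercept, rel=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, size=12)
        y = x + rng.normal(0, 0.3, size=12)
        base = passing_bablok(x, y)
        perm = rng.permutation(12)
        shuffled = passing_bablok(x[perm], y[perm])
        assert shuffled.slope == base.slope
        assert shuffled.intercept == base.intercept
        assert shuffled.slope_ci_low == base.slope_ci_low

    def test_ci_orders_and_brackets_estimates(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 25, size=40)
        y = 1.1 * x + rng.normal(0, 1.5, size=40)
        r = passing_bablok(x, y)
        assert r.slope_ci_low <= r.slope <= r.slope_ci_high
        assert r.intercept_ci_low <= r.intercept <= r.intercept_ci_high

    def test_agreement_ci_coverage_on_noisy_identity(self):
        """When predictions equal measurements up to small noise, the 95%
        CIs must contain slope 1 and intercept 0 in >= 90% of replicates —
        the validation logic used to accept a predictor."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            # 50 pairs spanning 4-25 mmol, the size and range of a typical
            # titration validation campaign
            x = rng.uniform(4, 25, size=50)
            y = x + rng.normal(0, 0.35, size=50)
            r = passing_bablok(x, y)
            if r.slope_ci_low <= 1.0 <= r.slope_ci_high and (
                r.intercept_ci_low <= 0.0 <= r.intercept_ci_high
            ):
                hits += 1
        assert hits >= 0.90 * n_rep

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            passing_bablok([1.0, 2.0], [1.0, 2.0])  # n < 3
        with pytest.raises(ValueError):
            passing_bablok([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])  # constant x

    def test_estimator_api(self):
        x = np.arange(8.0)
        est = PassingBablokRegression().fit(x, 2 * x + 1)
        assert est.get_params() == {"ci_level": 0.95}
        assert np.allclose(est.predict([0.0, 1.0]), [1.0, 3.0])


class TestCusum:
    def test_exactly_affine_data_is_degenerate_p1(self):
        x = np.arange(1.0, 11.0)
        est = PassingBablokRegression().fit(x, 3 * x - 2)
        assert est.cusum_p_ == 1.0
        assert est.cusum_.degenerate

    def test_quadratic_curvature_detected(self):
        x = np.arange(1.0, 41.0)
        est = PassingBablokRegression().fit(x, x**2)
        assert est.cusum_p_ < 0.05

    def test_statistic_matches_hand_enumerated_path(self):
        """Residual signs +,+,-,+,-,-,-,+,+,- around y = x give the cusum
        path 1,2,1,2,1,0,-1,0,1,0 whose maximum excursion is 2."""
        x = np.arange(1.0, 11.0)
        signs = np.array([1, 1, -1, 1, -1, -1, -1, 1, 1, -1], dtype=float)
        y = x + 0.5 * signs
        res = cusum_linearity(x, y, slope=1.0, intercept=0.0)
        assert res.statistic == pytest.approx(2.0)
        lam = 2.0 / math.sqrt(10)
        p_expected = 2.0 * sum(
            (-1) ** (k - 1) * math.exp(-2.0 * k**2 * lam**2) for k in range(1, 101)
        )
        assert res.p_value == pytest.approx(p_expected, rel=1e-9)

    def test_requires_fit_parameters(self):
        with pytest.raises(ValueError):
            cusum_linearity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_series(self):
        x = np.arange(5.0)
        r = bland_altman(x, x)
        assert r.bias == 0.0
        assert r.sd_diff == 0.0
        assert r.loa_low == r.loa_high == 0.0

    def test_constant_offset(self):
        x = np.arange(5.0)
        r = bland_altman(x, x + 1.0)
        assert r.bias == pytest.approx(1.0)
        assert r.sd_diff == 0.0

    def test_gaussian_differences_recover_generating_mean(self):
        rng = np.random.default_rng(12)
        n = 10_000
        x = rng.uniform(0, 30, size=n)
        y = x + rng.normal(0.5, 1.0, size=n)
        r = bland_altman(x, y)
        assert abs(r.bias - 0.5) < 3.0 * r.sd_diff / math.sqrt(n)
        assert r.loa_low == pytest.approx(r.bias - 1.96 * r.sd_diff)
        assert r.bias_ci_low < r.bias < r.bias_ci_high

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, size=20)
        y = x + rng.normal(0, 1, size=20)
        fwd = bland_altman(x, y)
        rev = bland_altman(y, x)
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.loa_low == pytest.approx(-fwd.loa_high)
        assert rev.loa_high == pytest.approx(-fwd.loa_low)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestNormality:
    def test_large_normal_sample_passes(self):
        rng = np.random.default_rng(0)
        r = ks_normality(rng.normal(5.0, 2.0, size=500))
        assert r.p_value > 0.05
        assert r.method == "lilliefors"

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ks_normality([3.0] * 10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])

    def test_statistic_matches_brute_force_sup_distance(self):
        rng = np.random.default_rng(5)
        v = rng.normal(2, 3, size=7)
        z = np.sort((v - v.mean()) / v.std(ddof=1))
        F = stats.norm.cdf(z)
        n = len(z)
        D = max(
            max(abs((i + 1) / n - F[i]), abs(i / n - F[i])) for i in range(n)
        )
        assert ks_normality(v).statistic == pytest.approx(D, rel=1e-12)
        assert ks_normality(v, lilliefors=False).statistic == pytest.approx(D, rel=1e-12)

    def test_plain_ks_more_conservative_than_lilliefors(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=100)
        assert ks_normality(v, lilliefors=False).p_value >= ks_normality(v).p_value
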