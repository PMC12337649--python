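"""Statistical procedures checked against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icepools.stats import (
    detrend_linear,
    kruskal_wallis,
    lagged_residual_correlation,
    loglinear_decay_fit,
    ols_fit,
    pearson,
    significance_label,
    sma_fit,
)

# ---------------------------------------------------------------------------
# oracles (kept independent of the implementation)


def grid_search_ols(x, y, span=3.0, steps=401, refinements=3):
    """Minimize SSE over a shrinking slope/intercept grid."""
    b0, a0 = 0.0, float(np.mean(y))
    width_b, width_a = span * (np.ptp(y) / max(np.ptp(x), 1e-9) + 1), span * (
        np.ptp(y) + 1
    )
    for _ in range(refinements):
        bs = np.linspace(b0 - width_b, b0 + width_b, steps)
        as_ = np.linspace(a0 - width_a, a0 + width_a, steps)
        sse = (
            (y[None, None, :] - bs[:, None, None] * x[None, None, :]
             - as_[None, :, None]) ** 2
        ).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        b0, a0 = bs[i], as_[j]
        width_b /= steps / 4
        width_a /= steps / 4
    return b0, a0


def exact_permutation_pearson_p(x, y):
    """Two-sided permutation p for |r| by exhaustive enumeration."""
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    count = total = 0
    for perm in itertools.permutations(y):
        r = abs(np.corrcoef(x, perm)[0, 1])
        count += r >= r_obs - 1e-12
        total += 1
    return count / total


def kw_h_oracle(groups):
    """Tie-corrected Kruskal-Wallis H computed from first principles."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j < pooled.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n = pooled.size
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[bounds[k]:bounds[k + 1]].sum() ** 2 / sizes[k]
        for k in range(len(sizes))
    ) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    return h / (1 - np.sum(counts**3 - counts) / (n**3 - n))


def kw_exact_p_oracle(groups):
    """Exact permutation p by enumerating all pooled-value permutations."""
    sizes = [len(g) for g in groups]
    pooled = list(np.concatenate(groups))
    h_obs = kw_h_oracle(groups)
    count = total = 0
    for perm in itertools.permutations(pooled):
        bounds = np.cumsum([0] + sizes)
        gs = [np.asarray(perm[bounds[k]:bounds[k + 1]]) for k in range(len(sizes))]
        count += kw_h_oracle(gs) >= h_obs - 1e-12
        total += 1
    return count / total


# ---------------------------------------------------------------------------


class TestOLS:
    def test_exact_line(self):
        res = ols_fit([0, 1, 2], [0, 2, 4])
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        res = ols_fit([0, 1, 2, 3], [5, 5, 5, 5])
        assert res.slope == 0.0
        assert res.r_squared == 0.0
        assert res.p_value == 1.0

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ols_fit([1, 1, 1], [1, 2, 3])

    def test_against_grid_search_oracle(self, rng):
        x = rng.uniform(0, 10, 10)
        y = 1.7 * x - 2.0 + rng.normal(0, 1.0, 10)
        res = ols_fit(x, y)
        b, a = grid_search_ols(x, y)
        assert res.slope == pytest.approx(b, abs=1e-3)
        assert res.intercept == pytest.approx(a, abs=1e-2)

    def test_invariant_to_reordering(self, rng):
        x = rng.uniform(0, 10, 12)
        y = 0.5 * x + rng.normal(0, 1, 12)
        perm = rng.permutation(12)
        a, b = ols_fit(x, y), ols_fit(x[perm], y[perm])
        assert a.slope == pytest.approx(b.slope)
        assert a.p_value == pytest.approx(b.p_value)


class TestSMA:
    def test_equals_ols_on_perfect_line(self):
        res = sma_fit([0, 1, 2], [0, 2, 4])
        assert res.slope == pytest.approx(2.0)
        assert res.method == "SMA"

    def test_slope_is_sd_ratio_and_exceeds_ols(self, rng):
        x = rng.uniform(0, 10, 20)
        y = 2.0 * x + rng.normal(0, 3, 20)
        sma = sma_fit(x, y)
        ols = ols_fit(x, y)
        assert abs(sma.slope) == pytest.approx(
            np.std(y, ddof=1) / np.std(x, ddof=1)
        )
        assert abs(ols.slope) <= abs(sma.slope) + 1e-12

    def test_axis_swap_reciprocal(self, rng):
        x = rng.uniform(0, 10, 15)
        y = 1.3 * x + rng.normal(0, 1, 15)
        assert sma_fit(x, y).slope * sma_fit(y, x).slope == pytest.approx(1.0)

    def test_scaling_y_scales_slope(self, rng):
        x = rng.uniform(0, 5, 10)
        y = x + rng.normal(0, 0.3, 10)
        assert sma_fit(x, 11 * y).slope == pytest.approx(
            11 * sma_fit(x, y).slope
        )

    def test_r_zero_flagged_positive(self):
        # orthogonal design: exactly zero correlation
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        res = sma_fit(x, y)
        assert res.slope > 0
        assert "sign_undefined" in res.flags


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(5.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        res = pearson([1, 1, 1], [1, 2, 3])
        assert math.isnan(res.r)
        assert "zero_variance" in res.flags

    def test_p_against_exhaustive_permutation(self, rng):
        x = rng.uniform(0, 1, 5)
        y = x + rng.normal(0, 0.5, 5)
        res = pearson(x, y)
        p_exact = exact_permutation_pearson_p(x, y)
        assert abs(res.p_value - p_exact) < 0.12


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1, 1, 1], [1, 1, 1]])
        assert h == 0.0
        assert p == 1.0

    def test_separated_groups_exact(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=1e-3)
        assert p == pytest.approx(0.10, abs=1e-9)  # 2 of 20 assignments

    def test_exact_p_matches_enumeration_oracle(self, rng):
        groups = [rng.uniform(0, 1, 3), rng.uniform(0.2, 1.2, 3)]
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(kw_h_oracle(groups), abs=1e-9)
        assert p == pytest.approx(kw_exact_p_oracle(groups), abs=1e-9)

    def test_chisquare_close_to_exact_at_n10(self, rng):
        groups = [rng.uniform(0, 1, 5), rng.uniform(0, 1, 5)]
        _, p_exact = kruskal_wallis(groups, exact_threshold=10)
        _, p_chi2 = kruskal_wallis(groups, exact_threshold=0)
        assert abs(p_exact - p_chi2) < 0.05

    @settings(max_examples=25, derandomize=True)
    @given(shift=st.floats(min_value=0, max_value=2))
    def test_invariant_under_monotone_transform(self, shift):
        g1 = np.array([0.1, 0.5, 0.9, 1.4])
        g2 = np.array([0.3, 0.8, 1.1, 2.0]) + shift
        h1, p1 = kruskal_wallis([g1, g2])
        h2, p2 = kruskal_wallis([np.exp(g1), np.exp(g2)])
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)


class TestDetrendAndLag:
    def test_perfect_line_gives_zero_residuals(self):
        t = np.arange(6.0)
        resid = detrend_linear(t, 3 * t + 1)
        assert np.allclose(resid, 0, atol=1e-12)

    def test_residuals_centred_and_orthogonal(self, rng):
        t = np.arange(10.0)
        y = rng.normal(0, 1, 10)
        resid = detrend_linear(t, y)
        assert abs(resid.sum()) < 1e-9
        assert abs(resid @ t) < 1e-7

    def test_adding_trend_leaves_residuals_unchanged(self, rng):
        t = np.arange(10.0)
        y = rng.normal(0, 1, 10)
        assert np.allclose(detrend_linear(t, y), detrend_linear(t, y + 2.5 * t))

    def test_lag_recovers_shift(self, rng):
        base = rng.normal(0, 1, 13)
        forcing = base[1:]
        residuals = base[:-1]  # residual[i] == forcing[i-1]: lags by one cycle
        r_by_lag = {
            lag: abs(lagged_residual_correlation(residuals, forcing, lag).r)
            for lag in (0, 1, 2)
        }
        assert max(r_by_lag, key=r_by_lag.get) == 1

    def test_lag0_identity(self):
        x = np.arange(5.0)
        assert lagged_residual_correlation(x, x, 0).r == pytest.approx(1.0)

    def test_trimmed_n_reported(self, rng):
        r = lagged_residual_correlation(rng.normal(0, 1, 10),
                                        rng.normal(0, 1, 10), lag=3)
        assert r.n == 7

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            lagged_residual_correlation([1, 2, 3], [1, 2, 3], lag=2)

    def test_white_noise_null_bound(self):
        # |r| below 0.58 (the n=12 5% point) in ~90% of seeds
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            r = lagged_residual_correlation(g.normal(0, 1, 12),
                                            g.normal(0, 1, 12), 0)
            hits += abs(r.r) < 0.58
        assert hits >= 85


class TestLoglinearDecay:
    def test_exact_exponential(self):
        t = np.arange(12.0)
        res = loglinear_decay_fit(t, np.exp(-0.1 * t))
        assert res.slope == pytest.approx(-0.1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.method == "log-OLS"

    def test_constant_ratio(self):
        res = loglinear_decay_fit(np.arange(5.0), np.ones(5))
        assert res.slope == 0.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            loglinear_decay_fit([0, 1, 2], [1.0, 0.0, 1.0])

    def test_against_grid_rate_oracle(self, rng):
        t = np.arange(15.0)
        ratio = 2.0 * np.exp(-0.08 * t) * np.exp(rng.normal(0, 0.05, 15))
        fit = loglinear_decay_fit(t, ratio)
        # direct grid search on the log-scale SSE
        rates = np.linspace(-0.2, 0.0, 2001)
        sse = [
            ((np.log(ratio) - (r * t + np.mean(np.log(ratio) - r * t))) ** 2).sum()
            for r in rates
        ]
        assert fit.slope == pytest.approx(rates[int(np.argmin(sse))], abs=1e-4)


class TestSignificanceConvention:
    @pytest.mark.parametrize(
        "p, label",
        [(0.008, "significant"), (0.068, "weak"), (0.054, "weak"),
         (0.210, "ns"), (0.01, "weak"), (0.1, "weak"), (float("nan"), "undefined")],
    )
    def test_two_level_convention(self, p, label):
        assert significance_label(p) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_label(1.5)
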