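"""Statistical procedures for the campaign analysis.

Ordinary least squares (OLS) is used for relationships with a natural
predictor (e.g. concentration vs time); standardized major axis (SMA)
regression for pairs of variables that are both estimated with error and
play symmetric roles (bulk-melt vs independently estimated intracellular
concentrations); Pearson correlation for association; Kruskal-Wallis for
comparing groups without distributional assumptions.  Significance follows
a two-level convention: p < 0.01 is "significant", 0.01 <= p <= 0.1 is a
"weak" association, larger p is not significant.

SMA slope and the exact-permutation Kruskal-Wallis (small samples) are
implemented here from their definitions; OLS, Pearson and the chi-square
Kruskal-Wallis path delegate to scipy.stats.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "detrend_linear",
    "kruskal_wallis",
    "lagged_residual_correlation",
    "loglinear_decay_fit",
    "ols_fit",
    "pearson",
    "significance_label",
    "sma_fit",
]


@dataclass(frozen=True)
class RegressionResult:
    """A fitted line with its inference, tagged by method ('OLS'/'SMA'/'log-OLS')."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    method: str
    n: int
    flags: tuple = field(default_factory=tuple)

    @property
    def significance(self) -> str:
        return significance_label(self.p_value)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    lag: int = 0
    flags: tuple = field(default_factory=tuple)

    @property
    def significance(self) -> str:
        return significance_label(self.p_value)


def _validate_xy(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def ols_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x; p from a two-sided t test on the slope."""
    x, y = _validate_xy(x, y)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x has zero variance")
    res = sps.linregress(x, y)
    r = res.rvalue
    p = res.pvalue
    if np.isnan(r):  # constant y: slope 0, no explained variance
        r, p = 0.0, 1.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r**2),
        p_value=float(p),
        method="OLS",
        n=int(x.size),
    )


def sma_fit(x, y) -> RegressionResult:
    """Standardized major axis regression of y on x.

    slope = sign(r) * sd(y)/sd(x); intercept through the means; r^2 is the
    squared Pearson correlation and the p-value is that of the correlation
    test (the standard inference for SMA).  When r is exactly 0 the slope
    sign is undefined; the positive root is returned with a flag.
    """
    x, y = _validate_xy(x, y)
    sx = np.std(x, ddof=1)
    sy = np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("SMA requires nonzero variance in both variables")
    r, p = sps.pearsonr(x, y)
    flags = ()
    sign = np.sign(r)
    if sign == 0:
        sign, flags = 1.0, ("sign_undefined",)
    slope = float(sign * sy / sx)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=float(r**2),
        p_value=float(p),
        method="SMA",
        n=int(x.size),
        flags=flags,
    )


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-based p."""
    x, y = _validate_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            r=float("nan"), p_value=float("nan"), n=int(x.size),
            flags=("zero_variance",),
        )
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=int(x.size))


def _kw_h(groups_ranks, n_total, tie_correction):
    h = 0.0
    for rk in groups_ranks:
        h += rk.sum() ** 2 / rk.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    return h / tie_correction


def kruskal_wallis(groups, exact_threshold: int = 10):
    """Kruskal-Wallis rank test across >= 2 groups.

    Returns (H, p).  H uses the tie-corrected rank statistic.  For total
    n <= ``exact_threshold`` the p-value is computed by exhaustive
    enumeration of all assignments of the pooled ranks to groups; otherwise
    it comes from the chi-square approximation with k-1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    group_ranks = [ranks[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
    h_obs = _kw_h(group_ranks, n_total, tie_corr)

    if n_total <= exact_threshold:
        p = _kw_exact_p(ranks, sizes, n_total, tie_corr, h_obs)
    else:
        p = float(sps.chi2.sf(h_obs, df=len(groups) - 1))
    return float(h_obs), p


def _kw_exact_p(ranks, sizes, n_total, tie_corr, h_obs):
    """Exact permutation p: enumerate all partitions of ranks into group sizes."""
    idx_all = frozenset(range(n_total))
    count = 0
    total = 0

    def recurse(remaining, size_idx, chosen):
        nonlocal count, total
        if size_idx == len(sizes) - 1:
            parts = chosen + [sorted(remaining)]
            h = _kw_h([ranks[list(p)] for p in parts], n_total, tie_corr)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        rem = sorted(remaining)
        for combo in itertools.combinations(rem, sizes[size_idx]):
            recurse(remaining - set(combo), size_idx + 1, chosen + [list(combo)])

    recurse(idx_all, 0, [])
    return count / total


def detrend_linear(t, y):
    """Residuals of y about its OLS line on t; sum to 0 and orthogonal to t."""
    t, y = _validate_xy(t, y)
    fit = ols_fit(t, y)
    return y - (fit.slope * t + fit.intercept)


def lagged_residual_correlation(residuals, forcing, lag: int = 0) -> CorrelationResult:
    """Pearson correlation of residuals against earlier forcing.

    The biological residual at cycle i is paired with the forcing at cycle
    i - lag (the response lags the forcing); ``lag`` is in sampling cycles
    on an aligned grid.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    r = np.asarray(residuals, dtype=float)
    f = np.asarray(forcing, dtype=float)
    if r.shape != f.shape or r.ndim != 1:
        raise ValueError("residuals and forcing must be aligned 1-d arrays")
    n = r.size - lag
    if n < 3:
        raise ValueError("fewer than 3 pairs remain after lag trimming")
    out = pearson(f[: r.size - lag], r[lag:])
    return CorrelationResult(r=out.r, p_value=out.p_value, n=n, lag=lag,
                             flags=out.flags)


def loglinear_decay_fit(t, ratio) -> RegressionResult:
    """Exponential (natural log-linear) fit of a positive ratio against time.

    OLS of ln(ratio) on t; the slope is the decay rate per unit time
    (negative for decay).  Method tag 'log-OLS'.
    """
    t = np.asarray(t, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("ratio values must be > 0 for a log-linear fit")
    fit = ols_fit(t, np.log(ratio))
    return RegressionResult(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        p_value=fit.p_value,
        method="log-OLS",
        n=fit.n,
    )


def significance_label(p, weak_alpha: float = 0.1, strict_alpha: float = 0.01) -> str:
    """Two-level convention: 'significant' (p < strict), 'weak' (p <= weak), 'ns'."""
    if math.isnan(p):
        return "undefined"
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < strict_alpha:
        return "significant"
    if p <= weak_alpha:
        return "weak"
    return "ns"
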