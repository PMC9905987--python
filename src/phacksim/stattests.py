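"""Statistical test kernels and reliability measures used by every strategy.

All kernels are self-contained closed forms so that the Monte-Carlo loops
stay cheap; they are cross-validated against scipy/statsmodels in the test
suite.  Every test is two-sided.  Effect sizes follow the usual conventions:
Cohen's d with the pooled SD for group comparisons, R^2 for regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rngdata import DegenerateDataError, InvalidArgumentError

__all__ = [
    "TestResult",
    "student_t",
    "welch_t",
    "wilcoxon_rank_sum",
    "yuen_t",
    "anova_f",
    "ols_slope",
    "ancova_group_test",
    "shapiro_wilk_p",
    "cronbach_alpha",
    "alpha_if_deleted",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: two-sided p, statistic, df, effect size, label, n."""

    __test__ = False  # not a pytest class, despite the name

    p: float
    statistic: float
    df: float | tuple[float, float]
    effect_size: float | None
    test_label: str
    n_used: int

    def to_dict(self) -> dict:
        df = self.df if not isinstance(self.df, tuple) else list(self.df)
        return {"p": self.p, "statistic": self.statistic, "df": df,
                "effect_size": self.effect_size, "test_label": self.test_label,
                "n_used": self.n_used}


def _as_group(g) -> np.ndarray:
    a = np.asarray(g, dtype=float).ravel()
    if a.size < 2:
        raise InvalidArgumentError(f"each group needs >= 2 observations, got {a.size}")
    return a


def student_t(g1, g2) -> TestResult:
    """Pooled-variance independent-samples t test; effect size = Cohen's d."""
    g1, g2 = _as_group(g1), _as_group(g2)
    n1, n2 = g1.size, g2.size
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 <= _EPS:
        if abs(g1.mean() - g2.mean()) <= _EPS:
            # identical constant groups: no evidence against the null
            return TestResult(1.0, 0.0, float(df), 0.0, "student_t", n1 + n2)
        raise DegenerateDataError("zero pooled variance with unequal means")
    diff = g1.mean() - g2.mean()
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    d = diff / np.sqrt(sp2)
    return TestResult(float(p), float(t), float(df), float(d), "student_t", n1 + n2)


def welch_t(g1, g2) -> TestResult:
    """Welch unequal-variance t test with Satterthwaite degrees of freedom."""
    g1, g2 = _as_group(g1), _as_group(g2)
    n1, n2 = g1.size, g2.size
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 <= _EPS:
        if abs(g1.mean() - g2.mean()) <= _EPS:
            return TestResult(1.0, 0.0, float(n1 + n2 - 2), 0.0, "welch_t", n1 + n2)
        raise DegenerateDataError("zero variance with unequal means")
    t = (g1.mean() - g2.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    d = (g1.mean() - g2.mean()) / np.sqrt(sp2) if sp2 > _EPS else 0.0
    return TestResult(float(p), float(t), float(df), float(d), "welch_t", n1 + n2)


def wilcoxon_rank_sum(g1, g2) -> TestResult:
    """Two-sided Wilcoxon rank-sum test, normal approximation with continuity
    and tie correction."""
    g1, g2 = _as_group(g1), _as_group(g2)
    n1, n2 = g1.size, g2.size
    n = n1 + n2
    combined = np.concatenate([g1, g2])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= _EPS:
        raise DegenerateDataError("all observations tied; rank-sum variance is zero")
    delta = w - mean_w
    # continuity correction shrinks |delta| by 0.5
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var_w) if delta != 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(float(min(p, 1.0)), float(z), np.inf, None, "wilcoxon", n)


def _winsorize_sorted(a: np.ndarray, g: int) -> np.ndarray:
    w = np.sort(a)
    if g > 0:
        w[:g] = w[g]
        w[-g:] = w[-g - 1]
    return w


def yuen_t(g1, g2, trim: float) -> TestResult:
    """Yuen's test on trimmed means with winsorized variances (Yuen 1974).

    ``floor(trim * n)`` observations are removed from each tail of each
    group; ``trim = 0`` reduces exactly to the Welch test.
    """
    if not 0.0 <= trim < 0.5:
        raise InvalidArgumentError(f"trim must lie in [0, 0.5), got {trim}")
    g1, g2 = _as_group(g1), _as_group(g2)
    n1, n2 = g1.size, g2.size
    c1, c2 = int(np.floor(trim * n1)), int(np.floor(trim * n2))
    h1, h2 = n1 - 2 * c1, n2 - 2 * c2
    if h1 < 2 or h2 < 2:
        raise DegenerateDataError(f"over-trimming: effective sizes {h1}, {h2}")
    tm1 = np.sort(g1)[c1:n1 - c1].mean()
    tm2 = np.sort(g2)[c2:n2 - c2].mean()
    wv1 = _winsorize_sorted(g1, c1).var(ddof=1)
    wv2 = _winsorize_sorted(g2, c2).var(ddof=1)
    d1 = (n1 - 1) * wv1 / (h1 * (h1 - 1))
    d2 = (n2 - 1) * wv2 / (h2 * (h2 - 1))
    if d1 + d2 <= _EPS:
        if abs(tm1 - tm2) <= _EPS:
            return TestResult(1.0, 0.0, float(h1 + h2 - 2), None, f"yuen_{trim:g}", n1 + n2)
        raise DegenerateDataError("zero winsorized variance with unequal trimmed means")
    t = (tm1 - tm2) / np.sqrt(d1 + d2)
    df = (d1 + d2) ** 2 / (d1**2 / (h1 - 1) + d2**2 / (h2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(p), float(t), float(df), None, f"yuen_{trim:g}", n1 + n2)


def anova_f(groups) -> TestResult:
    """One-way fixed-effects ANOVA F test."""
    gs = [_as_group(g) for g in groups]
    if len(gs) < 2:
        raise InvalidArgumentError("need >= 2 groups")
    n = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = len(gs) - 1, n - len(gs)
    if ss_within <= _EPS:
        if ss_between <= _EPS:
            return TestResult(1.0, 0.0, (float(df1), float(df2)), None, "anova_f", n)
        raise DegenerateDataError("zero within-group variance with unequal means")
    f = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(f, df1, df2)
    return TestResult(float(p), float(f), (float(df1), float(df2)), None, "anova_f", n)


def ols_slope(x, y, label: str = "ols_slope") -> TestResult:
    """Two-sided t test on the slope of ``y ~ intercept + x``; effect size = R^2."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n < 4 or y.size != n:
        raise InvalidArgumentError(f"need n >= 4 matched observations, got {n} and {y.size}")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = (xd**2).sum()
    if sxx <= _EPS:
        raise DegenerateDataError("constant predictor")
    slope = (xd * yd).sum() / sxx
    resid = yd - slope * xd
    sse = (resid**2).sum()
    syy = (yd**2).sum()
    df = n - 2
    if syy <= _EPS:
        raise DegenerateDataError("constant outcome")
    r2 = 1.0 - sse / syy
    if sse <= _EPS * syy:
        # perfect fit: p underflows to 0
        return TestResult(0.0, np.inf, float(df), float(r2), label, n)
    se = np.sqrt(sse / df / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(p), float(t), float(df), float(r2), label, n)


def ancova_group_test(y, group, covariates=None, label: str = "ancova") -> TestResult:
    """t test of the group coefficient in ``y ~ intercept + group + covariates``.

    Equivalent to a type-III test of the group effect in this design.  With
    zero covariates this is the binary-predictor OLS formulation of the
    pooled-variance t test.
    """
    y = np.asarray(y, dtype=float).ravel()
    group = np.asarray(group, dtype=float).ravel()
    n = y.size
    if group.size != n:
        raise InvalidArgumentError("y and group must have equal length")
    if min((group == group.min()).sum(), (group == group.max()).sum()) < 2 or group.min() == group.max():
        raise DegenerateDataError("each group needs >= 2 observations")
    cols = [np.ones(n), group]
    if covariates is not None:
        z = np.asarray(covariates, dtype=float)
        z = z.reshape(n, -1)
        cols.extend(z.T)
    X = np.column_stack(cols)
    k = X.shape[1]
    if n <= k:
        raise DegenerateDataError("more parameters than observations")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"rank-deficient design matrix: {exc}") from exc
    if np.linalg.cond(xtx) > 1e12:
        raise DegenerateDataError("rank-deficient design matrix")
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sse = (resid**2).sum()
    df = n - k
    sigma2 = sse / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    if se <= _EPS:
        raise DegenerateDataError("zero residual variance")
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(p), float(t), float(df), None, label, n)


def shapiro_wilk_p(residuals) -> float:
    """Shapiro-Wilk normality p-value (scipy implementation)."""
    r = np.asarray(residuals, dtype=float).ravel()
    if not 3 <= r.size <= 5000:
        raise InvalidArgumentError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {r.size}")
    if np.ptp(r) <= _EPS:
        raise DegenerateDataError("constant residual vector")
    return float(stats.shapiro(r).pvalue)


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / variance of sums)."""
    m = np.asarray(items, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise InvalidArgumentError("need an n x k item matrix with k >= 2")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var <= _EPS:
        raise DegenerateDataError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - m.var(axis=0, ddof=1).sum() / total_var))


def alpha_if_deleted(items) -> np.ndarray:
    """Cronbach's alpha of the scale with each item removed in turn (k >= 3)."""
    m = np.asarray(items, dtype=float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise InvalidArgumentError("alpha-if-deleted needs k >= 3 items")
    k = m.shape[1]
    return np.array([cronbach_alpha(np.delete(m, j, axis=1)) for j in range(k)])
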