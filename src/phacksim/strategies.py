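"""The twelve p-hacking strategies.

Each strategy consumes one null dataset (strategy 3, optional stopping, is
the exception: it models data *collection* and therefore accrues its own
observations) and emits a :class:`StrategyRun` — the ordered list of
candidate hypothesis tests a researcher trying that strategy would have
computed, with the original planned analysis always first.  A p-hacking
attempt is *successful* when at least one candidate p-value falls below the
significance level; by construction this does not depend on the order of
candidates nor on which p-value would later be reported.

Degenerate candidate tests (zero variance, undersized subgroups, ...) are
skipped and counted, never treated as significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import imputation as imp
from . import outliers as outl
from .rngdata import (DatasetBundle, DegenerateDataError, InvalidArgumentError,
                      RngStream, apply_mcar, gen_regression, gen_two_group)
from .stattests import (TestResult, alpha_if_deleted, ancova_group_test, anova_f,
                        cronbach_alpha, ols_slope, shapiro_wilk_p, student_t,
                        welch_t, wilcoxon_rank_sum, yuen_t)

__all__ = [
    "StrategyRun", "STRATEGY_REGISTRY", "strategy_names", "simulate_once",
    "s1_selective_dv", "s2_selective_iv", "s3_optional_stopping",
    "s4_outlier_exclusion", "s5_covariates", "s6_scale_redefinition",
    "s7_transformation", "s8_discretization", "s9_alternative_tests",
    "s10_imputation", "s11_subgroups", "s12_incorrect_rounding",
]

DEFAULT_ALPHA = 0.05


@dataclass
class StrategyRun:
    """Ordered candidate tests produced by one p-hacking attempt on one dataset."""

    strategy: str
    candidates: list[TestResult]
    condition: dict
    alpha: float = DEFAULT_ALPHA
    skipped: int = 0
    notes: list[str] = field(default_factory=list)
    success_override: bool | None = None  # used by rounding, whose rule is not "p < alpha"

    def __post_init__(self) -> None:
        if not self.candidates:
            raise InvalidArgumentError("a StrategyRun needs at least the planned test")

    @property
    def original(self) -> TestResult:
        return self.candidates[0]

    @property
    def min_p(self) -> float:
        return min(c.p for c in self.candidates)

    @property
    def success(self) -> bool:
        """At least one candidate significant; order- and reporting-independent."""
        if self.success_override is not None:
            return self.success_override
        return self.min_p < self.alpha

    def pvalues(self) -> np.ndarray:
        return np.array([c.p for c in self.candidates])


class _Collector:
    """Accumulates candidates, silently skipping degenerate tests."""

    def __init__(self) -> None:
        self.candidates: list[TestResult] = []
        self.skipped = 0
        self.notes: list[str] = []

    def add(self, fn, *args, **kwargs) -> TestResult | None:
        try:
            res = fn(*args, **kwargs)
        except DegenerateDataError as exc:
            self.skipped += 1
            self.notes.append(str(exc))
            return None
        self.candidates.append(res)
        return res

    def run(self, strategy: str, condition: dict, alpha: float) -> StrategyRun:
        return StrategyRun(strategy, self.candidates, condition, alpha,
                           self.skipped, self.notes)


# --- strategy 1: selective reporting of the dependent variable ----------------

def s1_selective_dv(bundle: DatasetBundle, alpha: float = DEFAULT_ALPHA) -> StrategyRun:
    """One Student t test per dependent variable, in column order."""
    bundle.require("group1", "group2")
    col = _Collector()
    for j in range(bundle.group1.shape[1]):
        col.add(student_t, bundle.group1[:, j], bundle.group2[:, j])
    return col.run("s1", bundle.condition, alpha)


# --- strategy 2: selective reporting of the independent variable --------------

def s2_selective_iv(bundle: DatasetBundle, design: str = "ttest",
                    alpha: float = DEFAULT_ALPHA) -> StrategyRun:
    """Fixed control group against each experimental group (t-test design), or
    the outcome against each candidate predictor (regression design)."""
    col = _Collector()
    if design == "ttest":
        bundle.require("group1", "group2")
        control = bundle.group1[:, 0]
        for j in range(bundle.group2.shape[1]):
            col.add(student_t, control, bundle.group2[:, j])
    elif design == "regression":
        bundle.require("items", "y")
        for j in range(bundle.items.shape[1]):
            col.add(ols_slope, bundle.items[:, j], bundle.y)
    else:
        raise InvalidArgumentError(f"design must be 'ttest' or 'regression', got {design!r}")
    return col.run("s2", {**bundle.condition, "design": design}, alpha)


# --- strategy 3: optional stopping --------------------------------------------

def s3_optional_stopping(n_min: int, n_max: int, step: int,
                         alpha: float = DEFAULT_ALPHA,
                         rng: RngStream | None = None) -> StrategyRun:
    """Repeatedly test two accruing groups, stopping at the first significant peek.

    Peeks happen at ``n_min`` per group, then every ``step`` added
    observations, and finally at ``n_max``.  A step larger than
    ``n_max - n_min`` yields exactly two peeks.  Candidates after the first
    significant peek never happen and are not recorded.
    """
    if rng is None:
        raise InvalidArgumentError("an RngStream is required")
    if not 2 <= n_min <= n_max or step < 1:
        raise InvalidArgumentError("need 2 <= n_min <= n_max and step >= 1")
    g = rng.generator
    g1 = g.standard_normal(n_max)
    g2 = g.standard_normal(n_max)
    peeks = list(range(n_min, n_max + 1, step))
    if peeks[-1] != n_max:
        peeks.append(n_max)
    col = _Collector()
    for n in peeks:
        res = col.add(student_t, g1[:n], g2[:n])
        if res is not None and res.p < alpha:
            break
    return col.run("s3", {"n_min": n_min, "n_max": n_max, "step": step}, alpha)


# --- strategy 4: outlier exclusion --------------------------------------------

def s4_outlier_exclusion(bundle: DatasetBundle, k_methods: int = 3,
                         alpha: float = DEFAULT_ALPHA,
                         rng: RngStream | None = None) -> StrategyRun:
    """Original slope test, then re-tests after every candidate exclusion of
    ``k_methods`` detection techniques drawn at random from the roster.

    Identical exclusion sets produced by different methods or thresholds are
    tested only once.
    """
    bundle.require("x", "y")
    roster = outl.list_methods()
    if not 1 <= k_methods <= len(roster):
        raise InvalidArgumentError(f"k_methods must lie in 1..{len(roster)}")
    if k_methods < len(roster):
        if rng is None:
            raise InvalidArgumentError("subsampling methods requires an RngStream")
        idx = rng.generator.choice(len(roster), size=k_methods, replace=False)
        methods = [roster[i] for i in sorted(idx)]
    else:
        methods = roster
    x, y = bundle.x, bundle.y
    col = _Collector()
    col.add(ols_slope, x, y)
    seen: set[frozenset] = set()
    for m in methods:
        for cand in outl.candidate_exclusions(m, x, y):
            if cand.excluded in seen:
                continue
            seen.add(cand.excluded)
            col.add(ols_slope, *cand.apply(x, y))
    return col.run("s4", {**bundle.condition, "k_methods": k_methods}, alpha)


# --- strategy 5: controlling for covariates -----------------------------------

def s5_covariates(bundle: DatasetBundle, alpha: float = DEFAULT_ALPHA) -> StrategyRun:
    """Planned t test, each covariate singly, then sequential models adding
    covariates in decreasing order of their sample correlation with the DV
    (the single-covariate sequential model duplicates a singly-added one and
    is dropped); k covariates yield 2k - 1 additional tests."""
    bundle.require("group1", "group2", "covariates")
    y = np.concatenate([bundle.group1[:, 0], bundle.group2[:, 0]])
    group = np.repeat([0.0, 1.0], bundle.n)
    z = bundle.covariates
    k = z.shape[1]
    col = _Collector()
    col.add(student_t, bundle.group1[:, 0], bundle.group2[:, 0])
    for j in range(k):
        col.add(ancova_group_test, y, group, z[:, [j]], label=f"ancova_z{j + 1}")
    order = np.argsort(-np.abs([np.corrcoef(z[:, j], y)[0, 1] for j in range(k)]),
                       kind="stable")
    for m in range(2, k + 1):
        cols = order[:m]
        col.add(ancova_group_test, y, group, z[:, cols],
                label="ancova_seq_" + "+".join(str(c + 1) for c in cols))
    return col.run("s5", bundle.condition, alpha)


# --- strategy 6: scale redefinition -------------------------------------------

def s6_scale_redefinition(bundle: DatasetBundle, m_max: int = 1,
                          alpha: float = DEFAULT_ALPHA) -> StrategyRun:
    """Slope test with the full-scale mean as predictor, then up to ``m_max``
    greedy item deletions maximising alpha-if-deleted (ties broken by lowest
    item index); each deletion adds two candidates — the reduced-scale mean
    and the deleted item alone as predictor.  Stops when 2 items remain."""
    bundle.require("items", "y")
    items, y = bundle.items, bundle.y
    k = items.shape[1]
    if m_max < 0:
        raise InvalidArgumentError("m_max must be >= 0")
    col = _Collector()
    col.add(ols_slope, items.mean(axis=1), y, label="scale_full")
    remaining = list(range(k))
    for _ in range(m_max):
        if len(remaining) <= 2:
            break
        try:
            aid = alpha_if_deleted(items[:, remaining])
        except DegenerateDataError:
            break
        drop = remaining[int(np.argmax(aid))]  # argmax takes the lowest index on ties
        remaining.remove(drop)
        col.add(ols_slope, items[:, remaining].mean(axis=1), y,
                label=f"scale_minus_{k - len(remaining)}")
        col.add(ols_slope, items[:, drop], y, label=f"item_{drop + 1}_alone")
    return col.run("s6", {**bundle.condition, "m_max": m_max}, alpha)


# --- strategy 7: variable transformation --------------------------------------

def _safe_log(v: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log(v)


def _safe_recip(v: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return 1.0 / v


def _safe_sqrt(v: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.sqrt(v)


_TRANSFORMS = {
    "log": _safe_log,
    "reciprocal": _safe_recip,
    "sqrt": _safe_sqrt,
}


def _to_positive(v: np.ndarray) -> np.ndarray:
    """Shift a variable to strict positivity (min maps to 1) when needed."""
    m = v.min()
    return v - m + 1.0 if m <= 0 else v


def _finite_pair_test(col: _Collector, tx: np.ndarray, ty: np.ndarray, label: str) -> None:
    ok = np.isfinite(tx) & np.isfinite(ty)
    if ok.sum() < 4:
        col.skipped += 1
        col.notes.append(f"{label}: fewer than 4 usable observations")
        return
    col.add(ols_slope, tx[ok], ty[ok], label=label)


def s7_transformation(bundle: DatasetBundle, gate_on_normality: bool = False,
                      targets: tuple[str, ...] = ("x", "y", "both"),
                      positivity: str = "drop",
                      alpha: float = DEFAULT_ALPHA) -> StrategyRun:
    """Original slope test, then log / reciprocal / square-root transforms of
    the predictor, the outcome, or both.

    ``positivity`` governs how non-positive values meet log/sqrt/reciprocal:
    ``"drop"`` (default) leaves them undefined so each transformed analysis
    uses only the observations on which the transform exists — the candidate
    analyses then differ both in scale and in the analyzed subset, which is
    what makes this strategy severe; ``"shift"`` first translates the
    variable so its minimum maps to 1, a milder convention that keeps all
    observations.

    With ``gate_on_normality`` the transforms are only attempted when a
    Shapiro-Wilk test on the residuals of the planned fit is significant at
    0.05 — the data-driven justification a researcher would cite.
    """
    bundle.require("x", "y")
    bad = set(targets) - {"x", "y", "both"}
    if bad:
        raise InvalidArgumentError(f"unknown transformation target(s): {sorted(bad)}")
    if positivity not in {"drop", "shift"}:
        raise InvalidArgumentError(f"positivity must be 'drop' or 'shift', got {positivity!r}")
    x, y = bundle.x, bundle.y
    col = _Collector()
    orig = col.add(ols_slope, x, y)
    if orig is None:
        raise DegenerateDataError("planned regression is degenerate")
    if gate_on_normality:
        xd = x - x.mean()
        slope = (xd * (y - y.mean())).sum() / (xd**2).sum()
        resid = (y - y.mean()) - slope * xd
        if shapiro_wilk_p(resid) >= 0.05:
            return col.run("s7", {**bundle.condition, "gated": True, "targets": targets},
                           alpha)
    xin = _to_positive(x) if positivity == "shift" else x
    yin = _to_positive(y) if positivity == "shift" else y
    for tname, tf in _TRANSFORMS.items():
        for target in targets:
            tx = tf(xin) if target in {"x", "both"} else x
            ty = tf(yin) if target in {"y", "both"} else y
            _finite_pair_test(col, tx, ty, f"{tname}_{target}")
    return col.run("s7", {**bundle.condition, "gated": gate_on_normality,
                          "targets": targets}, alpha)


# --- strategy 8: discretizing variables ---------------------------------------

def s8_discretization(bundle: DatasetBundle, alpha: float = DEFAULT_ALPHA) -> StrategyRun:
    """Continuous slope test, median-split t test, tertile-split ANOVA, and
    extreme-tertiles ("cut the middle") t test on the same predictor."""
    bundle.require("x", "y")
    x, y = bundle.x, bundle.y
    if np.ptp(x) <= 1e-12:
        raise DegenerateDataError("constant predictor: splits undefined")
    col = _Collector()
    col.add(ols_slope, x, y)
    med = np.median(x)
    col.add(student_t, y[x <= med], y[x > med])
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    lo, mid, hi = y[x <= q1], y[(x > q1) & (x <= q2)], y[x > q2]
    col.add(anova_f, [lo, mid, hi])
    col.add(student_t, lo, hi)
    return col.run("s8", bundle.condition, alpha)


# --- strategy 9: exploiting alternative hypothesis tests ----------------------

def s9_alternative_tests(bundle: DatasetBundle,
                         trims: tuple[float, ...] = (0.1, 0.15, 0.2, 0.25),
                         alpha: float = DEFAULT_ALPHA) -> StrategyRun:
    """Student t (planned), Welch, Wilcoxon rank-sum, and Yuen at each
    trimming proportion, all on the same two groups."""
    bundle.require("group1", "group2")
    g1, g2 = bundle.group1[:, 0], bundle.group2[:, 0]
    col = _Collector()
    col.add(student_t, g1, g2)
    col.add(welch_t, g1, g2)
    col.add(wilcoxon_rank_sum, g1, g2)
    for tr in trims:
        col.add(yuen_t, g1, g2, tr)
    return col.run("s9", {**bundle.condition, "trims": tuple(trims)}, alpha)


# --- strategy 10: favourable imputation ---------------------------------------

def s10_imputation(bundle: DatasetBundle, k_methods: int = 3,
                   alpha: float = DEFAULT_ALPHA,
                   rng: RngStream | None = None) -> StrategyRun:
    """Planned analysis = slope test after listwise deletion; then one slope
    test per completion from ``k_methods`` imputation methods sampled
    without replacement (a sampled listwise duplicate of the planned test is
    not re-added)."""
    bundle.require("x", "y")
    if bundle.missing_mask_x is None or bundle.missing_mask_y is None:
        raise InvalidArgumentError("bundle carries no missingness masks; apply_mcar first")
    roster = imp.list_methods()
    if not 1 <= k_methods <= len(roster):
        raise InvalidArgumentError(f"k_methods must lie in 1..{len(roster)}")
    if k_methods < len(roster):
        if rng is None:
            raise InvalidArgumentError("subsampling methods requires an RngStream")
        idx = rng.generator.choice(len(roster), size=k_methods, replace=False)
        methods = [roster[i] for i in sorted(idx)]
    else:
        methods = roster
    x, y = bundle.x, bundle.y
    mx, my = bundle.missing_mask_x, bundle.missing_mask_y
    col = _Collector()
    xc, yc = imp.impute(imp.get_method("listwise"), x, y, mx, my)
    col.add(ols_slope, xc, yc, label="listwise_planned")
    for i, m in enumerate(methods):
        if m.name == "listwise":
            continue
        try:
            xi, yi = imp.impute(m, x, y, mx, my,
                                rng.child(100 + i) if (rng is not None and m.stochastic) else None)
        except DegenerateDataError as exc:
            col.skipped += 1
            col.notes.append(str(exc))
            continue
        col.add(ols_slope, xi, yi, label=f"impute_{m.name}")
    return col.run("s10", {**bundle.condition, "k_methods": k_methods}, alpha)


# --- strategy 11: subgroup analyses -------------------------------------------

def s11_subgroups(bundle: DatasetBundle, alpha: float = DEFAULT_ALPHA,
                  min_cell: int = 3) -> StrategyRun:
    """Full-sample t test, then the t test within each level of every binary
    grouping variable; subgroup tests with a cell below ``min_cell`` are
    skipped (counted as non-significant)."""
    bundle.require("group1", "group2")
    g1, g2 = bundle.group1[:, 0], bundle.group2[:, 0]
    n = bundle.n
    col = _Collector()
    col.add(student_t, g1, g2)
    if bundle.grouping_vars is not None:
        for j in range(bundle.grouping_vars.shape[1]):
            lab = bundle.grouping_vars[:, j]
            l1, l2 = lab[:n], lab[n:]
            for level in (0, 1):
                a, b = g1[l1 == level], g2[l2 == level]
                if a.size < min_cell or b.size < min_cell:
                    col.skipped += 1
                    col.notes.append(f"grouping {j + 1} level {level}: cell below {min_cell}")
                    continue
                col.add(student_t, a, b)
    return col.run("s11", bundle.condition, alpha)


# --- strategy 12: incorrect rounding ------------------------------------------

def s12_incorrect_rounding(p: float, level: float,
                           alpha: float = DEFAULT_ALPHA) -> tuple[bool, float]:
    """Round a p-value just above the threshold down to significance.

    ``level`` is the largest p-value a researcher would round down; any
    ``alpha <= p < level`` is reported as ``alpha``, so the effective type I
    error rate equals ``level`` exactly.  Returns ``(significant, reported_p)``.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidArgumentError(f"p must lie in [0, 1], got {p}")
    if level < alpha:
        raise InvalidArgumentError(f"rounding level {level} below alpha {alpha}")
    if p < alpha:
        return True, p
    if p < level:
        return True, alpha
    return False, p


# --- registry / one-shot simulation -------------------------------------------

@dataclass(frozen=True)
class StrategyInfo:
    """Registry entry: display name, design family and a one-shot simulator."""

    label: str
    name: str
    design: str  # "ttest" | "regression" | "analytic"
    simulate: object  # callable(rng, alpha, **params) -> StrategyRun


def _sim_s1(rng, alpha, n=30, k_dv=3, r_dv=0.0):
    b = gen_two_group(n, k_dv=k_dv, r_dv=r_dv, rng=rng)
    return s1_selective_dv(b, alpha)


def _sim_s2(rng, alpha, n=30, k_iv=3, r_iv=0.0, design="ttest"):
    if design == "ttest":
        b = gen_two_group(n, k_dv=k_iv, r_dv=r_iv, rng=rng)
    else:
        b = gen_regression(n, k_items=k_iv, r_items=r_iv, rng=rng)
    return s2_selective_iv(b, design, alpha)


def _sim_s3(rng, alpha, n_min=5, n_max=30, step=5):
    return s3_optional_stopping(n_min, n_max, step, alpha, rng)


def _sim_s4(rng, alpha, n=30, k_methods=3):
    b = gen_regression(n, rng=rng.child(0))
    return s4_outlier_exclusion(b, k_methods, alpha, rng.child(1))


def _sim_s5(rng, alpha, n=30, k_cov=3, r_z=0.0, r_zy=0.0):
    b = gen_two_group(n, k_dv=1, k_cov=k_cov, r_z=r_z, r_zy=r_zy, rng=rng)
    return s5_covariates(b, alpha)


def _sim_s6(rng, alpha, n=30, k_items=5, r_items=0.3, m_max=1):
    b = gen_regression(n, k_items=k_items, r_items=r_items, rng=rng)
    return s6_scale_redefinition(b, m_max, alpha)


def _sim_s7(rng, alpha, n=30, gate_on_normality=False, targets=("x", "y", "both"),
            positivity="drop"):
    b = gen_regression(n, rng=rng)
    return s7_transformation(b, gate_on_normality, tuple(targets), positivity, alpha)


def _sim_s8(rng, alpha, n=30):
    b = gen_regression(n, rng=rng)
    return s8_discretization(b, alpha)


def _sim_s9(rng, alpha, n=30, trims=(0.1, 0.15, 0.2, 0.25)):
    b = gen_two_group(n, rng=rng)
    return s9_alternative_tests(b, tuple(trims), alpha)


def _sim_s10(rng, alpha, n=30, rho=0.05, k_methods=3):
    b = gen_regression(n, rng=rng.child(0))
    b = apply_mcar(b, rho, rng.child(1))
    return s10_imputation(b, k_methods, alpha, rng.child(2))


def _sim_s11(rng, alpha, n=30, k_groups=1):
    b = gen_two_group(n, k_groups=k_groups, rng=rng)
    return s11_subgroups(b, alpha)


def _sim_s12(rng, alpha, n=30, level=0.051):
    b = gen_two_group(n, rng=rng)
    res = student_t(b.group1[:, 0], b.group2[:, 0])
    significant, reported = s12_incorrect_rounding(res.p, level, alpha)
    reported_result = TestResult(reported, res.statistic, res.df, res.effect_size,
                                 "student_t_rounded", res.n_used)
    return StrategyRun("s12", [res, reported_result], {"n": n, "level": level},
                       alpha, success_override=significant)


STRATEGY_REGISTRY: dict[str, StrategyInfo] = {
    "s1": StrategyInfo("s1", "selective_dv", "ttest", _sim_s1),
    "s2": StrategyInfo("s2", "selective_iv", "ttest", _sim_s2),
    "s3": StrategyInfo("s3", "optional_stopping", "ttest", _sim_s3),
    "s4": StrategyInfo("s4", "outlier_exclusion", "regression", _sim_s4),
    "s5": StrategyInfo("s5", "covariates", "ttest", _sim_s5),
    "s6": StrategyInfo("s6", "scale_redefinition", "regression", _sim_s6),
    "s7": StrategyInfo("s7", "transformation", "regression", _sim_s7),
    "s8": StrategyInfo("s8", "discretization", "regression", _sim_s8),
    "s9": StrategyInfo("s9", "alternative_tests", "ttest", _sim_s9),
    "s10": StrategyInfo("s10", "imputation", "regression", _sim_s10),
    "s11": StrategyInfo("s11", "subgroups", "ttest", _sim_s11),
    "s12": StrategyInfo("s12", "incorrect_rounding", "ttest", _sim_s12),
}

_ALIASES = {info.name: label for label, info in STRATEGY_REGISTRY.items()}


def strategy_names() -> list[str]:
    return list(STRATEGY_REGISTRY)


def simulate_once(strategy: str, params: dict, alpha: float, rng: RngStream) -> StrategyRun:
    """Generate one null dataset and apply one strategy to it."""
    label = _ALIASES.get(strategy, strategy)
    if label not in STRATEGY_REGISTRY:
        raise InvalidArgumentError(f"unknown strategy {strategy!r}")
    return STRATEGY_REGISTRY[label].simulate(rng, alpha, **params)
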