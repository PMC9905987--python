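"""Monte-Carlo engines: condition grids, alpha comparison, chained workflows.

Every result is a pure function of (specification, seed).  Streams are
spawned hierarchically — ``(seed, [cell, rule, iteration])`` for grids — so
grid cells, reporting rules and iterations are statistically independent,
while re-running any subset reproduces it bit-identically.  In
:func:`compare_alpha` the *same* stream path is replayed at every
significance level, so the comparison uses common random numbers and the
observed ordering of false-positive rates across alphas is exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import strategies as strat
from .rngdata import (DatasetBundle, InvalidArgumentError, RngStream,
                      apply_mcar, gen_two_group, spawn_stream)
from .reportmetrics import REPORTING_RULES, SeverityEstimate, fp_rate, select_report
from .strategies import DEFAULT_ALPHA, StrategyRun, s12_incorrect_rounding

__all__ = [
    "GridResult", "WorkflowSpec", "WorkflowResult",
    "run_grid", "run_workflow", "builtin_scenario", "compare_alpha",
]


def expand_grid(condition_grid) -> list[dict]:
    """A dict of parameter lists becomes its cartesian product of cells."""
    if isinstance(condition_grid, dict):
        keys = list(condition_grid)
        vals = [v if isinstance(v, (list, tuple)) else [v] for v in condition_grid.values()]
        return [dict(zip(keys, combo)) for combo in itertools.product(*vals)]
    return [dict(c) for c in condition_grid]


@dataclass
class GridResult:
    """Per-cell severity estimates plus per-rule reported-p/effect summaries."""

    strategy: str
    table: pd.DataFrame
    seed: int
    alpha: float
    iterations: int
    pvalues: dict = field(default_factory=dict)   # (cell_idx, rule) -> reported p array
    effects: dict = field(default_factory=dict)   # (cell_idx, rule) -> reported effect array

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=1)


def run_grid(strategy: str, condition_grid, iterations: int = 10_000,
             seed: int = 0, alpha: float = DEFAULT_ALPHA,
             rules: tuple[str, ...] = REPORTING_RULES,
             collect: bool = True) -> GridResult:
    """Monte-Carlo estimate of one strategy's false-positive rate over a grid.

    Each cell runs ``iterations`` independent p-hacking attempts per
    reporting rule (the paper's convention: the pooled severity estimate
    uses all of them, since success does not depend on the rule, while each
    rule's reported-p distribution comes from its own iterations).
    Infeasible cells are marked failed and the run continues.
    """
    if iterations < 1:
        raise InvalidArgumentError("iterations must be >= 1")
    cells = expand_grid(condition_grid)
    rows = []
    pvals: dict = {}
    effects: dict = {}
    for ci, cell in enumerate(cells):
        successes = 0
        total = 0
        skipped = 0
        cell_failed = None
        for ri, rule in enumerate(rules):
            rep_p = np.empty(iterations)
            rep_eff = np.full(iterations, np.nan)
            for it in range(iterations):
                rng = spawn_stream(seed, [ci, ri, it])
                try:
                    run = strat.simulate_once(strategy, cell, alpha, rng)
                except InvalidArgumentError as exc:
                    cell_failed = str(exc)
                    break
                successes += run.success
                skipped += run.skipped
                total += 1
                sel = select_report(run, rule)
                rep_p[it] = sel.p
                if sel.effect_size is not None:
                    rep_eff[it] = sel.effect_size
            if cell_failed:
                break
            if collect:
                pvals[(ci, rule)] = rep_p
                effects[(ci, rule)] = rep_eff
        if cell_failed:
            rows.append({**cell, "failed": cell_failed, "fp_rate": np.nan,
                         "mc_se": np.nan, "iterations": total})
            continue
        phat = successes / total
        row = {**cell, "failed": None, "fp_rate": phat,
               "mc_se": float(np.sqrt(phat * (1 - phat) / total)),
               "iterations": total, "skipped_tests": skipped}
        for rule in rules:
            rp = pvals.get((ci, rule))
            if rp is not None:
                row[f"mean_reported_p_{rule}"] = float(rp.mean())
                row[f"share_sig_{rule}"] = float((rp < alpha).mean())
        rows.append(row)
    return GridResult(strategy, pd.DataFrame(rows), seed, alpha,
                      iterations, pvals, effects)


# --- workflows ----------------------------------------------------------------

@dataclass(frozen=True)
class WorkflowSpec:
    """An ordered chain of p-hacking stages applied to one dataset.

    ``rounding_level`` (if set) applies incorrect rounding at every stage:
    any candidate p below the level counts as a success.  ``data_params``
    parameterize the single shared dataset each iteration draws.
    """

    name: str
    design: str                     # "ttest" | "regression"
    n: int
    stages: tuple[tuple[str, dict], ...]
    rounding_level: float | None = None
    alpha: float = DEFAULT_ALPHA
    data_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stages:
            raise InvalidArgumentError("a workflow needs at least one stage")
        allowed = {"ttest": {"s9", "s1", "s5", "s11"},
                   "regression": {"s10", "s7", "s6", "s4"}}
        if self.design not in allowed:
            raise InvalidArgumentError(f"unknown design {self.design!r}")
        bad = [lab for lab, _ in self.stages if lab not in allowed[self.design]]
        if bad:
            raise InvalidArgumentError(
                f"stage(s) {bad} not compatible with the {self.design} design")


@dataclass
class WorkflowResult:
    """Cumulative success proportions after the planned test and each stage."""

    spec: WorkflowSpec
    table: pd.DataFrame          # rows: stage 0..S with cumulative_fp
    rounding_share: float        # fraction of successes that needed rounding
    iterations: int
    seed: int


def _ttest_workflow_bundle(spec: WorkflowSpec, rng: RngStream) -> DatasetBundle:
    p = spec.data_params
    return gen_two_group(spec.n, k_dv=p.get("k_dv", 1), r_dv=p.get("r_dv", 0.0),
                         k_cov=p.get("k_cov", 0), r_z=p.get("r_z", 0.0),
                         r_zy=p.get("r_zy", 0.0), k_groups=p.get("k_groups", 0),
                         rng=rng)


def _regression_workflow_data(spec: WorkflowSpec, rng: RngStream):
    """Predictor x, scale items, outcome y = item mean, MCAR masks on (x, y)."""
    p = spec.data_params
    k_items, r_items = p.get("k_items", 5), p.get("r_items", 0.3)
    g = rng.child(0).generator
    x = g.standard_normal(spec.n)
    shared = g.standard_normal((spec.n, 1))
    unique = g.standard_normal((spec.n, k_items))
    items = np.sqrt(r_items) * shared + np.sqrt(1.0 - r_items) * unique
    y = items.mean(axis=1)
    bundle = DatasetBundle(n=spec.n, x=x, y=y, items=items, condition={})
    rho = p.get("rho", 0.0)
    if rho > 0:
        bundle = apply_mcar(bundle, rho, rng.child(1))
    return bundle


def _run_stage(label: str, params: dict, bundle: DatasetBundle, alpha: float,
               rng: RngStream) -> StrategyRun:
    if label == "s9":
        return strat.s9_alternative_tests(bundle, tuple(params.get("trims", (0.2,))), alpha)
    if label == "s1":
        return strat.s1_selective_dv(bundle, alpha)
    if label == "s5":
        return strat.s5_covariates(bundle, alpha)
    if label == "s11":
        return strat.s11_subgroups(bundle, alpha)
    if label == "s10":
        return strat.s10_imputation(bundle, params.get("k_methods", 5), alpha, rng)
    if label == "s7":
        return strat.s7_transformation(bundle, params.get("gate_on_normality", False),
                                       tuple(params.get("targets", ("x", "y", "both"))),
                                       params.get("positivity", "drop"), alpha)
    if label == "s6":
        return strat.s6_scale_redefinition(bundle, params.get("m_max", 3), alpha)
    if label == "s4":
        return strat.s4_outlier_exclusion(bundle, params.get("k_methods", 3), alpha, rng)
    raise InvalidArgumentError(f"unknown workflow stage {label!r}")


def run_workflow(spec: WorkflowSpec, iterations: int = 10_000, seed: int = 0) -> WorkflowResult:
    """Apply the stages in order to one shared dataset per iteration, stopping
    at the first success; returns the cumulative false-positive proportion
    after the planned test (stage 0) and after each stage, and the share of
    successes that existed only thanks to per-stage incorrect rounding."""
    level = spec.rounding_level if spec.rounding_level is not None else spec.alpha
    n_stages = len(spec.stages)
    first_success = np.full(iterations, -1)      # stage index of first success
    by_rounding = np.zeros(iterations, dtype=bool)
    for it in range(iterations):
        rng = spawn_stream(seed, [0, it])
        if spec.design == "ttest":
            shared = _ttest_workflow_bundle(spec, rng.child(0))
            listwise = None
        else:
            shared = _regression_workflow_data(spec, rng.child(0))
            if shared.missing_mask_x is not None:
                keep = ~shared.missing_mask_x & ~shared.missing_mask_y
            else:
                keep = np.ones(spec.n, dtype=bool)
            listwise = DatasetBundle(n=int(keep.sum()), x=shared.x[keep],
                                     y=shared.y[keep], items=shared.items[keep],
                                     condition={})
        for si, (label, params) in enumerate(spec.stages, start=1):
            if spec.design == "regression" and label != "s10":
                if label == "s6":
                    # the scale is the outcome here; the slope test's p-value is
                    # symmetric in (predictor, outcome), so reuse the op with
                    # the items as the scale and x as the companion variable
                    stage_bundle = DatasetBundle(n=listwise.n, items=listwise.items,
                                                 y=listwise.x, condition={})
                else:
                    stage_bundle = listwise
            else:
                stage_bundle = shared
            run = _run_stage(label, params, stage_bundle, spec.alpha, rng.child(si))
            pvs = run.pvalues()
            if si == 1:
                # stage 0 = the planned analysis alone
                p0 = pvs[0]
                sig0, _ = s12_incorrect_rounding(p0, level, spec.alpha)
                if sig0:
                    first_success[it] = 0
                    by_rounding[it] = p0 >= spec.alpha
                    break
            if (pvs < level).any():
                first_success[it] = si
                by_rounding[it] = not (pvs < spec.alpha).any()
                break
    rows = []
    for stage in range(n_stages + 1):
        cum = ((first_success >= 0) & (first_success <= stage)).mean()
        label = "planned" if stage == 0 else spec.stages[stage - 1][0]
        rows.append({"stage": stage, "label": label, "cumulative_fp": float(cum)})
    n_success = int((first_success >= 0).sum())
    share = float(by_rounding.sum() / n_success) if n_success else 0.0
    return WorkflowResult(spec, pd.DataFrame(rows), share, iterations, seed)


def builtin_scenario(name: str) -> WorkflowSpec:
    """The two showcase workflows, frozen at medium aggressiveness (N = 100).

    ``ttest``: three alternative tests (Welch, Wilcoxon, Yuen 0.2), five DVs
    correlated 0.6, three covariates correlated 0.3 with each other and the
    DV, three binary grouping variables.  ``regression``: five random
    imputation methods on 10% MCAR data, unconditional transformations,
    up to three deletions from a five-item scale, three random outlier
    methods.  Both apply incorrect rounding at level 0.051 at every stage.
    """
    if name == "ttest":
        return WorkflowSpec(
            name="ttest", design="ttest", n=100,
            stages=(("s9", {"trims": (0.2,)}),
                    ("s1", {}),
                    ("s5", {}),
                    ("s11", {})),
            rounding_level=0.051,
            data_params={"k_dv": 5, "r_dv": 0.6, "k_cov": 3, "r_z": 0.3,
                         "r_zy": 0.3, "k_groups": 3},
        )
    if name == "regression":
        return WorkflowSpec(
            name="regression", design="regression", n=100,
            stages=(("s10", {"k_methods": 5}),
                    ("s7", {}),
                    ("s6", {"m_max": 3}),
                    ("s4", {"k_methods": 3})),
            rounding_level=0.051,
            data_params={"k_items": 5, "r_items": 0.3, "rho": 0.10},
        )
    raise InvalidArgumentError(f"unknown scenario {name!r}; choose 'ttest' or 'regression'")


# --- alpha comparison ---------------------------------------------------------

def compare_alpha(strategy: str, condition_grid, alphas: tuple[float, ...] = (0.05, 0.005),
                  iterations: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """False-positive rates of one strategy at several significance levels.

    The same stream path is replayed at every alpha (common random numbers),
    so within a cell the alphas see identical simulated datasets and the
    rate ordering across alphas is exact.  The ratio of the first to each
    other alpha's rate is attached.
    """
    if any(not 0 < a < 1 for a in alphas):
        raise InvalidArgumentError("alphas must lie in (0, 1)")
    cells = expand_grid(condition_grid)
    rows = []
    for ci, cell in enumerate(cells):
        rates = {}
        for a in alphas:
            succ = 0
            for it in range(iterations):
                rng = spawn_stream(seed, [ci, 0, it])
                run = strat.simulate_once(strategy, cell, a, rng)
                succ += run.success
            rates[a] = succ / iterations
        row = {**cell}
        for a in alphas:
            row[f"fp_rate_{a:g}"] = rates[a]
        base = alphas[0]
        for a in alphas[1:]:
            row[f"ratio_{base:g}_over_{a:g}"] = (
                rates[base] / rates[a] if rates[a] > 0 else np.inf)
        rows.append(row)
    return pd.DataFrame(rows)
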