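"""Reporting-strategy selection and diagnostic metrics.

A *reporting strategy* decides which of a batch of computed p-values a
researcher makes public: the first significant one, the smallest overall, or
the smallest significant one (reverting to the planned test when nothing is
significant).  The reporting strategy shapes the distribution of reported
p-values and effect sizes but — by construction — never the false-positive
rate, which depends only on whether *any* candidate was significant.

Also provided: the severity estimate (false-positive rate with Monte-Carlo
standard error), the p-curve (proportions of reported p-values in ten
0.01-wide bins over (0, 0.1]), and the default JZS Bayes factor for the
two-sample t test (Cauchy prior with scale r on the standardized effect,
Jeffreys prior on the variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .rngdata import InvalidArgumentError
from .stattests import TestResult
from .strategies import StrategyRun

__all__ = [
    "REPORTING_RULES",
    "SeverityEstimate",
    "PCurve",
    "select_report",
    "fp_rate",
    "p_curve",
    "bf_jzs_ttest",
    "effect_summary",
]

REPORTING_RULES = ("first_sig", "smallest", "smallest_sig")

DEFAULT_RSCALE = np.sqrt(2.0) / 2.0  # the "medium" default of common BF software


@dataclass(frozen=True)
class SeverityEstimate:
    """False-positive rate for one condition cell, with Monte-Carlo error."""

    fp_rate: float
    mc_se: float
    iterations: int
    condition: dict
    alpha: float


@dataclass(frozen=True)
class PCurve:
    """Proportions of reported p-values in the ten 0.01-wide bins over (0, 0.1]."""

    bin_edges: np.ndarray   # 11 edges, 0.00 .. 0.10
    proportions: np.ndarray  # 10 proportions of the full input


def select_report(run: StrategyRun, rule: str) -> TestResult:
    """The candidate a researcher following ``rule`` would report.

    ``first_sig``: first candidate with p < alpha, else the planned test;
    ``smallest``: global minimum p; ``smallest_sig``: smallest significant
    p, else the planned test.
    """
    if rule not in REPORTING_RULES:
        raise InvalidArgumentError(f"unknown reporting rule {rule!r}")
    cands = run.candidates
    if rule == "smallest":
        return min(cands, key=lambda c: c.p)
    sig = [c for c in cands if c.p < run.alpha]
    if not sig:
        return cands[0]
    return sig[0] if rule == "first_sig" else min(sig, key=lambda c: c.p)


def fp_rate(runs: list[StrategyRun]) -> SeverityEstimate:
    """Proportion of runs in which p-hacking succeeded, with binomial MC error."""
    if not runs:
        raise InvalidArgumentError("need at least one run")
    cond, alpha = runs[0].condition, runs[0].alpha
    for r in runs[1:]:
        if r.condition != cond or r.alpha != alpha:
            raise InvalidArgumentError("runs mix conditions; estimate each cell separately")
    n = len(runs)
    phat = sum(r.success for r in runs) / n
    return SeverityEstimate(phat, float(np.sqrt(phat * (1 - phat) / n)), n, cond, alpha)


def p_curve(pvalues) -> PCurve:
    """Proportions of all input p-values in (0, 0.01], (0.01, 0.02], ..., (0.09, 0.10]."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise InvalidArgumentError("empty p-value input")
    if ((p < 0) | (p > 1)).any():
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    edges = np.round(np.linspace(0.0, 0.1, 11), 10)
    props = np.array([((p > lo) & (p <= hi)).mean() for lo, hi in zip(edges[:-1], edges[1:])])
    return PCurve(edges, props)


def _jzs_integrand(g: np.ndarray, t: float, n_eff: float, nu: float, rscale: float):
    # g is the variance of the normal effect-size prior, mixed over an
    # inverse-gamma(1/2, rscale^2/2) to realise the Cauchy(0, rscale) prior.
    shrink = 1.0 + n_eff * g
    dens = stats.invgamma.pdf(g, 0.5, scale=rscale**2 / 2.0)
    return shrink**-0.5 * (1.0 + t**2 / (shrink * nu)) ** (-(nu + 1.0) / 2.0) * dens


def bf_jzs_ttest(t: float, n1: int, n2: int, rscale: float = DEFAULT_RSCALE) -> float:
    """Default JZS Bayes factor BF10 for the two-sample t test.

    Marginal likelihood under H1 integrates the scaled-t likelihood over the
    Jeffreys-Zellner-Siow prior (Cauchy with scale ``rscale`` on the
    standardized effect), evaluated by adaptive quadrature with relative
    tolerance 1e-6; H0 is the central t likelihood.  BF10 > 1 favours a
    group difference.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("need n1, n2 >= 2")
    if not np.isfinite(t):
        raise InvalidArgumentError(f"t must be finite, got {t}")
    if rscale <= 0:
        raise InvalidArgumentError("rscale must be positive")
    n_eff = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    null_like = (1.0 + t**2 / nu) ** (-(nu + 1.0) / 2.0)
    alt_like, err = integrate.quad(_jzs_integrand, 0.0, np.inf,
                                   args=(float(t), n_eff, nu, rscale),
                                   epsrel=1e-6, limit=200)
    if not np.isfinite(alt_like) or alt_like <= 0 or err > max(1e-6 * alt_like, 1e-12):
        raise ArithmeticError(
            f"JZS integral did not converge (value={alt_like}, abserr={err}, "
            f"t={t}, n1={n1}, n2={n2}, rscale={rscale})")
    return float(alt_like / null_like)


def effect_summary(runs: list[StrategyRun], rule: str, rscale: float = DEFAULT_RSCALE,
                   with_bf: bool = False) -> pd.DataFrame:
    """Reported and original p-values and effect sizes under one reporting rule.

    One row per run: the planned analysis and the candidate selected by
    ``rule``; with ``with_bf`` a JZS Bayes factor is attached wherever the
    selected candidate is a two-group t test (statistic interpretable as t).
    """
    if not runs:
        raise InvalidArgumentError("need at least one run")
    strategy = runs[0].strategy
    if any(r.strategy != strategy for r in runs):
        raise InvalidArgumentError("runs mix designs/strategies")
    rows = []
    for r in runs:
        sel = select_report(r, rule)
        orig = r.original
        row = {
            "reported_p": sel.p, "original_p": orig.p,
            "reported_effect": sel.effect_size, "original_effect": orig.effect_size,
            "reported_label": sel.test_label, "n_used": sel.n_used,
            "success": r.success,
        }
        if with_bf:
            for key, res in (("reported_bf10", sel), ("original_bf10", orig)):
                if res.test_label.startswith(("student_t", "welch_t")) and np.isfinite(res.statistic):
                    n_half = res.n_used // 2
                    row[key] = bf_jzs_ttest(res.statistic, n_half, res.n_used - n_half, rscale)
                else:
                    row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
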