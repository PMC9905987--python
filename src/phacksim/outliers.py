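"""Outlier-detection techniques with subjective threshold escalation.

Twelve detection techniques are registered, spanning the families commonly
used around a univariate regression of y on x: four univariate rules applied
per variable (SD-from-mean, boxplot/IQR fences, MAD robust z, percentile
cut), seven regression-influence diagnostics (standardized and externally
studentized residuals, leverage, Cook's distance, DFFITS, DFBETAS of the
slope, covariance ratio), and the bivariate Mahalanobis distance.  The exact
roster and cut-offs are a declared, configurable registry — textbook
defaults throughout (e.g. Belsley/Kuh/Welsch size-adjusted cut-offs for the
influence measures, type-7 interpolated quartiles for the IQR fences).

"Subjective threshold setting" is modelled as an escalation ladder: start
at a lenient cut-off and tighten it stepwise (e.g. 2.0, 2.5, 3.0 SDs) until
no observation is flagged; each non-empty rung yields candidate exclusions.
Exclusion is a single-step procedure: flags are always computed on the
original data, never re-detected on a reduced dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats as sps

from .rngdata import InvalidArgumentError

__all__ = [
    "OutlierMethod",
    "ExclusionCandidate",
    "DegenerateSpreadWarning",
    "list_methods",
    "get_method",
    "detect",
    "escalation_ladder",
    "candidate_exclusions",
]

_EPS = 1e-12
_MAX_LADDER = 60  # safety cap; geometric/additive ladders terminate long before


class DegenerateSpreadWarning(UserWarning):
    """Emitted when a spread estimate (SD, MAD, IQR) is zero and nothing can be flagged."""


@dataclass(frozen=True)
class OutlierMethod:
    """One registered detection technique.

    ``kind`` is ``univariate`` (applied per variable), ``influence``
    (regression diagnostics of y ~ x) or ``bivariate``.  The escalation is
    either an explicit tuple of levels (possibly sample-size dependent, see
    :meth:`thresholds`) or a base threshold plus an additive/multiplicative
    step.
    """

    name: str
    kind: str
    base_threshold: float | None = None
    escalation_step: tuple[str, float] | None = None  # ("add", 0.5) or ("mul", 1.25)
    levels: tuple[float, ...] | None = None           # explicit ladder
    size_adjusted: bool = False                       # levels scale with k/n
    description: str = ""

    def thresholds(self, n: int) -> Iterator[float]:
        """Yield the escalation ladder's cut-offs, lenient first."""
        k = 2  # parameters of the simple regression (intercept + slope)
        if self.levels is not None:
            for lv in self.levels:
                yield lv * (k / n) if self.size_adjusted else lv
            return
        t = self.base_threshold
        if self.name == "cooks_distance":
            yield 4.0 / n
            yield 1.0
            return
        if self.name == "dffits":
            t = 2.0 * np.sqrt(k / n)
        elif self.name == "dfbeta_slope":
            t = 2.0 / np.sqrt(n)
        op, step = self.escalation_step
        for _ in range(_MAX_LADDER):
            yield t
            t = t + step if op == "add" else t * step


_REGISTRY: tuple[OutlierMethod, ...] = (
    OutlierMethod("sd", "univariate", 2.0, ("add", 0.5),
                  description="|value - mean| / SD"),
    OutlierMethod("iqr", "univariate", 1.5, ("add", 0.5),
                  description="boxplot fences at Q1/Q3 -/+ t*IQR (type-7 quartiles)"),
    OutlierMethod("mad", "univariate", 2.0, ("add", 0.5),
                  description="robust z: |value - median| / (1.4826*MAD)"),
    OutlierMethod("percentile", "univariate", levels=(0.025, 0.01, 0.005),
                  description="outside the [t, 1-t] empirical quantiles per tail"),
    OutlierMethod("standardized_residual", "influence", 2.0, ("add", 0.5),
                  description="|e_i| / s"),
    OutlierMethod("studentized_residual", "influence", 2.0, ("add", 0.5),
                  description="externally studentized residual"),
    OutlierMethod("leverage", "influence", levels=(2.0, 3.0), size_adjusted=True,
                  description="hat value > c*k/n"),
    OutlierMethod("cooks_distance", "influence",
                  description="Cook's D > 4/n, then 1.0"),
    OutlierMethod("dffits", "influence", escalation_step=("mul", 1.25),
                  description="|DFFITS| > 2*sqrt(k/n), escalated x1.25"),
    OutlierMethod("dfbeta_slope", "influence", escalation_step=("mul", 1.25),
                  description="|DFBETAS(slope)| > 2/sqrt(n), escalated x1.25"),
    OutlierMethod("covratio", "influence", levels=(3.0,), size_adjusted=True,
                  description="|COVRATIO - 1| > 3k/n (single level)"),
    OutlierMethod("mahalanobis", "bivariate",
                  levels=tuple(sps.chi2.ppf([0.975, 0.99, 0.999], df=2)),
                  description="squared Mahalanobis distance of (x, y) vs chi2(2) quantiles"),
)


def list_methods() -> list[OutlierMethod]:
    """The registered roster of 12 detection techniques."""
    return list(_REGISTRY)


def get_method(name: str) -> OutlierMethod:
    for m in _REGISTRY:
        if m.name == name:
            return m
    raise InvalidArgumentError(f"unknown outlier method {name!r}")


def _warn_degenerate(what: str) -> np.ndarray:
    warnings.warn(f"degenerate spread ({what}); no outliers flagged", DegenerateSpreadWarning,
                  stacklevel=3)
    return np.zeros(0, dtype=int)


def _univariate_stat(name: str, v: np.ndarray) -> np.ndarray | None:
    if name == "sd":
        sd = v.std(ddof=1)
        return None if sd <= _EPS else np.abs(v - v.mean()) / sd
    if name == "mad":
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        return None if mad <= _EPS else np.abs(v - med) / (1.4826 * mad)
    if name == "iqr":
        q1, q3 = np.quantile(v, [0.25, 0.75])  # type-7 (linear) interpolation
        iqr = q3 - q1
        return None if iqr <= _EPS else np.maximum(q1 - v, v - q3) / iqr
    raise InvalidArgumentError(f"not a stat-form univariate method: {name}")


def _regression_diagnostics(x: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    """Influence measures of the simple regression y ~ x, computed in closed form."""
    n = x.size
    k = 2
    xd = x - x.mean()
    sxx = (xd**2).sum()
    if sxx <= _EPS:
        raise InvalidArgumentError("constant predictor: influence measures undefined")
    slope = (xd * (y - y.mean())).sum() / sxx
    resid = (y - y.mean()) - slope * xd
    h = 1.0 / n + xd**2 / sxx
    sse = (resid**2).sum()
    s2 = sse / (n - k)
    if s2 <= _EPS:
        zeros = np.zeros(n)
        return {"standardized_residual": zeros, "studentized_residual": zeros,
                "leverage": h, "cooks_distance": zeros, "dffits": zeros,
                "dfbeta_slope": zeros, "covratio_dev": zeros}
    one_minus_h = np.clip(1.0 - h, _EPS, None)
    s2_i = np.clip((sse - resid**2 / one_minus_h) / (n - k - 1), _EPS, None)
    t_ext = resid / np.sqrt(s2_i * one_minus_h)
    stand = np.abs(resid) / np.sqrt(s2)
    cooks = resid**2 / (k * s2) * h / one_minus_h**2
    dffits = np.abs(t_ext) * np.sqrt(h / one_minus_h)
    dfbetas = np.abs(resid * xd / one_minus_h / sxx) / np.sqrt(s2_i / sxx)
    covratio = (s2_i / s2) ** k / one_minus_h
    return {"standardized_residual": stand, "studentized_residual": np.abs(t_ext),
            "leverage": h, "cooks_distance": cooks, "dffits": dffits,
            "dfbeta_slope": dfbetas, "covratio_dev": np.abs(covratio - 1.0)}


def _mahalanobis_sq(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    m = np.column_stack([x, y])
    cov = np.cov(m, rowvar=False)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        return np.zeros(x.size)
    d = m - m.mean(axis=0)
    return np.einsum("ij,jk,ik->i", d, inv, d)


def detect(method: OutlierMethod, x, y, threshold: float, variable: str = "x") -> np.ndarray:
    """Indices flagged by ``method`` at the given cut-off.

    Univariate methods examine the variable named by ``variable`` ("x" or
    "y"); influence and bivariate methods flag observations jointly and
    ignore ``variable``.  A zero spread estimate yields an empty set with a
    :class:`DegenerateSpreadWarning`.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 5:
        raise InvalidArgumentError("need matched x, y with n >= 5")
    if method.kind == "univariate":
        if variable not in {"x", "y"}:
            raise InvalidArgumentError("variable must be 'x' or 'y'")
        v = x if variable == "x" else y
        if method.name == "percentile":
            lo, hi = np.quantile(v, [threshold, 1.0 - threshold])
            if hi - lo <= _EPS:
                return _warn_degenerate("zero inter-quantile range")
            return np.flatnonzero((v < lo) | (v > hi))
        stat = _univariate_stat(method.name, v)
        if stat is None:
            return _warn_degenerate(f"{method.name} spread is zero")
        return np.flatnonzero(stat > threshold)
    if method.kind == "influence":
        diag = _regression_diagnostics(x, y)
        key = "covratio_dev" if method.name == "covratio" else method.name
        return np.flatnonzero(diag[key] > threshold)
    if method.kind == "bivariate":
        return np.flatnonzero(_mahalanobis_sq(x, y) > threshold)
    raise InvalidArgumentError(f"unknown method kind {method.kind!r}")


def _flags_at(method: OutlierMethod, x, y, threshold: float) -> dict[str, np.ndarray]:
    """Flag sets per exclusion path at one threshold."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateSpreadWarning)
        if method.kind == "univariate":
            fx = detect(method, x, y, threshold, "x")
            fy = detect(method, x, y, threshold, "y")
            return {"x": fx, "y": fy, "both": np.union1d(fx, fy)}
        joint = detect(method, x, y, threshold)
        return {"joint": joint}


def escalation_ladder(method: OutlierMethod, x, y) -> list[float]:
    """Cut-offs from lenient to strict, ending before the first all-clear level.

    The ladder contains every cut-off whose flagged set (union over the x
    and y sweeps for univariate methods) is non-empty; the terminal empty
    level is not part of the ladder.  Explicit-level methods stop at their
    last registered level regardless.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ladder: list[float] = []
    for t in method.thresholds(x.size):
        flags = _flags_at(method, x, y, t)
        total = flags["both"] if "both" in flags else flags["joint"]
        if total.size == 0:
            break
        ladder.append(float(t))
    return ladder


@dataclass(frozen=True)
class ExclusionCandidate:
    """One candidate analysis dataset produced by removing flagged rows."""

    excluded: frozenset
    threshold: float
    path: str  # "x", "y", "both" or "joint"
    method: str

    def apply(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        keep = np.ones(x.size, dtype=bool)
        keep[list(self.excluded)] = False
        return x[keep], y[keep]


def candidate_exclusions(method: OutlierMethod, x, y) -> list[ExclusionCandidate]:
    """All candidate exclusion sets for one method across its escalation ladder.

    For univariate methods each ladder rung contributes up to three
    candidates (rows flagged in x, in y, and in either); influence and
    bivariate methods contribute one per rung.  Duplicated exclusion sets
    are collapsed, empty sets are skipped, and candidates leaving fewer
    than 4 observations are dropped.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    seen: set[frozenset] = set()
    out: list[ExclusionCandidate] = []
    for t in escalation_ladder(method, x, y):
        for path, idx in _flags_at(method, x, y, t).items():
            excl = frozenset(int(i) for i in idx)
            if not excl or excl in seen or n - len(excl) < 4:
                continue
            seen.add(excl)
            out.append(ExclusionCandidate(excl, float(t), path, method.name))
    return out
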