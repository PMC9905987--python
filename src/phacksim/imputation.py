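"""Missing-data handling methods exploited by the favourable-imputation strategy.

Ten methods are registered, spanning the common families: deletion,
single-value replacement (mean/median), donor-based (hot deck, predictive
mean matching, k-nearest-neighbour), model-based single imputation
(deterministic and stochastic regression, EM under bivariate normality) and
an averaged multiple imputation.  All methods operate on the bivariate
(x, y) record with MCAR masks; observed entries are never modified (listwise
deletion removes rows instead).

Multiple imputation is collapsed to the mean of m = 5 stochastic-regression
completions rather than Rubin's-rules pooling: the surrounding strategy
needs a single p-value per candidate analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rngdata import DegenerateDataError, InvalidArgumentError, RngStream

__all__ = ["ImputationMethod", "list_methods", "get_method", "impute", "em_parameters"]

_EPS = 1e-12


@dataclass(frozen=True)
class ImputationMethod:
    name: str
    stochastic: bool = False
    description: str = ""


_REGISTRY: tuple[ImputationMethod, ...] = (
    ImputationMethod("listwise", False, "drop rows with any missing entry"),
    ImputationMethod("mean", False, "replace by the observed mean"),
    ImputationMethod("median", False, "replace by the observed median"),
    ImputationMethod("hot_deck", True, "random draw from the observed values"),
    ImputationMethod("regression", False, "deterministic regression on the companion variable"),
    ImputationMethod("stochastic_regression", True, "regression prediction + normal residual noise"),
    ImputationMethod("pmm", False, "predictive mean matching (nearest-prediction donor)"),
    ImputationMethod("knn", False, "mean of the k=5 nearest neighbours on the companion variable"),
    ImputationMethod("em", False, "EM under bivariate normality, conditional-mean completion"),
    ImputationMethod("mi_mean", True, "mean of m=5 stochastic-regression completions"),
)


def list_methods() -> list[ImputationMethod]:
    return list(_REGISTRY)


def get_method(name: str) -> ImputationMethod:
    for m in _REGISTRY:
        if m.name == name:
            return m
    raise InvalidArgumentError(f"unknown imputation method {name!r}")


def _check(x, y, mx, my):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    mx = np.asarray(mx, dtype=bool).ravel()
    my = np.asarray(my, dtype=bool).ravel()
    if not (x.size == y.size == mx.size == my.size):
        raise InvalidArgumentError("x, y and masks must share length")
    if (~mx).sum() < 2 or (~my).sum() < 2:
        raise DegenerateDataError("fewer than 2 observed values in a variable")
    return x, y, mx, my


def _ols(pred: np.ndarray, resp: np.ndarray) -> tuple[float, float, float]:
    """Intercept, slope and residual SD of resp ~ pred (on complete pairs)."""
    pd_ = pred - pred.mean()
    sxx = (pd_**2).sum()
    if sxx <= _EPS:
        return resp.mean(), 0.0, resp.std(ddof=1)
    slope = (pd_ * (resp - resp.mean())).sum() / sxx
    intercept = resp.mean() - slope * pred.mean()
    resid = resp - intercept - slope * pred
    df = max(pred.size - 2, 1)
    return intercept, slope, float(np.sqrt((resid**2).sum() / df))


def _regression_fill(v: np.ndarray, mask: np.ndarray, companion: np.ndarray,
                     comp_mask: np.ndarray, noise_sd: bool, g) -> np.ndarray:
    """Fill masked v from a regression on the companion; companion-missing rows get the mean."""
    out = v.copy()
    both = ~mask & ~comp_mask
    if both.sum() < 3:
        out[mask] = v[~mask].mean()
        return out
    a, b, s = _ols(companion[both], v[both])
    fill_rows = mask & ~comp_mask
    out[fill_rows] = a + b * companion[fill_rows]
    out[mask & comp_mask] = v[~mask].mean()
    if noise_sd:
        out[mask] = out[mask] + g.normal(0.0, s, size=int(mask.sum()))
    return out


def _pmm_fill(v: np.ndarray, mask: np.ndarray, companion: np.ndarray, comp_mask: np.ndarray) -> np.ndarray:
    out = v.copy()
    both = ~mask & ~comp_mask
    if both.sum() < 3:
        out[mask] = v[~mask].mean()
        return out
    a, b, _ = _ols(companion[both], v[both])
    donor_pred = a + b * companion[both]
    donor_vals = v[both]
    for i in np.flatnonzero(mask):
        if comp_mask[i]:
            out[i] = v[~mask].mean()
        else:
            pred = a + b * companion[i]
            out[i] = donor_vals[np.argmin(np.abs(donor_pred - pred))]
    return out


def _knn_fill(v: np.ndarray, mask: np.ndarray, companion: np.ndarray, comp_mask: np.ndarray,
              k: int = 5) -> np.ndarray:
    out = v.copy()
    donors = ~mask & ~comp_mask
    if donors.sum() < 1:
        out[mask] = v[~mask].mean()
        return out
    dc, dv = companion[donors], v[donors]
    for i in np.flatnonzero(mask):
        if comp_mask[i]:
            out[i] = v[~mask].mean()
        else:
            nearest = np.argsort(np.abs(dc - companion[i]))[: min(k, dc.size)]
            out[i] = dv[nearest].mean()
    return out


def em_parameters(x, y, mx, my, tol: float = 1e-6, max_iter: int = 200):
    """Maximum-likelihood mean and covariance of a bivariate normal with
    MCAR-missing entries, fitted by EM (returns ``(mu, cov)``)."""
    x, y, mx, my = _check(x, y, mx, my)
    xs = np.where(mx, np.nanmean(x[~mx]), x)
    ys = np.where(my, np.nanmean(y[~my]), y)
    mu = np.array([xs.mean(), ys.mean()])
    cov = np.cov(np.column_stack([xs, ys]), rowvar=False)
    n = x.size
    for _ in range(max_iter):
        ex, ey = np.where(mx, 0.0, x), np.where(my, 0.0, y)
        exx = np.zeros(n)
        eyy = np.zeros(n)
        exy = np.zeros(n)
        vx, vy, cxy = cov[0, 0], cov[1, 1], cov[0, 1]
        only_x = mx & ~my   # x missing, y observed
        only_y = my & ~mx
        both = mx & my
        if vy > _EPS:
            ex[only_x] = mu[0] + cxy / vy * (y[only_x] - mu[1])
            resid_var_x = max(vx - cxy**2 / vy, 0.0)
        else:
            ex[only_x] = mu[0]
            resid_var_x = vx
        if vx > _EPS:
            ey[only_y] = mu[1] + cxy / vx * (x[only_y] - mu[0])
            resid_var_y = max(vy - cxy**2 / vx, 0.0)
        else:
            ey[only_y] = mu[1]
            resid_var_y = vy
        ex[both], ey[both] = mu
        exx[:] = ex**2
        eyy[:] = ey**2
        exy[:] = ex * ey
        exx[only_x] += resid_var_x
        eyy[only_y] += resid_var_y
        exx[both] += vx
        eyy[both] += vy
        exy[both] += cxy
        mu_new = np.array([ex.mean(), ey.mean()])
        cov_new = np.array([
            [exx.mean() - mu_new[0] ** 2, exy.mean() - mu_new[0] * mu_new[1]],
            [exy.mean() - mu_new[0] * mu_new[1], eyy.mean() - mu_new[1] ** 2],
        ])
        delta = max(np.abs(mu_new - mu).max(), np.abs(cov_new - cov).max())
        mu, cov = mu_new, cov_new
        if delta < tol:
            break
    return mu, cov


def _em_bivariate(x, y, mx, my):
    """Conditional-mean completion under the EM-fitted bivariate normal."""
    mu, cov = em_parameters(x, y, mx, my)
    xs, ys = x.copy(), y.copy()
    vx, vy, cxy = cov[0, 0], cov[1, 1], cov[0, 1]
    fill_x = mx & ~my
    fill_y = my & ~mx
    xs[fill_x] = mu[0] + (cxy / vy if vy > _EPS else 0.0) * (y[fill_x] - mu[1])
    ys[fill_y] = mu[1] + (cxy / vx if vx > _EPS else 0.0) * (x[fill_y] - mu[0])
    xs[mx & my] = mu[0]
    ys[mx & my] = mu[1]
    return xs, ys


def impute(method: ImputationMethod, x, y, missing_mask_x, missing_mask_y,
           rng: RngStream | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One completed ``(x, y)`` pair under the given method.

    Deterministic methods depend on data only; stochastic methods (hot deck,
    stochastic regression, averaged MI) additionally require an
    :class:`~phacksim.rngdata.RngStream`.  ``listwise`` returns the reduced
    complete-case vectors.
    """
    x, y, mx, my = _check(x, y, missing_mask_x, missing_mask_y)
    if method.stochastic:
        if rng is None:
            raise InvalidArgumentError(f"method {method.name!r} requires an RngStream")
        g = rng.generator
    name = method.name
    if name == "listwise":
        keep = ~mx & ~my
        return x[keep], y[keep]
    if name == "mean":
        return (np.where(mx, x[~mx].mean(), x), np.where(my, y[~my].mean(), y))
    if name == "median":
        return (np.where(mx, np.median(x[~mx]), x), np.where(my, np.median(y[~my]), y))
    if name == "hot_deck":
        xs, ys = x.copy(), y.copy()
        xs[mx] = g.choice(x[~mx], size=int(mx.sum()), replace=True)
        ys[my] = g.choice(y[~my], size=int(my.sum()), replace=True)
        return xs, ys
    if name == "regression":
        return (_regression_fill(x, mx, y, my, False, None),
                _regression_fill(y, my, x, mx, False, None))
    if name == "stochastic_regression":
        return (_regression_fill(x, mx, y, my, True, g),
                _regression_fill(y, my, x, mx, True, g))
    if name == "pmm":
        return _pmm_fill(x, mx, y, my), _pmm_fill(y, my, x, mx)
    if name == "knn":
        return _knn_fill(x, mx, y, my), _knn_fill(y, my, x, mx)
    if name == "em":
        return _em_bivariate(x, y, mx, my)
    if name == "mi_mean":
        m = 5
        acc_x = np.zeros(int(mx.sum()))
        acc_y = np.zeros(int(my.sum()))
        for _ in range(m):
            acc_x += _regression_fill(x, mx, y, my, True, g)[mx]
            acc_y += _regression_fill(y, my, x, mx, True, g)[my]
        xs, ys = x.copy(), y.copy()
        xs[mx] = acc_x / m
        ys[my] = acc_y / m
        return xs, ys
    raise InvalidArgumentError(f"unknown imputation method {name!r}")
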