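"""Seeded random-number streams and synthetic null-data generators.

All simulated datasets in this package are drawn under the global null: no
mean difference between groups and a true slope of zero.  Every generator is
a pure function of its arguments and an :class:`RngStream`, so any simulation
result can be reproduced bit-identically from a single integer seed.

Streams are hierarchical: a top-level seed plus an integer *path* (e.g.
``[condition_index, iteration_index]``) identifies a statistically
independent substream.  This enables common random numbers across compared
conditions — e.g. evaluating the same simulated datasets at two significance
levels — which turns "the false-positive rate does not depend on the
reporting strategy" into an exact, not merely statistical, statement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RngStream",
    "DatasetBundle",
    "spawn_stream",
    "mvn_compound_symmetry",
    "gen_two_group",
    "gen_regression",
    "apply_mcar",
    "write_bundle_csv",
]


class InvalidArgumentError(ValueError):
    """Raised when a generator or test receives an out-of-contract argument."""


class DegenerateDataError(ValueError):
    """Raised when data admit no well-defined test statistic (zero variance etc.)."""


@dataclass(frozen=True)
class RngStream:
    """A reproducible random substream identified by ``(seed, path)``.

    Identical ``(seed, path)`` pairs always produce identical draw
    sequences; distinct paths under one seed are statistically independent
    (numpy ``SeedSequence`` spawn-key semantics).
    """

    seed: int
    path: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise InvalidArgumentError(f"seed must be a non-negative integer, got {self.seed!r}")
        if any((not isinstance(p, (int, np.integer))) or p < 0 for p in self.path):
            raise InvalidArgumentError(f"path entries must be non-negative integers, got {self.path!r}")
        object.__setattr__(self, "path", tuple(int(p) for p in self.path))

    @property
    def generator(self) -> np.random.Generator:
        """A fresh generator positioned at the start of this substream."""
        return np.random.Generator(np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=self.path)))

    def child(self, *path: int) -> "RngStream":
        """Extend the path, yielding an independent substream."""
        return RngStream(self.seed, self.path + tuple(int(p) for p in path))


def spawn_stream(seed: int, path: Sequence[int] = ()) -> RngStream:
    """Create the substream identified by ``(seed, path)``."""
    return RngStream(int(seed), tuple(path))


@dataclass
class DatasetBundle:
    """One synthetic null dataset; components are populated per design.

    Two-group designs fill ``group1``/``group2`` (n_per_group x k_dv),
    optionally ``covariates`` (2n x k_cov, row-aligned with the stacked
    groups) and ``grouping_vars`` (2n x k_groups of 0/1 labels).  Regression
    designs fill ``x``, ``y`` and optionally the ``items`` matrix whose row
    means define ``x``.  ``missing_mask_x``/``missing_mask_y`` mark MCAR
    entries; the underlying values are preserved so oracles can compare
    imputed against complete data.
    """

    n: int
    group1: np.ndarray | None = None
    group2: np.ndarray | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    items: np.ndarray | None = None
    covariates: np.ndarray | None = None
    grouping_vars: np.ndarray | None = None
    missing_mask_x: np.ndarray | None = None
    missing_mask_y: np.ndarray | None = None
    condition: dict = field(default_factory=dict)

    def require(self, *names: str) -> None:
        missing = [nm for nm in names if getattr(self, nm) is None]
        if missing:
            raise InvalidArgumentError(f"bundle lacks required component(s): {', '.join(missing)}")


def _check_corr(name: str, r: float) -> float:
    r = float(r)
    if not 0.0 <= r <= 1.0:
        raise InvalidArgumentError(f"{name} must lie in [0, 1], got {r}")
    return r


def mvn_compound_symmetry(n: int, k: int, r: float, rng: RngStream) -> np.ndarray:
    """Draw an ``n x k`` matrix of standard-normal columns with common pairwise correlation ``r``.

    Uses the one-factor representation X_j = sqrt(r) * Z0 + sqrt(1-r) * Z_j,
    which realises the compound-symmetric correlation matrix exactly for
    r in [0, 1] without a Cholesky factorisation.
    """
    if n < 2 or k < 1:
        raise InvalidArgumentError(f"need n >= 2 and k >= 1, got n={n}, k={k}")
    r = _check_corr("r", r)
    g = rng.generator
    shared = g.standard_normal((n, 1))
    unique = g.standard_normal((n, k))
    return np.sqrt(r) * shared + np.sqrt(1.0 - r) * unique


def _cs_block(k: int, r: float) -> np.ndarray:
    m = np.full((k, k), r)
    np.fill_diagonal(m, 1.0)
    return m


def _joint_corr(k_dv: int, r_dv: float, k_cov: int, r_z: float, r_zy: float) -> np.ndarray:
    """Joint correlation matrix of (DVs, covariates); raises if not PSD."""
    k = k_dv + k_cov
    m = np.empty((k, k))
    m[:k_dv, :k_dv] = _cs_block(k_dv, r_dv)
    m[k_dv:, k_dv:] = _cs_block(k_cov, r_z)
    m[:k_dv, k_dv:] = r_zy
    m[k_dv:, :k_dv] = r_zy
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise InvalidArgumentError(
            f"implied correlation matrix is not positive semi-definite for "
            f"r_dv={r_dv}, r_z={r_z}, r_zy={r_zy} (k_dv={k_dv}, k_cov={k_cov})"
        )
    return m


def _mvn_from_corr(n: int, corr: np.ndarray, g: np.random.Generator) -> np.ndarray:
    # eigh-based factor tolerates exactly-singular targets (e.g. r = 1)
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    return g.standard_normal((n, corr.shape[0])) @ factor.T


def gen_two_group(
    n_per_group: int,
    k_dv: int = 1,
    r_dv: float = 0.0,
    k_cov: int = 0,
    r_z: float = 0.0,
    r_zy: float = 0.0,
    k_groups: int = 0,
    rng: RngStream | None = None,
) -> DatasetBundle:
    """Generate a null two-group design with optional covariates and grouping variables.

    DVs and covariates are drawn jointly for all ``2 * n_per_group``
    participants so that covariate-covariate correlation is ``r_z`` and
    covariate-DV correlation is ``r_zy``; group membership for the two
    *experimental* groups is balanced by construction, while incidental
    grouping variables are fair Bernoulli draws per participant (subgroup
    sizes may differ).
    """
    if rng is None:
        raise InvalidArgumentError("an RngStream is required")
    if n_per_group < 2 or k_dv < 1 or k_cov < 0 or k_groups < 0:
        raise InvalidArgumentError("need n_per_group >= 2, k_dv >= 1, k_cov >= 0, k_groups >= 0")
    for nm, v in (("r_dv", r_dv), ("r_z", r_z), ("r_zy", r_zy)):
        _check_corr(nm, v)
    g = rng.generator
    n_total = 2 * n_per_group
    if k_cov > 0:
        corr = _joint_corr(k_dv, r_dv, k_cov, r_z, r_zy)
        joint = _mvn_from_corr(n_total, corr, g)
        dvs, covs = joint[:, :k_dv], joint[:, k_dv:]
    else:
        shared = g.standard_normal((n_total, 1))
        unique = g.standard_normal((n_total, k_dv))
        dvs = np.sqrt(r_dv) * shared + np.sqrt(1.0 - r_dv) * unique
        covs = None
    groups = g.integers(0, 2, size=(n_total, k_groups)) if k_groups > 0 else None
    return DatasetBundle(
        n=n_per_group,
        group1=dvs[:n_per_group],
        group2=dvs[n_per_group:],
        covariates=covs,
        grouping_vars=groups,
        condition={"n": n_per_group, "k_dv": k_dv, "r_dv": r_dv, "k_cov": k_cov,
                   "r_z": r_z, "r_zy": r_zy, "k_groups": k_groups},
    )


def gen_regression(n: int, k_items: int = 1, r_items: float = 0.0, rng: RngStream | None = None) -> DatasetBundle:
    """Generate a null univariate-regression design.

    ``y`` is standard normal and independent of the items; items are
    compound-symmetric at ``r_items``.  The predictor ``x`` is the row mean
    of the items when ``k_items > 1``, else a single standard-normal draw.
    The true slope of ``y`` on ``x`` is zero.
    """
    if rng is None:
        raise InvalidArgumentError("an RngStream is required")
    if n < 4 or k_items < 1:
        raise InvalidArgumentError(f"need n >= 4 and k_items >= 1, got n={n}, k_items={k_items}")
    _check_corr("r_items", r_items)
    g = rng.generator
    y = g.standard_normal(n)
    if k_items > 1:
        shared = g.standard_normal((n, 1))
        unique = g.standard_normal((n, k_items))
        items = np.sqrt(r_items) * shared + np.sqrt(1.0 - r_items) * unique
        x = items.mean(axis=1)
    else:
        items = None
        x = g.standard_normal(n)
    return DatasetBundle(n=n, x=x, y=y, items=items,
                         condition={"n": n, "k_items": k_items, "r_items": r_items})


def apply_mcar(
    bundle: DatasetBundle,
    rho: float,
    rng: RngStream,
    mask_vars: str = "both",
) -> DatasetBundle:
    """Mask entries of ``x`` and/or ``y`` missing-completely-at-random at rate ``rho``.

    Values are preserved underneath the mask so that complete-data oracles
    remain available.  ``mask_vars`` selects which variables receive
    missingness ("x", "y" or "both"); each entry is masked independently.
    """
    bundle.require("x", "y")
    if not 0.0 <= rho < 1.0:
        raise InvalidArgumentError(f"rho must lie in [0, 1), got {rho}")
    if mask_vars not in {"x", "y", "both"}:
        raise InvalidArgumentError(f"mask_vars must be 'x', 'y' or 'both', got {mask_vars!r}")
    g = rng.generator
    n = len(bundle.x)
    mx = g.random(n) < rho if mask_vars in {"x", "both"} else np.zeros(n, dtype=bool)
    my = g.random(n) < rho if mask_vars in {"y", "both"} else np.zeros(n, dtype=bool)
    return replace(bundle, missing_mask_x=mx, missing_mask_y=my,
                   condition={**bundle.condition, "rho_missing": float(rho)})


def write_bundle_csv(bundle: DatasetBundle, path) -> None:
    """Emit a bundle as tidy CSV, one row per participant; masked cells are empty."""
    import pandas as pd

    cols: dict[str, np.ndarray] = {}
    if bundle.group1 is not None:
        n = bundle.n
        cols["group"] = np.repeat([1, 2], n)
        stacked = np.vstack([bundle.group1, bundle.group2])
        for j in range(stacked.shape[1]):
            cols[f"dv{j + 1}"] = stacked[:, j]
        if bundle.covariates is not None:
            for j in range(bundle.covariates.shape[1]):
                cols[f"z{j + 1}"] = bundle.covariates[:, j]
        if bundle.grouping_vars is not None:
            for j in range(bundle.grouping_vars.shape[1]):
                cols[f"g{j + 1}"] = bundle.grouping_vars[:, j]
    if bundle.x is not None:
        x = bundle.x.astype(float).copy()
        y = bundle.y.astype(float).copy()
        if bundle.missing_mask_x is not None:
            x[bundle.missing_mask_x] = np.nan
        if bundle.missing_mask_y is not None:
            y[bundle.missing_mask_y] = np.nan
        if bundle.items is not None:
            for j in range(bundle.items.shape[1]):
                cols[f"item{j + 1}"] = bundle.items[:, j]
        cols["x"] = x
        cols["y"] = y
    pd.DataFrame(cols).to_csv(path, index=False)
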