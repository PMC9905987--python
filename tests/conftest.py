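"""Shared helpers for the test suite.

Monte-Carlo checks use fixed seeds and iteration counts chosen so the whole
suite runs on one CPU in well under half an hour; binomial three-standard-
error bounds are computed at the iteration count actually used.
"""

from __future__ import annotations

import numpy as np
import pytest

import phacksim as ph


def mc_fp(strategy: str, params: dict, iterations: int, seed: int, alpha: float = 0.05,
          cell: int = 0) -> float:
    """Monte-Carlo false-positive rate of one strategy under one condition."""
    succ = 0
    for it in range(iterations):
        run = ph.simulate_once(strategy, params, alpha, ph.spawn_stream(seed, [cell, it]))
        succ += run.success
    return succ / iterations


def binom_3se(p: float, n: int) -> float:
    """Three binomial standard errors around a target proportion."""
    return 3.0 * np.sqrt(p * (1.0 - p) / n)


@pytest.fixture
def rng():
    return ph.spawn_stream(12345, [0])


def collect_runs(strategy: str, params: dict, iterations: int, seed: int,
                 alpha: float = 0.05, cell: int = 0) -> list:
    return [ph.simulate_once(strategy, params, alpha, ph.spawn_stream(seed, [cell, it]))
            for it in range(iterations)]
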