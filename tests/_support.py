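"""Shared helpers for the test suite: the standard fixture battery
(10 seeds x n in {8, 10, 12}) and model draws."""

from __future__ import annotations

import numpy as np

import rnascoredist as rsd
from rnascoredist.io import generate_fixture

COUNTING = rsd.EnergyModel.counting()

# the standard enumerable battery driving every oracle-equivalence check
SUITE = [(n, seed) for seed in range(10) for n in (8, 10, 12)]
SMALL_SUITE = [(n, seed) for seed in range(3) for n in (8, 10, 12)]


def fixture(n: int, seed: int):
    """Deterministic (sequence, reference) pair for the counting model."""
    return generate_fixture(n, seed, COUNTING)


def models_for(seed: int, draws: int = 3):
    """The counting model plus `draws` random thermodynamic models."""
    out = [COUNTING]
    for r in range(draws):
        out.append(rsd.random_model(np.random.default_rng(1000 * seed + r)))
    return out


def second_reference(n: int, seed: int):
    """An independent reference structure on the same length."""
    _, ref = generate_fixture(n, seed + 7777, COUNTING)
    return ref
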