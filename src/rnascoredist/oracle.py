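"""Brute-force reference path.

Enumerates the whole ensemble, weighs each structure with the energy
model, scores it with a direct structure-level function, and bins the
weights — the literal definition of the score distribution, independent
of the dynamic-programming engine (no recursion code is shared), and the
ground truth for every engine test on enumerable sequences.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .energy import EnergyModel
from .landscape import Distribution2D
from .score_engine import ScoreDistribution
from .structures import ENUMERATION_CAP, RnaSequence, SecondaryStructure, \
    enumerate_structures


def oracle_partition(seq: RnaSequence, model: EnergyModel,
                     cap: int = ENUMERATION_CAP) -> float:
    """Partition function by direct summation of structure weights."""
    return sum(
        model.structure_weight(seq, s)
        for s in enumerate_structures(seq, model, cap=cap)
    )


def oracle_distribution(seq: RnaSequence, model: EnergyModel,
                        score_fn: Callable[[SecondaryStructure], object],
                        dim: int = 1, s_max=None,
                        cap: int = ENUMERATION_CAP):
    """Exact score distribution by exhaustive enumeration.

    ``score_fn`` maps a structure to an integer (dim 1) or a pair of
    integers (dim 2).  ``s_max`` defaults to the maximum observed score.
    """
    scored: list[tuple[object, float]] = []
    for s in enumerate_structures(seq, model, cap=cap):
        w = model.structure_weight(seq, s)
        if w != 0.0:
            scored.append((score_fn(s), w))
    if dim == 1:
        top = max(sc for sc, _ in scored) if s_max is None else s_max
        z = np.zeros(top + 1)
        for sc, w in scored:
            z[sc] += w
        return ScoreDistribution(z, top)
    if dim == 2:
        if s_max is None:
            top1 = max(sc[0] for sc, _ in scored)
            top2 = max(sc[1] for sc, _ in scored)
        else:
            top1, top2 = s_max
        z = np.zeros((top1 + 1, top2 + 1))
        for (s1, s2), w in scored:
            z[s1, s2] += w
        return Distribution2D(z, top1, top2)
    raise ValueError("dim must be 1 or 2")
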