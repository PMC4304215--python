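"""Plain partition-function dynamic programming.

Fills the five tables Z, Z1, Zb, Zm, Zm1 over all intervals and returns
Z = Z_{1,n}, the partition function of the Boltzmann ensemble.  This is
the scalar specialization of the score-accumulable engine: evaluating the
engine at x = 1 (or with an all-zero scoring scheme) must reproduce it
exactly, and its value must equal the brute-force sum of structure
weights on enumerable sequences — both identities are enforced in the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._dp import fill_real
from .energy import EnergyModel
from .structures import RnaSequence

OVERFLOW_GUARD = 1e290


class Weights(NamedTuple):
    """x-free Boltzmann weight tables shared by every backend."""

    span: int
    apair: np.ndarray  # (n+2, n+2) int8
    WH: np.ndarray     # (n+2, n+2) float64
    Wint: np.ndarray   # (span+1, span+1) float64
    WM3: np.ndarray    # (n+2, n+2) float64
    Wm4: np.ndarray    # (n+1,) float64


def build_weights(seq: RnaSequence, model: EnergyModel) -> Weights:
    """Precompute all loop Boltzmann factors for one sequence/model."""
    n = seq.n
    span = int(min(model.max_interior_span, n))
    apair = model.pair_matrix(seq)
    WH = np.zeros((n + 2, n + 2))
    WM3 = np.zeros((n + 2, n + 2))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if apair[i, j]:
                WH[i, j] = model.w_hairpin(seq, i, j)
                WM3[i, j] = model.w_multi_close(seq, i, j)
    Wint = np.zeros((span + 1, span + 1))
    for a in range(span + 1):
        for b in range(span + 1 - a):
            if a == 0 and b == 0:
                Wint[a, b] = np.exp(-model.stack / model.kT)
            else:
                Wint[a, b] = np.exp(
                    -(model.interior_a + model.interior_b * (a + b)) / model.kT
                )
    Wm4 = np.array([model.w_multi_unpaired(u) for u in range(n + 1)])
    return Weights(span, apair, WH, Wint, WM3, Wm4)


@dataclass
class PartitionMatrices:
    """The five triangular DP tables, 1-based in both indices."""

    n: int
    Z: np.ndarray
    Z1: np.ndarray
    Zb: np.ndarray
    Zm: np.ndarray
    Zm1: np.ndarray

    @property
    def partition(self) -> float:
        return float(self.Z[1, self.n])


def compute_partition(
    seq: RnaSequence, model: EnergyModel
) -> tuple[PartitionMatrices, float]:
    """Partition function of *seq* under *model*.

    Returns the filled tables and Z = Z_{1,n}.  Values are kept in linear
    space; a warning is emitted when Z approaches the float64 ceiling.
    """
    w = build_weights(seq, model)
    Z, Z1, Zb, Zm, Zm1 = fill_real(seq.n, w.span, w.apair, w.WH, w.Wint, w.WM3, w.Wm4)
    mats = PartitionMatrices(seq.n, Z, Z1, Zb, Zm, Zm1)
    total = mats.partition
    if total > OVERFLOW_GUARD:
        warnings.warn(
            f"partition function {total:.3e} is close to float64 overflow; "
            "results may be unreliable",
            RuntimeWarning,
        )
    return mats, total
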