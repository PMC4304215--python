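"""2D folding landscapes: joint distribution of the Hamming distances from
two reference structures.

The scalar engine is lifted to 2-vector scores: every gain becomes the
pair of the two references' Hamming gains, the generating function is
evaluated on the full grid of root-of-unity pairs (x1, x2), and the
coefficients are recovered by a separable 2D inverse DFT.  Axis limits
are the exact per-reference d_max values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .energy import EnergyModel
from .errors import InputError
from .hamming import compute_dmax, make_hamming_scheme
from .score_engine import (
    CombinedScheme,
    EngineWorkspace,
    ScoreDistribution,
    _extract_real,
    dft_points,
)
from .structures import RnaSequence, SecondaryStructure


@dataclass
class Distribution2D:
    """Joint weights z[S1, S2] and probabilities over the score grid."""

    z: np.ndarray  # (s1_max+1, s2_max+1)
    s1_max: int = field(default=-1)
    s2_max: int = field(default=-1)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.s1_max < 0:
            self.s1_max = self.z.shape[0] - 1
        if self.s2_max < 0:
            self.s2_max = self.z.shape[1] - 1
        if self.z.shape != (self.s1_max + 1, self.s2_max + 1):
            raise InputError("weight matrix shape does not match score bounds")

    @cached_property
    def Z(self) -> float:
        return float(self.z.sum())

    @cached_property
    def p(self) -> np.ndarray:
        return self.z / self.Z

    def marginal(self, axis: int) -> ScoreDistribution:
        """Marginal over the other axis; equals the corresponding 1D
        Hamming distribution."""
        if axis == 0:
            return ScoreDistribution(self.z.sum(axis=1), self.s1_max)
        if axis == 1:
            return ScoreDistribution(self.z.sum(axis=0), self.s2_max)
        raise InputError("axis must be 0 or 1")


def make_2d_scheme(ref1: SecondaryStructure,
                   ref2: SecondaryStructure) -> CombinedScheme:
    """2-vector scheme scoring (d(., ref1), d(., ref2)) componentwise."""
    if ref1.n != ref2.n:
        raise InputError(
            f"reference lengths differ: {ref1.n} vs {ref2.n}"
        )
    return CombinedScheme(make_hamming_scheme(ref1), make_hamming_scheme(ref2))


def landscape_distribution(seq: RnaSequence, ref1: SecondaryStructure,
                           ref2: SecondaryStructure, model: EnergyModel,
                           jobs: int = 1) -> Distribution2D:
    """Exact joint distribution of Hamming distances from two references.

    Evaluates the engine at the (d1_max+1) x (d2_max+1) grid of
    root-of-unity pairs (row-major; points independent) and applies a
    separable 2D inverse DFT with the same tolerance checks as the 1D
    extraction.
    """
    scheme = make_2d_scheme(ref1, ref2)
    scheme.comp1.s_max = compute_dmax(seq, ref1, model)
    scheme.comp2.s_max = compute_dmax(seq, ref2, model)
    scheme.s_max = (scheme.comp1.s_max, scheme.comp2.s_max)
    ws = EngineWorkspace(seq, model, scheme)
    zeta = dft_points(ws, jobs=jobs)
    N1, N2 = zeta.shape
    zraw = np.fft.fft2(zeta) / (N1 * N2)
    z = _extract_real(zraw, scale=abs(zeta[0, 0]))
    return Distribution2D(z, scheme.comp1.s_max, scheme.comp2.s_max)
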