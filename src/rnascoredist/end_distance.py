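"""Distribution of the 5'-3' (end-to-end) distance.

The distance of a structure is the length of the walk through its
exterior loop: one unit per covalent backbone bond and one per hydrogen
bridge of an exterior pair.  Only the exterior recursions accumulate
score:

    g1(i, j) = j - i          open chain on [i, j]
    g2(i, j, k) = 1           junction bond between k and k+1 (the split
                              of the exterior segment; 0 for the empty
                              prefix, where no junction exists)
    g3(i, j, k) = 1 + j - k   exterior pair (i, k) plus the unpaired tail
    g4..g9 = 0                interior transitions never touch the walk

Since g4..g9 vanish, the tables Zb, Zm, Zm1 are x-free; the optimized
driver computes them once with the scalar DP and recomputes only Z1 and
the Z row per evaluation point, which leaves results bit-identical to
the full engine.  s_max = n - 1 exactly (the open chain realizes it).
"""

from __future__ import annotations

import numpy as np

from ._dp import fill_point_ext, fill_real
from .energy import EnergyModel
from .errors import InputError
from .score_engine import (
    GainTables,
    ScoreDistribution,
    ScoringScheme,
    _finish_tables,
    distribution_dft,
    distribution_poly,
    inverse_dft,
)
from .structures import RnaSequence


class EndDistanceScheme(ScoringScheme):
    """Gain functions for the 5'-3' distance; s_max = n - 1."""

    def __init__(self, n: int):
        super().__init__(n, s_max=max(n - 1, 0))

    def g1(self, i, j):
        return j - i

    def g2(self, i, j, k):
        return 1 if k >= i else 0

    def g3(self, i, j, k):
        return 1 + j - k

    def tables(self) -> GainTables:
        n = self.n
        idx = np.arange(n + 2, dtype=np.int32)
        I = idx[:, None, None]
        J = idx[None, :, None]
        K = idx[None, None, :]
        zeros2 = np.zeros((n + 2, n + 2), np.int32)
        zeros3 = np.zeros((n + 2, n + 2, n + 2), np.int32)
        G1 = np.clip(idx[None, :] - idx[:, None], 0, None).astype(np.int32)
        G2 = (K >= I).astype(np.int32) * np.ones_like(zeros3)
        G3 = np.clip(1 + J - K, 0, n - 1).astype(np.int32) * np.ones_like(zeros3)
        return _finish_tables(n, G1, G2, G3, zeros2, zeros2, zeros2,
                              zeros3, zeros3, zeros3, zeros3)


def make_end_distance_scheme(n: int) -> EndDistanceScheme:
    return EndDistanceScheme(n)


def end_distance_distribution(seq: RnaSequence, model: EnergyModel,
                              backend: str = "dft", optimized: bool = True,
                              jobs: int = 1) -> ScoreDistribution:
    """Exact 5'-3' distance distribution over the Boltzmann ensemble.

    With the default DFT backend the x-free tables are precomputed once
    and shared across all evaluation points; ``optimized=False`` runs the
    unrestricted engine instead (identical results).
    """
    scheme = make_end_distance_scheme(seq.n)
    if backend == "poly":
        return distribution_poly(seq, model, scheme)
    if backend != "dft":
        raise InputError(f"unknown backend {backend!r}")
    if not optimized:
        return distribution_dft(seq, model, scheme, jobs=jobs)
    from .mccaskill import build_weights  # local import avoids cycle at import time

    n = seq.n
    w = build_weights(seq, model)
    _, _, Zb, _, _ = fill_real(n, w.span, w.apair, w.WH, w.Wint, w.WM3, w.Wm4)
    # fold the multiloop tail weight pattern: Zm/Zm1 are not needed by the
    # exterior recursions, only Zb is.
    t = scheme.tables()
    N = scheme.s_max + 1
    zeta = np.empty(N, dtype=np.complex128)
    for S in range(N):
        x = np.exp(2j * np.pi * S / N)
        P = x ** np.arange(t.width)
        zeta[S] = fill_point_ext(n, P, Zb, w.Wm4, t.G1, t.G2, t.G3)
    return ScoreDistribution(inverse_dft(zeta), scheme.s_max)
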