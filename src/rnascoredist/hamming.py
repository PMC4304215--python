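"""Distribution of base-pair Hamming distances from a reference structure.

Every decomposition step of the partition DP decides the pairing status
of a definite set of structure-vector cells that no sub-state has decided
yet: the cells separated by a split boundary or covered by an unpaired
stretch are fixed to 0, and a pair-creating term fixes its own cell (i,j)
to 1.  The gain of a step is therefore

    (# reference pairs among the cells fixed to 0)  +  (1 - S[i][j])

for the created pair (equivalently, counting the cell (i,j) in the fixed
region first and correcting with 1 - 2 S[i][j]).  Summed along any parse,
the gains add up to the XOR count between the structure's vector and the
reference's — the Hamming distance.  All region counts reduce to O(1)
lookups in a 2D prefix-sum table of the reference pairs.

s_max for the engine is the exact ensemble maximum d_max, obtained from
the max-plus transform of the same recursions in cubic time.
"""

from __future__ import annotations

import numpy as np

from ._dp import fill_maxplus
from .energy import EnergyModel
from .errors import InputError
from .mccaskill import build_weights
from .score_engine import (
    GainTables,
    ScoreDistribution,
    ScoringScheme,
    _finish_tables,
    distribution_dft,
    distribution_poly,
)
from .structures import RnaSequence, SecondaryStructure


class ReferencePrefixSums:
    """2D cumulative table over the reference pair matrix.

    C[a, b] counts reference pairs (p, q) with p <= a and q <= b, so any
    rectangle query is four lookups.
    """

    def __init__(self, ref: SecondaryStructure):
        self.n = ref.n
        self.num_pairs = ref.num_pairs
        S = ref.pair_matrix()  # (n+2, n+2), entries only at i < j
        self.C = np.cumsum(np.cumsum(S[: self.n + 1, : self.n + 1], 0), 1)

    def region_pair_count(self, i1: int, i2: int, j1: int, j2: int) -> int:
        """Number of reference pairs (p, q) with p in [i1, i2], q in [j1, j2].
        Degenerate (empty) ranges return 0."""
        i1, j1 = max(i1, 1), max(j1, 1)
        i2, j2 = min(i2, self.n), min(j2, self.n)
        if i2 < i1 or j2 < j1:
            return 0
        C = self.C
        return int(C[i2, j2] - C[i1 - 1, j2] - C[i2, j1 - 1] + C[i1 - 1, j1 - 1])


def region_pair_count(P: ReferencePrefixSums, i1, i2, j1, j2) -> int:
    return P.region_pair_count(i1, i2, j1, j2)


def _interval_count_table(ref: SecondaryStructure) -> np.ndarray:
    """T[i, j] = number of reference pairs lying entirely inside [i, j]
    (0 whenever j <= i or indices leave [1, n]); shape (n+2, n+2)."""
    n = ref.n
    S = ref.pair_matrix()
    T = np.zeros((n + 2, n + 2), np.int32)
    for sp in range(1, n):
        for i in range(1, n + 1 - sp):
            j = i + sp
            T[i, j] = T[i + 1, j] + T[i, j - 1] - T[i + 1, j - 1] + S[i, j]
    return T


class HammingScheme(ScoringScheme):
    """Gain functions g1..g9 for the Hamming distance from one reference."""

    def __init__(self, ref: SecondaryStructure, s_max: int | None = None):
        super().__init__(ref.n, s_max)
        self.ref = ref
        self.prefix = ReferencePrefixSums(ref)
        self._T = _interval_count_table(ref)
        self._S = ref.pair_matrix()

    # region counts written via the prefix-sum object (O(1) each); the
    # T table is the same quantity specialized to full intervals.

    def _within(self, i, j):
        return self.prefix.region_pair_count(i, j, i, j)

    def g1(self, i, j):
        # open chain on [i, j]: every cell inside fixed to 0
        return self._within(i, j)

    def g2(self, i, j, k):
        # split [i, k] | [k+1, j]: cross cells fixed to 0 (k = i-1: empty prefix)
        return self.prefix.region_pair_count(i, k, k + 1, j)

    def g3(self, i, j, k):
        # leftmost pair ends at k, tail [k+1, j] unpaired
        return self.prefix.region_pair_count(i, j, k + 1, j)

    def g4(self, i, j):
        # hairpin: all cells in [i, j] fixed, (i, j) itself to 1
        return self._within(i, j) + 1 - 2 * int(self._S[i, j])

    def g5_outer(self, i, j):
        return self._within(i, j) + 1 - 2 * int(self._S[i, j])

    def g5_inner(self, k, l):
        return -self._within(k, l)

    def g6(self, i, j, k):
        # multiloop closure: matches the direct structure-vector sum
        # g6 = sum_{p=k}^{j-1} S[p][j] + sum_{q=i+1}^{j} S[i][q]
        #      + sum_{p=i+1}^{k-1} sum_{q=k}^{j} S[p][q] + 1 - 2 S[i][j]
        return (
            self._within(i, j)
            - self._within(i + 1, k - 1)
            - self._within(k, j - 1)
            + 1 - 2 * int(self._S[i, j])
        )

    def g7(self, i, j, k):
        # multiloop stretch [i, k-1] unpaired before the only remaining helix
        return self.prefix.region_pair_count(i, k - 1, i, j)

    def g8(self, i, j, k):
        # multiloop split [i, k-1] | [k, j]
        return (
            self._within(i, j) - self._within(i, k - 1) - self._within(k, j)
        )

    def g9(self, i, j, k):
        return self.g3(i, j, k)

    def tables(self) -> GainTables:
        """Vectorized gain tables; every gain is an affine combination of
        entries of the interval-count table T."""
        n = self.n
        T = self._T.astype(np.int32)
        B = (1 - 2 * self._S[: n + 2, : n + 2]).astype(np.int32)  # 1 - 2 S[i][j]
        A = T[:, :, None]          # T[i, j]
        T_ik = T[:, None, :]       # T[i, k]
        T_kj = T.T[None, :, :]     # T[k, j]
        # shifted views
        Tk1j = np.zeros_like(T)    # Tk1j[k, j] = T[k+1, j]
        Tk1j[: n + 1, :] = T[1: n + 2, :]
        Tik1 = np.zeros_like(T)    # Tik1[i, k] = T[i, k-1]
        Tik1[:, 1:] = T[:, : n + 1]
        Ti1k1 = np.zeros_like(T)   # Ti1k1[i, k] = T[i+1, k-1]
        Ti1k1[: n + 1, 1:] = T[1: n + 2, : n + 1]
        Tkj1 = np.zeros_like(T)    # Tkj1[k, j] = T[k, j-1]
        Tkj1[:, 1:] = T[:, : n + 1]

        G1 = T.copy()
        G4 = T + B
        G5a = T + B
        G5b = -T
        G2 = np.clip(A - T_ik - Tk1j.T[None, :, :], 0, None).astype(np.int32)
        G3 = np.clip(A - T_ik, 0, None).astype(np.int32)
        G9 = G3
        G6 = np.clip(
            A + B[:, :, None] - Ti1k1[:, None, :] - Tkj1.T[None, :, :], 0, None
        ).astype(np.int32)
        G7 = np.clip(A - T_kj, 0, None).astype(np.int32)
        G8 = np.clip(A - Tik1[:, None, :] - T_kj, 0, None).astype(np.int32)
        return _finish_tables(n, G1, G2, G3, G4, G5a, G5b, G6, G7, G8, G9)


def make_hamming_scheme(ref: SecondaryStructure, n: int | None = None) -> HammingScheme:
    """Scoring scheme for the Hamming distance from *ref*."""
    if n is not None and ref.n != n:
        raise InputError(f"reference length {ref.n} does not match n={n}")
    return HammingScheme(ref)


def compute_dmax(seq: RnaSequence, ref: SecondaryStructure,
                 model: EnergyModel) -> int:
    """Exact maximum Hamming distance from *ref* over the whole ensemble,
    via the max-plus transform of the recursions (cubic time)."""
    if ref.n != seq.n:
        raise InputError(f"reference length {ref.n} != sequence length {seq.n}")
    scheme = HammingScheme(ref)
    w = build_weights(seq, model)
    t = scheme.tables()
    d = fill_maxplus(seq.n, w.span, w.apair, w.WH, w.Wint, w.WM3, w.Wm4,
                     *t.as_args())
    dmax = int(round(d))
    if not 0 <= dmax <= seq.n:
        raise AssertionError(f"d_max={dmax} outside [0, n]")
    return dmax


def hamming_distribution(seq: RnaSequence, ref: SecondaryStructure,
                         model: EnergyModel, backend: str = "dft",
                         s_max: int | None = None,
                         jobs: int = 1) -> ScoreDistribution:
    """Exact distribution of Hamming distances from *ref* over the Boltzmann
    ensemble of *seq*.

    s_max defaults to the exact d_max; passing a looser bound (e.g. n)
    changes nothing but the number of evaluation points.
    """
    scheme = make_hamming_scheme(ref, seq.n)
    scheme.s_max = s_max if s_max is not None else compute_dmax(seq, ref, model)
    if backend == "dft":
        return distribution_dft(seq, model, scheme, jobs=jobs)
    if backend == "poly":
        return distribution_poly(seq, model, scheme)
    raise InputError(f"unknown backend {backend!r}")
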