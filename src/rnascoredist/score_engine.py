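"""Score-accumulable partition-function engine.

The McCaskill recursions are augmented so that every transition term is
multiplied by x^{g_k(.)}, where the nine integer gain functions g1..g9 of
a :class:`ScoringScheme` describe how much of the target score each
decomposition step contributes.  The final cell Z(x)_{1,n} is then the
generating polynomial sum_S z_S x^S of the score distribution, and two
backends extract the coefficients:

* ``poly``  — cells hold coefficient vectors of length s_max + 1; exact
  polynomial arithmetic (convolutions), O(n^3 s_max^2) time.
* ``dft``   — the polynomial is evaluated at the (s_max + 1)-th roots of
  unity x_S = exp(2*pi*i*S / (s_max + 1)) and the coefficients recovered
  by a single inverse discrete Fourier transform, O(n^3 s_max) time.
  Evaluation points are mutually independent, so they may be computed in
  any order or in parallel without changing the result.

For 2-vector scores the evaluation runs over the full grid of root-of-
unity pairs and the inverse transform is applied separably along each
axis.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from ._dp import fill_point
from .energy import EnergyModel
from .errors import InputError, NumericalError, ScoreBoundError
from .mccaskill import Weights, build_weights
from .structures import RnaSequence

IMAG_TOL = 1e-8
NEG_TOL = 1e-8


# ---------------------------------------------------------------------------
# gain tables
# ---------------------------------------------------------------------------

@dataclass
class GainTables:
    """Precomputed integer gains for every recursion term.

    G1, G4 are per-cell (i, j); G2, G3, G6, G7, G8, G9 per transition
    (i, j, k).  The interior-loop gain is stored in separated form,
    g5(i,j,k,l) = G5a[i,j] + G5b[k,l] (an engine requirement that keeps
    gain lookup O(1); both shipped features satisfy it).  ``width`` bounds
    every gain the kernels can read, and sizes the power table of an
    evaluation point.
    """

    n: int
    G1: np.ndarray
    G2: np.ndarray
    G3: np.ndarray
    G4: np.ndarray
    G5a: np.ndarray
    G5b: np.ndarray
    G6: np.ndarray
    G7: np.ndarray
    G8: np.ndarray
    G9: np.ndarray
    width: int

    def as_args(self) -> tuple:
        return (self.G1, self.G2, self.G3, self.G4, self.G5a,
                self.G5b, self.G6, self.G7, self.G8, self.G9)


class ScoringScheme:
    """Integer gain functions attached to the recursion terms.

    Subclasses implement g1(i,j), g2(i,j,k), g3(i,j,k), g4(i,j),
    g5_outer(i,j), g5_inner(k,l), g6(i,j,k), g7(i,j,k), g8(i,j,k),
    g9(i,j,k); the interior gain is g5 = g5_outer + g5_inner.  Every total
    gain must be a non-negative integer bounded by s_max.  ``s_max`` is
    supplied by the feature (exact maximum of the score over the
    ensemble), never guessed by the engine.
    """

    dim = 1

    def __init__(self, n: int, s_max: int | None = None):
        self.n = n
        self.s_max = s_max

    # per-term gains; subclasses override the relevant ones
    def g1(self, i, j): return 0
    def g2(self, i, j, k): return 0
    def g3(self, i, j, k): return 0
    def g4(self, i, j): return 0
    def g5_outer(self, i, j): return 0
    def g5_inner(self, k, l): return 0
    def g6(self, i, j, k): return 0
    def g7(self, i, j, k): return 0
    def g8(self, i, j, k): return 0
    def g9(self, i, j, k): return 0

    def g5(self, i, j, k, l):
        return self.g5_outer(i, j) + self.g5_inner(k, l)

    def tables(self) -> GainTables:
        """Materialize the gains; the generic path loops over all valid
        (i, j, k), so feature schemes override it with vectorized builders."""
        n = self.n
        G1 = np.zeros((n + 2, n + 2), np.int32)
        G4 = np.zeros((n + 2, n + 2), np.int32)
        G5a = np.zeros((n + 2, n + 2), np.int32)
        G5b = np.zeros((n + 2, n + 2), np.int32)
        G2, G3, G6, G7, G8, G9 = (
            np.zeros((n + 2, n + 2, n + 2), np.int32) for _ in range(6)
        )
        for i in range(1, n + 1):
            for j in range(i, n + 1):
                G1[i, j] = self.g1(i, j)
                if j > i:
                    G4[i, j] = self.g4(i, j)
                    G5a[i, j] = self.g5_outer(i, j)
                    G5b[i, j] = self.g5_inner(i, j)
                for k in range(i - 1, j):
                    G2[i, j, k] = self.g2(i, j, k)
                for k in range(i + 1, j + 1):
                    G3[i, j, k] = self.g3(i, j, k)
                    G9[i, j, k] = self.g9(i, j, k)
                for k in range(i, j):
                    G7[i, j, k] = self.g7(i, j, k)
                    G8[i, j, k] = self.g8(i, j, k)
                for k in range(i + 2, j):
                    G6[i, j, k] = self.g6(i, j, k)
        return _finish_tables(n, G1, G2, G3, G4, G5a, G5b, G6, G7, G8, G9)


def _finish_tables(n, G1, G2, G3, G4, G5a, G5b, G6, G7, G8, G9) -> GainTables:
    width = int(max(
        G1.max(), G2.max(), G3.max(), G4.max(),
        G5a.max() + max(int(G5b.max()), 0),
        G6.max(), G7.max(), G8.max(), G9.max(),
    )) + 1
    return GainTables(n, G1, G2, G3, G4, G5a, G5b, G6, G7, G8, G9, width)


class CombinedScheme(ScoringScheme):
    """2-vector scheme: componentwise combination of two scalar schemes.

    Gains become pairs; for the kernels they are folded into a single
    index g = g_1 * W2 + g_2 (W2 the power-table width of component 2),
    so the same DP code serves scalar and vector scores.
    """

    dim = 2

    def __init__(self, comp1: ScoringScheme, comp2: ScoringScheme):
        if comp1.n != comp2.n:
            raise InputError("component schemes disagree on n")
        super().__init__(comp1.n)
        self.comp1 = comp1
        self.comp2 = comp2
        self.s_max = (comp1.s_max, comp2.s_max)

    def _pair(self, name, *a):
        return (getattr(self.comp1, name)(*a), getattr(self.comp2, name)(*a))

    def g1(self, i, j): return self._pair("g1", i, j)
    def g2(self, i, j, k): return self._pair("g2", i, j, k)
    def g3(self, i, j, k): return self._pair("g3", i, j, k)
    def g4(self, i, j): return self._pair("g4", i, j)
    def g5_outer(self, i, j): return self._pair("g5_outer", i, j)
    def g5_inner(self, k, l): return self._pair("g5_inner", k, l)
    def g5(self, i, j, k, l): return self._pair("g5", i, j, k, l)
    def g6(self, i, j, k): return self._pair("g6", i, j, k)
    def g7(self, i, j, k): return self._pair("g7", i, j, k)
    def g8(self, i, j, k): return self._pair("g8", i, j, k)
    def g9(self, i, j, k): return self._pair("g9", i, j, k)

    def component_tables(self) -> tuple[GainTables, GainTables]:
        return self.comp1.tables(), self.comp2.tables()

    def tables(self) -> GainTables:
        t1, t2 = self.component_tables()
        w2 = t2.width
        combined = [
            (a.astype(np.int64) * w2 + b).astype(np.int32)
            for a, b in zip(t1.as_args(), t2.as_args())
        ]
        out = GainTables(self.n, *combined, width=t1.width * t2.width)
        out.widths = (t1.width, t2.width)  # per-component power-table sizes
        return out


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    """Weights z_S and probabilities p_S = z_S / Z over scores 0..s_max."""

    z: np.ndarray
    s_max: int = field(default=-1)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.s_max < 0:
            self.s_max = len(self.z) - 1
        if len(self.z) != self.s_max + 1:
            raise InputError("weight vector length does not match s_max")

    @cached_property
    def Z(self) -> float:
        return float(self.z.sum())

    @cached_property
    def p(self) -> np.ndarray:
        return self.z / self.Z

    def mean(self) -> float:
        return float(np.arange(self.s_max + 1) @ self.p)

    def __len__(self) -> int:
        return self.s_max + 1


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class EngineWorkspace:
    """Weight and gain tables for one (sequence, model, scheme) triple."""

    def __init__(self, seq: RnaSequence, model: EnergyModel,
                 scheme: ScoringScheme,
                 weights: Weights | None = None,
                 tables: GainTables | None = None):
        self.seq = seq
        self.model = model
        self.scheme = scheme
        self.weights = weights if weights is not None else build_weights(seq, model)
        self.tables = tables if tables is not None else scheme.tables()

    def powers(self, x) -> np.ndarray:
        """Power table of the evaluation point (flattened outer product of
        per-component powers for 2-vector schemes)."""
        t = self.tables
        if self.scheme.dim == 1:
            x = complex(x)
            _check_unit(x)
            return x ** np.arange(t.width)
        x1, x2 = complex(x[0]), complex(x[1])
        _check_unit(x1)
        _check_unit(x2)
        w1, w2 = t.widths
        return np.outer(x1 ** np.arange(w1), x2 ** np.arange(w2)).ravel()

    def point(self, x) -> complex:
        w, t = self.weights, self.tables
        return fill_point(self.seq.n, w.span, self.powers(x), w.apair, w.WH,
                          w.Wint, w.WM3, w.Wm4, *t.as_args())


def _check_unit(x: complex) -> None:
    if abs(abs(x) - 1.0) > 1e-9:
        raise InputError(f"evaluation point {x} is not on the unit circle")


def evaluate_at_point(seq: RnaSequence, model: EnergyModel,
                      scheme: ScoringScheme, x) -> complex:
    """Z(x)_{1,n} of the score-accumulable recursions at one point x on the
    unit circle (a pair of points for 2-vector schemes).  At x = 1 this is
    the plain partition function."""
    return EngineWorkspace(seq, model, scheme).point(x)


def inverse_dft(zeta: np.ndarray) -> np.ndarray:
    """Recover coefficients z_S from evaluations at the roots of unity:

        z_S = (1 / (s_max+1)) * sum_r zeta_r exp(-2*pi*i*r*S / (s_max+1))

    Imaginary residues and small negatives are checked against tolerances
    relative to the total weight (zeta_0 = Z) and then discarded/clipped;
    violations raise :class:`NumericalError`.
    """
    zeta = np.asarray(zeta, dtype=np.complex128)
    zraw = np.fft.fft(zeta) / len(zeta)
    return _extract_real(zraw, scale=abs(zeta.flat[0]))


def _extract_real(zraw: np.ndarray, scale: float) -> np.ndarray:
    scale = max(scale, np.finfo(float).tiny)
    worst_imag = float(np.abs(zraw.imag).max())
    if worst_imag > IMAG_TOL * scale:
        raise NumericalError(
            f"imaginary residue {worst_imag:.3e} exceeds {IMAG_TOL:g} * Z "
            f"(Z ~ {scale:.3e})"
        )
    zreal = zraw.real.copy()
    worst_neg = float(zreal.min())
    if worst_neg < -NEG_TOL * scale:
        raise NumericalError(
            f"negative weight {worst_neg:.3e} exceeds -{NEG_TOL:g} * Z "
            f"(Z ~ {scale:.3e})"
        )
    return np.clip(zreal, 0.0, None)


def dft_points(workspace: EngineWorkspace, jobs: int = 1) -> np.ndarray:
    """Evaluate the generating function at every root-of-unity point
    (grid of point pairs for dim 2).  Points are independent; with
    jobs > 1 they are computed in worker threads, results identical."""
    scheme = workspace.scheme
    if scheme.dim == 1:
        N = scheme.s_max + 1
        xs = [np.exp(2j * np.pi * S / N) for S in range(N)]
        return np.array(_map_points(workspace, xs, jobs))
    N1, N2 = scheme.s_max[0] + 1, scheme.s_max[1] + 1
    grid = [
        (np.exp(2j * np.pi * S1 / N1), np.exp(2j * np.pi * S2 / N2))
        for S1 in range(N1) for S2 in range(N2)
    ]
    return np.array(_map_points(workspace, grid, jobs)).reshape(N1, N2)


def _map_points(workspace: EngineWorkspace, xs, jobs: int) -> list:
    if jobs <= 1:
        return [workspace.point(x) for x in xs]
    with ThreadPoolExecutor(max_workers=jobs) as pool:
        return list(pool.map(workspace.point, xs))


def distribution_dft(seq: RnaSequence, model: EnergyModel,
                     scheme: ScoringScheme, jobs: int = 1) -> ScoreDistribution:
    """Exact score distribution via root-of-unity evaluation + inverse DFT."""
    if scheme.dim != 1:
        raise InputError("distribution_dft is the scalar driver; "
                         "use landscape_distribution for 2-vector schemes")
    if scheme.s_max is None:
        raise InputError("scheme.s_max must be set by the feature module")
    ws = EngineWorkspace(seq, model, scheme)
    zeta = dft_points(ws, jobs=jobs)
    return ScoreDistribution(inverse_dft(zeta), scheme.s_max)


# ---------------------------------------------------------------------------
# polynomial backend
# ---------------------------------------------------------------------------

def distribution_poly(seq: RnaSequence, model: EnergyModel,
                      scheme: ScoringScheme) -> ScoreDistribution:
    """Exact score distribution with polynomial-valued cells.

    Coefficient vectors have length s_max + 1; any accumulation reaching
    past s_max raises :class:`ScoreBoundError` naming the cell (an
    underestimated bound is an error, never silent truncation).
    """
    if scheme.dim != 1:
        raise InputError("the polynomial backend is one-dimensional")
    if scheme.s_max is None:
        raise InputError("scheme.s_max must be set by the feature module")
    n = seq.n
    L = scheme.s_max + 1
    w = build_weights(seq, model)
    t = scheme.tables()
    G1, G2, G3, G4, G5a, G5b, G6, G7, G8, G9 = t.as_args()

    def shift(v: np.ndarray, g: int, cell: str) -> np.ndarray:
        if g == 0:
            return v
        if g >= L or np.any(v[L - g:] != 0):
            raise ScoreBoundError(
                f"score bound s_max={scheme.s_max} violated at {cell} "
                f"(shift by {g})"
            )
        out = np.zeros(L)
        out[g:] = v[: L - g]
        return out

    def mul(a: np.ndarray, b: np.ndarray, cell: str) -> np.ndarray:
        full = np.convolve(a, b)
        if np.any(full[L:] != 0):
            raise ScoreBoundError(
                f"score bound s_max={scheme.s_max} violated at {cell} (product)"
            )
        return full[:L]

    Z = np.zeros((n + 2, n + 2, L))
    Z1 = np.zeros((n + 2, n + 2, L))
    Zb = np.zeros((n + 2, n + 2, L))
    Zm = np.zeros((n + 2, n + 2, L))
    Zm1 = np.zeros((n + 2, n + 2, L))
    for i in range(1, n + 2):
        Z[i, i - 1, 0] = 1.0
    for sp in range(0, n):
        for i in range(1, n + 1 - sp):
            j = i + sp
            cell = f"({i},{j})"
            if w.apair[i, j]:
                acc = np.zeros(L)
                if w.WH[i, j] != 0:
                    hp = np.zeros(L)
                    hp[0] = w.WH[i, j]
                    acc = acc + shift(hp, int(G4[i, j]), cell)
                kmax = min(j - 2, i + 1 + w.span)
                for k in range(i + 1, kmax + 1):
                    a = k - i - 1
                    for l in range(max(k + 1, j - 1 - (w.span - a)), j):
                        if np.any(Zb[k, l] != 0):
                            g5 = int(G5a[i, j]) + int(G5b[k, l])
                            acc = acc + shift(
                                Zb[k, l] * w.Wint[a, j - l - 1], g5, cell
                            )
                for k in range(i + 2, j):
                    prod = mul(Zm[i + 1, k - 1], Zm1[k, j - 1], cell)
                    if np.any(prod != 0):
                        acc = acc + shift(prod * w.WM3[i, j], int(G6[i, j, k]), cell)
                Zb[i, j] = acc
            a1 = np.zeros(L)
            am1 = np.zeros(L)
            for k in range(i + 1, j + 1):
                if np.any(Zb[i, k] != 0):
                    a1 = a1 + shift(Zb[i, k], int(G3[i, j, k]), cell)
                    am1 = am1 + shift(
                        Zb[i, k] * w.Wm4[j - k], int(G9[i, j, k]), cell
                    )
            Z1[i, j] = a1
            Zm1[i, j] = am1
            am = np.zeros(L)
            for k in range(i, j):
                if np.any(Zm1[k, j] != 0):
                    un = np.zeros(L)
                    un[0] = w.Wm4[k - i]
                    left = shift(un, int(G7[i, j, k]), cell) + shift(
                        Zm[i, k - 1], int(G8[i, j, k]), cell
                    )
                    am = am + mul(left, Zm1[k, j], cell)
            Zm[i, j] = am
            az = np.zeros(L)
            g1v = int(G1[i, j])
            if g1v >= L:
                raise ScoreBoundError(
                    f"score bound s_max={scheme.s_max} violated at {cell} "
                    f"(open-chain gain {g1v})"
                )
            az[g1v] = 1.0
            for k in range(i - 1, j):
                if np.any(Z1[k + 1, j] != 0):
                    prod = mul(Z[i, k], Z1[k + 1, j], cell)
                    az = az + shift(prod, int(G2[i, j, k]), cell)
            Z[i, j] = az
    return ScoreDistribution(Z[1, n].copy(), scheme.s_max)
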