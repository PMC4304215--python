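"""Configurable loop-decomposition energy model.

The Boltzmann weight of a structure factorizes over its loops: hairpins,
interior loops (including stacks and bulges), multiloops and the exterior
loop.  Each loop class carries a linear energy form:

    hairpin(i,j):        dE = h_a + h_b * (j - i - 1)
    stack:               dE = s
    interior/bulge:      dE = c_a + c_b * u      (u unpaired bases in loop)
    multiloop closing:   dE = m_a
    multiloop unpaired:  dE = m_b per unpaired base

and the weight of a loop is exp(-dE / kT).  In *counting* mode every
coefficient is zero, so every admissible structure has weight exactly 1
and the ensemble is uniform — the regime in which all distributions have
integer weights and can be validated against exhaustive enumeration.

The same model object drives both the dynamic programming and the
whole-structure evaluation :meth:`EnergyModel.structure_weight`, so the
two code paths can be compared term by term.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace

import numpy as np

from .errors import InputError
from .structures import RnaSequence, SecondaryStructure

DEFAULT_ALLOWED_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})


@dataclass(frozen=True)
class EnergyModel:
    """Pairing rules plus loop energy coefficients (energies in units of kT
    unless kT is changed).

    Parameters
    ----------
    allowed_pairs:
        Unordered residue pairs that may form hydrogen bonds; default
        canonical Watson-Crick plus wobble (AU, GC, GU).
    theta:
        Minimum number of unpaired bases in a hairpin loop (default 3).
    max_interior_span:
        Interior loops with more than this many unpaired bases in total get
        weight 0; restores cubic running time of the fill.
    kT:
        Boltzmann factor scale; 1.0 means coefficients are in kT units.
    mode:
        "counting" (all energies zero, uniform ensemble) or "thermodynamic".
    """

    allowed_pairs: frozenset = DEFAULT_ALLOWED_PAIRS
    theta: int = 3
    max_interior_span: int = 30
    kT: float = 1.0
    mode: str = "counting"
    hairpin_a: float = 0.0
    hairpin_b: float = 0.0
    stack: float = 0.0
    interior_a: float = 0.0
    interior_b: float = 0.0
    multi_close: float = 0.0
    multi_unpaired: float = 0.0

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise InputError("kT must be positive")
        if self.theta < 0:
            raise InputError("theta must be non-negative")
        if self.mode not in ("counting", "thermodynamic"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.mode == "counting":
            for name in (
                "hairpin_a", "hairpin_b", "stack", "interior_a",
                "interior_b", "multi_close", "multi_unpaired",
            ):
                if getattr(self, name) != 0.0:
                    raise InputError("counting mode requires all energies zero")
        object.__setattr__(
            self, "allowed_pairs", frozenset(self.allowed_pairs)
        )

    # -- constructors -------------------------------------------------

    @classmethod
    def counting(cls, **kw) -> "EnergyModel":
        """Uniform-ensemble model: every admissible structure has weight 1."""
        return cls(mode="counting", **kw)

    @classmethod
    def random(cls, rng: np.random.Generator, **kw) -> "EnergyModel":
        """Random thermodynamic parameter draw (coefficients in [-1.5, 1.5] kT),
        used to exercise the recursions away from the uniform case."""
        coef = rng.uniform(-1.5, 1.5, size=7)
        return cls(
            mode="thermodynamic",
            hairpin_a=coef[0], hairpin_b=coef[1], stack=coef[2],
            interior_a=coef[3], interior_b=coef[4],
            multi_close=coef[5], multi_unpaired=coef[6],
            **kw,
        )

    @classmethod
    def from_config(cls, source) -> "EnergyModel":
        """Load from a JSON mapping (path or dict)."""
        if isinstance(source, (str, bytes)):
            with open(source) as fh:
                data = json.load(fh)
        else:
            data = dict(source)
        if "allowed_pairs" in data:
            data["allowed_pairs"] = frozenset(data["allowed_pairs"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise InputError(f"bad model config: {exc}") from exc

    def to_config(self) -> dict:
        data = asdict(self)
        data["allowed_pairs"] = sorted(self.allowed_pairs)
        return data

    def with_(self, **kw) -> "EnergyModel":
        return replace(self, **kw)

    # -- pairing ------------------------------------------------------

    def pair_allowed(self, a: str, b: str) -> bool:
        return a + b in self.allowed_pairs

    def pair_matrix(self, seq: RnaSequence) -> np.ndarray:
        """(n+2, n+2) 0/1 matrix, 1-based: A[i, j] = 1 iff residues at i and j
        may pair (symmetric; no loop-size constraint included)."""
        n = seq.n
        A = np.zeros((n + 2, n + 2), dtype=np.int8)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if self.pair_allowed(seq.base(i), seq.base(j)):
                    A[i, j] = A[j, i] = 1
        return A

    # -- loop Boltzmann factors (the e^{f1..f4} of the recursions) -----

    def _w(self, dE: float) -> float:
        return math.exp(-dE / self.kT)

    def w_hairpin(self, seq: RnaSequence, i: int, j: int) -> float:
        """e^{f1(i,j)}: hairpin closed by (i,j); 0 if the pair is disallowed
        or the loop holds fewer than theta bases."""
        if j - i - 1 < self.theta:
            return 0.0
        if not self.pair_allowed(seq.base(i), seq.base(j)):
            return 0.0
        return self._w(self.hairpin_a + self.hairpin_b * (j - i - 1))

    def w_interior(self, seq: RnaSequence, i: int, j: int, k: int, l: int) -> float:
        """e^{f2(i,j,k,l)}: two-pair loop, outer (i,j), inner (k,l).

        A stack (no unpaired bases) uses the stack coefficient; anything
        else is a bulge/interior loop with affine energy in the number of
        unpaired bases.  Loops beyond max_interior_span get weight 0.
        The inner pair's own admissibility is the inner cell's concern.
        """
        if not (i < k < l < j):
            raise InputError(f"bad interior indices {(i, j, k, l)}")
        if not self.pair_allowed(seq.base(i), seq.base(j)):
            return 0.0
        u = (k - i - 1) + (j - l - 1)
        if u > self.max_interior_span:
            return 0.0
        if u == 0:
            return self._w(self.stack)
        return self._w(self.interior_a + self.interior_b * u)

    def w_multi_close(self, seq: RnaSequence, i: int, j: int) -> float:
        """e^{f3(i,j)}: penalty of the pair (i,j) closing a multiloop."""
        if not self.pair_allowed(seq.base(i), seq.base(j)):
            return 0.0
        return self._w(self.multi_close)

    def w_multi_unpaired(self, u: int) -> float:
        """e^{f4(u)}: u unpaired bases inside a multiloop (linear, so
        multiplicative over splits)."""
        if u < 0:
            raise InputError("negative unpaired count")
        return self._w(self.multi_unpaired * u)

    # -- whole-structure weight ----------------------------------------

    def validate_structure(self, seq: RnaSequence, s: SecondaryStructure) -> None:
        if s.n != seq.n:
            raise InputError(f"structure length {s.n} != sequence length {seq.n}")
        for i, j in sorted(s.pairs):
            if not self.pair_allowed(seq.base(i), seq.base(j)):
                raise InputError(
                    f"disallowed pair {seq.base(i)}{seq.base(j)} at ({i},{j})"
                )
            if j - i - 1 < self.theta:
                raise InputError(f"hairpin under pair ({i},{j}) smaller than theta")

    def structure_weight(self, seq: RnaSequence, s: SecondaryStructure) -> float:
        """Boltzmann factor e^{-E(s)/kT} of one structure.

        Loops are classified exactly as the dynamic programming decomposes
        them: each pair (i,j) closes a hairpin (no nested children), an
        interior loop (one child) or a multiloop (>= 2 children, weighted
        by its unpaired bases).  Exterior-loop bases carry weight 1.  A
        capped interior loop yields weight 0 (the structure is outside the
        model's ensemble), whereas a structurally invalid input raises.
        """
        self.validate_structure(seq, s)
        children = _loop_children(s)
        w = 1.0
        for (i, j), kids in children.items():
            if i == 0:  # exterior loop
                continue
            if not kids:
                w *= self.w_hairpin(seq, i, j)
            elif len(kids) == 1:
                k, l = kids[0]
                w *= self.w_interior(seq, i, j, k, l)
            else:
                unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
                w *= self.w_multi_close(seq, i, j) * self.w_multi_unpaired(unpaired)
        return w


def _loop_children(s: SecondaryStructure) -> dict:
    """Map each pair (and the pseudo-pair (0, n+1) for the exterior loop) to
    the list of pairs directly nested inside it, in ascending order."""
    out: dict[tuple, list] = {(0, s.n + 1): []}
    stack: list[tuple] = [(0, s.n + 1)]
    for pair in sorted(s.pairs):
        while stack and not (stack[-1][0] < pair[0] and pair[1] < stack[-1][1]):
            stack.pop()
        out[stack[-1]].append(pair)
        out[pair] = []
        stack.append(pair)
    return out


def random_model(seed_or_rng, theta: int = 3, **kw) -> EnergyModel:
    """Convenience wrapper around :meth:`EnergyModel.random`."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return EnergyModel.random(rng, theta=theta, **kw)
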