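"""RNA sequences, secondary structures and structure-level features.

Structures are non-crossing sets of base pairs (no pseudoknots) on a
1-based sequence.  This module also provides exhaustive enumeration of
all admissible structures for short sequences, which serves as the
substrate of the brute-force reference path used throughout the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator

import numpy as np

from .errors import InputError

if TYPE_CHECKING:  # pragma: no cover
    from .energy import EnergyModel

_VALID = set("ACGU")
ENUMERATION_CAP = 25


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A,C,G,U}; positions are 1-based."""

    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InputError("empty sequence")
        for pos, c in enumerate(self.residues, start=1):
            if c not in _VALID:
                raise InputError(
                    f"invalid residue {c!r} at position {pos} (expected A/C/G/U)"
                )

    @classmethod
    def from_string(cls, text: str) -> "RnaSequence":
        """Build from raw text, accepting lowercase and T (normalized to U)."""
        return cls(text.strip().upper().replace("T", "U"))

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """Residue at 1-based position i."""
        return self.residues[i - 1]

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class SecondaryStructure:
    """A secondary structure: a non-crossing set of base pairs (i, j), i < j.

    Well-formedness (disjoint, non-crossing pairs inside [1, n]) is checked
    at construction.  Admissibility under a particular energy model
    (pairing rules, minimum hairpin size) is a model question, checked by
    :meth:`rnascoredist.energy.EnergyModel.validate_structure`.
    """

    n: int
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise InputError(f"pair ({i},{j}) out of range for n={self.n}")
            if i in seen or j in seen:
                raise InputError(f"base in two pairs near ({i},{j})")
            seen.add(i)
            seen.add(j)
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for b in range(a + 1, len(ordered)):
                k, l = ordered[b]
                if k > j:
                    break
                if i < k <= j < l:
                    raise InputError(
                        f"crossing pairs ({i},{j}) and ({k},{l}) (pseudoknot)"
                    )

    @property
    def num_pairs(self) -> int:
        return len(self.pairs)

    def pair_map(self) -> np.ndarray:
        """partner[i] = j if (i,j) or (j,i) is a pair, else 0 (1-based)."""
        partner = np.zeros(self.n + 1, dtype=np.int64)
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        return partner

    def pair_matrix(self) -> np.ndarray:
        """Structure vector as a 0/1 matrix S with S[i, j] = 1 iff (i, j) pairs.

        Returned array is (n+2, n+2) and 1-based; only i < j entries are set.
        """
        S = np.zeros((self.n + 2, self.n + 2), dtype=np.int64)
        for i, j in self.pairs:
            S[i, j] = 1
        return S


def parse_dot_bracket(text: str, n: int | None = None) -> SecondaryStructure:
    """Parse Vienna dot-bracket notation ('(', ')', '.') into a structure."""
    text = text.strip()
    if n is not None and len(text) != n:
        raise InputError(
            f"dot-bracket length {len(text)} does not match expected length {n}"
        )
    stack: list[int] = []
    pairs = set()
    for pos, c in enumerate(text, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise InputError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif c != ".":
            raise InputError(f"invalid character {c!r} at position {pos}")
    if stack:
        raise InputError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(n=len(text), pairs=frozenset(pairs))


def to_dot_bracket(s: SecondaryStructure) -> str:
    """Dot-bracket string of a structure; round-trips with parse_dot_bracket."""
    out = ["."] * s.n
    for i, j in s.pairs:
        out[i - 1] = "("
        out[j - 1] = ")"
    return "".join(out)


def hamming_distance(s1: SecondaryStructure, s2: SecondaryStructure) -> int:
    """Base-pair Hamming distance: size of the symmetric difference of the
    pair sets, i.e. the XOR count of the two structure vectors."""
    if s1.n != s2.n:
        raise InputError(f"length mismatch: {s1.n} vs {s2.n}")
    return len(s1.pairs ^ s2.pairs)


def end_to_end_distance(s: SecondaryStructure) -> int:
    """5'-3' distance: covalent bonds plus base pairs along the exterior loop.

    The walk starts at position 1 and ends at position n; an exterior pair
    (i, j) is crossed in one step, a backbone bond likewise.
    """
    partner = s.pair_map()
    d = 0
    i = 1
    while i < s.n:
        j = int(partner[i])
        if j > i:
            d += 1  # hydrogen bridge of an exterior pair
            i = j
        else:
            d += 1  # covalent bond i -> i+1
            i += 1
    return d


def enumerate_structures(
    seq: RnaSequence, model: "EnergyModel", cap: int = ENUMERATION_CAP
) -> Iterator[SecondaryStructure]:
    """Yield every structure admissible under *model* exactly once.

    Order is deterministic: recursive decomposition on the leftmost
    position (leftmost base unpaired first, then paired with ascending
    partner).  The open chain is always the first structure.  Refuses
    sequences longer than *cap* — the output grows exponentially.
    """
    n = seq.n
    if n > cap:
        raise InputError(
            f"enumeration refused for n={n} > cap={cap}; raise cap explicitly "
            "only if you accept exponential output"
        )

    memo: dict[tuple[int, int], list[tuple]] = {}

    def rec(i: int, j: int) -> list[tuple]:
        # all pair-tuples on the closed interval [i, j]
        if j - i + 1 <= model.theta:  # too short to hold any pair
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out: list[tuple] = []
        for tail in rec(i + 1, j):  # i unpaired
            out.append(tail)
        for k in range(i + model.theta + 1, j + 1):
            if not model.pair_allowed(seq.base(i), seq.base(k)):
                continue
            inner = rec(i + 1, k - 1)
            outer = rec(k + 1, j)
            for a in inner:
                for b in outer:
                    out.append(((i, k),) + a + b)
        memo[key] = out
        return out

    for pairs in rec(1, n):
        yield SecondaryStructure(n=n, pairs=frozenset(pairs))
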