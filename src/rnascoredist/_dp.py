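"""Low-level dynamic-programming kernels (numba-compiled).

All kernels fill the five triangular tables

    Z    exterior segment          Z1   leftmost pair at i, tail unpaired
    Zb   pair (i, j)               Zm   multiloop segment, >= 1 helix
    Zm1  multiloop segment whose last helix starts at i

in increasing span ``j - i``; within a span the cell order is
Zb -> Z1 -> Zm1 -> Zm -> Z, so same-span dependencies (Zb feeding Z1/Zm1,
Zm1 feeding Zm, Z1 feeding Z) are already available.  The exterior
recursion carries an explicit empty-prefix term (``Z[i, i-1] = 1``) so a
structure whose first exterior helix starts at position i is generated
exactly once.

Summation order is fixed (ascending k, then l), so results are
bit-reproducible and point evaluations at different x can be run in any
order or in parallel without changing the output.

Score accumulation: every recursion term is multiplied by ``P[g]`` where
``g`` is the integer gain of the transition, read from precomputed gain
tables, and ``P`` holds the powers of the evaluation point x (for
2-vector scores, the flattened outer product of the powers of x1 and x2,
indexed by the combined gain ``g1 * W2 + g2``).  With ``P = [1]`` and
all-zero gains the kernels reduce to the plain partition function.

Weight tables (all x-free, built once per sequence/model):

    apair[i, j]   1 iff the residues at i and j may pair
    WH[i, j]      hairpin weight e^{f1} (0 if loop < theta or disallowed)
    Wint[a, b]    two-pair loop weight e^{f2} for a/b unpaired bases on the
                  5'/3' side (stack at a = b = 0); 0 beyond the span cap
    WM3[i, j]     multiloop closing weight e^{f3}
    Wm4[u]        weight e^{f4(u)} of u unpaired multiloop bases
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18  # max-plus "minus infinity"


@njit(cache=True, nogil=True)
def fill_point(n, span, P, apair, WH, Wint, WM3, Wm4,
               G1, G2, G3, G4, G5a, G5b, G6, G7, G8, G9):
    """Score-accumulable fill at one evaluation point; returns Z(x)_{1,n}."""
    Z = np.zeros((n + 2, n + 2), np.complex128)
    Z1 = np.zeros((n + 2, n + 2), np.complex128)
    Zb = np.zeros((n + 2, n + 2), np.complex128)
    Zm = np.zeros((n + 2, n + 2), np.complex128)
    Zm1 = np.zeros((n + 2, n + 2), np.complex128)
    for i in range(1, n + 2):
        Z[i, i - 1] = 1.0  # empty exterior prefix
    for sp in range(0, n):
        for i in range(1, n + 1 - sp):
            j = i + sp
            # -- Zb: pair (i, j) ---------------------------------------
            if apair[i, j] == 1:
                acc = WH[i, j] * P[G4[i, j]]
                kmax = min(j - 2, i + 1 + span)
                for k in range(i + 1, kmax + 1):
                    a = k - i - 1
                    lmin = j - 1 - (span - a)
                    if lmin < k + 1:
                        lmin = k + 1
                    for l in range(lmin, j):
                        zb = Zb[k, l]
                        if zb != 0:
                            acc += zb * Wint[a, j - l - 1] * P[G5a[i, j] + G5b[k, l]]
                wm3 = WM3[i, j]
                for k in range(i + 2, j):
                    t = Zm[i + 1, k - 1] * Zm1[k, j - 1]
                    if t != 0:
                        acc += t * wm3 * P[G6[i, j, k]]
                Zb[i, j] = acc
            # -- Z1 and Zm1: leftmost pair (i, k), tail unpaired -------
            a1 = 0.0 + 0.0j
            am1 = 0.0 + 0.0j
            for k in range(i + 1, j + 1):
                zb = Zb[i, k]
                if zb != 0:
                    a1 += zb * P[G3[i, j, k]]
                    am1 += zb * Wm4[j - k] * P[G9[i, j, k]]
            Z1[i, j] = a1
            Zm1[i, j] = am1
            # -- Zm: last multiloop helix starts at k ------------------
            am = 0.0 + 0.0j
            for k in range(i, j):
                zm1 = Zm1[k, j]
                if zm1 != 0:
                    am += (Wm4[k - i] * P[G7[i, j, k]]
                           + Zm[i, k - 1] * P[G8[i, j, k]]) * zm1
            Zm[i, j] = am
            # -- Z: open chain + last exterior helix in [k+1, j] -------
            az = P[G1[i, j]] + 0.0j
            for k in range(i - 1, j):
                z1 = Z1[k + 1, j]
                if z1 != 0:
                    az += Z[i, k] * z1 * P[G2[i, j, k]]
            Z[i, j] = az
    return Z[1, n]


@njit(cache=True, nogil=True)
def fill_real(n, span, apair, WH, Wint, WM3, Wm4):
    """Plain (score-free) partition-function fill; returns all five tables."""
    Z = np.zeros((n + 2, n + 2), np.float64)
    Z1 = np.zeros((n + 2, n + 2), np.float64)
    Zb = np.zeros((n + 2, n + 2), np.float64)
    Zm = np.zeros((n + 2, n + 2), np.float64)
    Zm1 = np.zeros((n + 2, n + 2), np.float64)
    for i in range(1, n + 2):
        Z[i, i - 1] = 1.0
    for sp in range(0, n):
        for i in range(1, n + 1 - sp):
            j = i + sp
            if apair[i, j] == 1:
                acc = WH[i, j]
                kmax = min(j - 2, i + 1 + span)
                for k in range(i + 1, kmax + 1):
                    a = k - i - 1
                    lmin = j - 1 - (span - a)
                    if lmin < k + 1:
                        lmin = k + 1
                    for l in range(lmin, j):
                        zb = Zb[k, l]
                        if zb != 0:
                            acc += zb * Wint[a, j - l - 1]
                wm3 = WM3[i, j]
                for k in range(i + 2, j):
                    t = Zm[i + 1, k - 1] * Zm1[k, j - 1]
                    if t != 0:
                        acc += t * wm3
                Zb[i, j] = acc
            a1 = 0.0
            am1 = 0.0
            for k in range(i + 1, j + 1):
                zb = Zb[i, k]
                if zb != 0:
                    a1 += zb
                    am1 += zb * Wm4[j - k]
            Z1[i, j] = a1
            Zm1[i, j] = am1
            am = 0.0
            for k in range(i, j):
                zm1 = Zm1[k, j]
                if zm1 != 0:
                    am += (Wm4[k - i] + Zm[i, k - 1]) * zm1
            Zm[i, j] = am
            az = 1.0
            for k in range(i - 1, j):
                z1 = Z1[k + 1, j]
                if z1 != 0:
                    az += Z[i, k] * z1
            Z[i, j] = az
    return Z, Z1, Zb, Zm, Zm1


@njit(cache=True, nogil=True)
def fill_point_ext(n, P, Zb, Wm4, G1, G2, G3):
    """Point evaluation when only the exterior recursions carry x.

    For schemes with g4..g9 = 0 (the 5'-3' distance), Zb/Zm/Zm1 are x-free;
    *Zb* is the precomputed real table and only Z1 and the Z row starting at
    1 are recomputed per point.  Expressions and summation order replicate
    :func:`fill_point` exactly, so the two paths agree bit for bit.
    """
    Z1 = np.zeros((n + 2, n + 2), np.complex128)
    for sp in range(0, n):
        for i in range(1, n + 1 - sp):
            j = i + sp
            a1 = 0.0 + 0.0j
            for k in range(i + 1, j + 1):
                zb = Zb[i, k]
                if zb != 0:
                    a1 += zb * P[G3[i, j, k]]
            Z1[i, j] = a1
    Zrow = np.zeros(n + 2, np.complex128)
    Zrow[0] = 1.0  # Z_{1,0}: empty prefix
    for j in range(1, n + 1):
        az = P[G1[1, j]] + 0.0j
        for k in range(0, j):
            z1 = Z1[k + 1, j]
            if z1 != 0:
                az += Zrow[k] * z1 * P[G2[1, j, k]]
        Zrow[j] = az
    return Zrow[n]


@njit(cache=True, nogil=True)
def fill_maxplus(n, span, apair, WH, Wint, WM3, Wm4,
                 G1, G2, G3, G4, G5a, G5b, G6, G7, G8, G9):
    """Max-plus transform of the fill: sums -> max, products -> +, weights ->
    0 / -inf admissibility, gains added.  Returns the exact maximum total
    score over the ensemble (s_max of the scheme, e.g. d_max for Hamming).
    """
    thr = NEG / 2.0
    M = np.full((n + 2, n + 2), NEG, np.float64)
    M1 = np.full((n + 2, n + 2), NEG, np.float64)
    Mb = np.full((n + 2, n + 2), NEG, np.float64)
    Mm = np.full((n + 2, n + 2), NEG, np.float64)
    Mm1 = np.full((n + 2, n + 2), NEG, np.float64)
    for i in range(1, n + 2):
        M[i, i - 1] = 0.0
    for sp in range(0, n):
        for i in range(1, n + 1 - sp):
            j = i + sp
            if apair[i, j] == 1:
                best = NEG
                if WH[i, j] > 0.0:
                    best = float(G4[i, j])
                kmax = min(j - 2, i + 1 + span)
                for k in range(i + 1, kmax + 1):
                    a = k - i - 1
                    lmin = j - 1 - (span - a)
                    if lmin < k + 1:
                        lmin = k + 1
                    for l in range(lmin, j):
                        if Mb[k, l] > thr and Wint[a, j - l - 1] > 0.0:
                            cand = Mb[k, l] + G5a[i, j] + G5b[k, l]
                            if cand > best:
                                best = cand
                if WM3[i, j] > 0.0:
                    for k in range(i + 2, j):
                        if Mm[i + 1, k - 1] > thr and Mm1[k, j - 1] > thr:
                            cand = Mm[i + 1, k - 1] + Mm1[k, j - 1] + G6[i, j, k]
                            if cand > best:
                                best = cand
                Mb[i, j] = best
            b1 = NEG
            bm1 = NEG
            for k in range(i + 1, j + 1):
                if Mb[i, k] > thr:
                    c1 = Mb[i, k] + G3[i, j, k]
                    if c1 > b1:
                        b1 = c1
                    c2 = Mb[i, k] + G9[i, j, k]
                    if c2 > bm1:
                        bm1 = c2
            M1[i, j] = b1
            Mm1[i, j] = bm1
            bm = NEG
            for k in range(i, j):
                if Mm1[k, j] > thr:
                    cand = Mm1[k, j] + G7[i, j, k]
                    if cand > bm:
                        bm = cand
                    if Mm[i, k - 1] > thr:
                        cand = Mm[i, k - 1] + G8[i, j, k] + Mm1[k, j]
                        if cand > bm:
                            bm = cand
            Mm[i, j] = bm
            bz = float(G1[i, j])
            for k in range(i - 1, j):
                if M[i, k] > thr and M1[k + 1, j] > thr:
                    cand = M[i, k] + M1[k + 1, j] + G2[i, j, k]
                    if cand > bz:
                        bz = cand
            M[i, j] = bz
    return M[1, n]
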