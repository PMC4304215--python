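# Methods

## Model and scope

The package works on the standard secondary-structure model: a structure
is a non-crossing set of base pairs (no pseudoknots) over allowed pair
types (default AU, GC, GU in either orientation) with at least θ
unpaired bases in every hairpin loop (default θ = 3; it is a model
parameter, not a constant).  Coordinates are 1-based closed intervals
throughout the library; only array padding is internal.

The Boltzmann weight of a structure factorizes over its loops.  The
energy model is a linear loop-energy family

| loop | energy |
|---|---|
| hairpin (i,j) | h_a + h_b·(j−i−1) |
| stack | s |
| interior/bulge | c_a + c_b·u, u = total unpaired |
| multiloop closing | m_a |
| multiloop unpaired | m_b per base |

with energies in kT units (kT configurable, default 1).  This family
exercises exactly the recursion shapes the distribution machinery needs
(one weight per hairpin, two-pair loop, multiloop closure and multiloop
unpaired base) while keeping the parameterization transparent; the
distribution engine itself is energy-model-agnostic, so swapping in a
richer parameter set changes no algorithmic code.  Experimentally
calibrated nearest-neighbor tables (dangles, terminal mismatches,
tabulated loop energies) are deliberately out of scope.  Interior loops
with more than `max_interior_span` unpaired bases (default 30) get
weight zero, which restores cubic time for the fill; counting mode sets
every energy to zero so the ensemble is uniform and all distribution
weights are integers.

## Recursions

The partition function is computed with the five-table interval scheme

    Z_{i,j}   = 1 + Σ_{k=i-1}^{j-1} Z_{i,k} · Z1_{k+1,j}
    Z1_{i,j}  = Σ_{k=i+1}^{j} Zb_{i,k}
    Zb_{i,j}  = w_hairpin(i,j)
              + Σ_{i<k<l<j} Zb_{k,l} · w_interior(i,j,k,l)
              + Σ_{k=i+2}^{j-1} Zm_{i+1,k-1} · Zm1_{k,j-1} · w_multi_close(i,j)
    Zm_{i,j}  = Σ_{k=i}^{j-1} ( w_unpaired(k-i) + Zm_{i,k-1} ) · Zm1_{k,j}
    Zm1_{i,j} = Σ_{k=i+1}^{j} Zb_{i,k} · w_unpaired(j-k)

filled in increasing span; within a span the order Zb → Z1 → Zm1 → Zm →
Z resolves all same-span dependencies.  Two points were genuinely open
and are fixed here by the requirement that the DP agree with brute-force
enumeration on every fixture:

* **Empty exterior prefix.**  The exterior recursion carries the
  boundary term Z_{i,i-1} = 1 (the k = i−1 summand), without which a
  structure whose first exterior helix starts exactly at position i is
  never generated.  The identity Z = Σ_x w(x) over the enumerated
  ensemble pins this down.
* **Multiloop grouping.**  Zm is read as the one-or-more-branch split
  (w_unpaired(k−i) + Zm_{i,k−1}) · Zm1_{k,j}, the standard unique
  decomposition by the start of the last helix; again validated by the
  enumeration identity.

Values are kept in linear space (no log transform).  That is exact for
the desk scales this package targets (n up to a few hundred); a guard
warns when Z exceeds 1e290.

## Score accumulation and coefficient extraction

A `ScoringScheme` attaches an integer gain g_1..g_9 to each of the nine
recursion terms (one per term above: open chain, exterior split, Z1
term, hairpin, interior, multiloop closure, multiloop unpaired stretch,
multiloop split, Zm1 term).  Multiplying each term by x^{g} turns
Z(x)_{1,n} into the generating function of the score.  Engine contract:
every gain is a non-negative integer, O(1) to evaluate after scheme
precomputation, and the interior-loop gain is separable,
g_5(i,j,k,l) = A(i,j) + B(k,l) — both shipped features satisfy this, and
it is what lets the kernels read all gains from precomputed tables.

* **Polynomial backend**: cells are coefficient vectors of length
  S_max+1.  Any accumulation that would pass S_max raises an error
  naming the cell — an underestimated bound aliases silently in the DFT
  backend, so in the exact backend it must be loud.
* **DFT backend**: the polynomial is evaluated at x_S =
  e^{2πiS/(S_max+1)}, S = 0..S_max, and coefficients are recovered by

      z_S = (1/(S_max+1)) Σ_r ζ_r e^{−2πirS/(S_max+1)},   ζ_r = Z(x_r)_{1,n}.

  This is the standard unnormalized-forward / normalized-inverse DFT
  pair; it is the convention under which forward evaluation followed by
  the inverse transform is the identity on coefficient vectors, which
  the tests assert directly.
* **2D scores**: gains become integer pairs, evaluation runs over the
  full (S1_max+1)×(S2_max+1) grid of root-of-unity pairs, and the
  inverse transform is applied separably along each axis.  The two gain
  components are folded into a single table index g1·W2 + g2 so the
  scalar kernels serve both cases.

Numerical tolerances: after the inverse transform the imaginary residue
must satisfy |Im z_S| ≤ 1e−8·Z and the real part z_S ≥ −1e−8·Z;
violations raise, small negatives are clipped to zero.  In practice
residues sit at ~1e−15·Z.  Summation order inside every cell is fixed
(ascending k, then l) and the engine contains no randomness, so results
are bit-reproducible; evaluation points are mutually independent and the
optional thread pool (`--jobs`) cannot change the output.

## Hamming-distance gains

With S the reference's 0/1 pair matrix, the distance of structure x is
the XOR count between the pair matrices.  The gain principle: every
parse of a structure by the recursions decides the pairing status of
each matrix cell exactly once — a split or an unpaired stretch fixes a
rectangle of cells to 0, a pair-creating term fixes its own cell (i,j)
to 1.  The gain of a step is the number of reference pairs among cells
fixed to 0, plus (1 − S[i][j]) for a created pair; summed over the
parse this is exactly the Hamming distance.  Writing T(i,j) for the
number of reference pairs inside [i,j], all nine gains are affine in T:

    g1 = T(i,j)                        g2 = T(i,j) − T(i,k) − T(k+1,j)
    g3 = g9 = T(i,j) − T(i,k)          g4 = T(i,j) + 1 − 2·S[i][j]
    g5 = T(i,j) − T(k,l) + 1 − 2·S[i][j]
    g6 = T(i,j) − T(i+1,k−1) − T(k,j−1) + 1 − 2·S[i][j]
    g7 = T(i,j) − T(k,j)               g8 = T(i,j) − T(i,k−1) − T(k,j)

(the tests check g6 against its literal double-sum form over the pair
matrix, and the whole scheme against enumeration).  T is an O(n²)
prefix-sum precomputation, so each gain is O(1).  Attribution note: the
cells covered by an unpaired tail are charged to the Z1/Zm1 transition
that creates the tail (g3/g9) rather than to the split that precedes it;
any attribution that decides each cell exactly once yields the same
totals, so this is a documentation choice, not a modeling one.

S_max is the exact ensemble maximum d_max, from the max-plus transform
of the same recursions (sums → max, products → +, weights → 0/−∞
admissibility, gains added) — cubic time, exact, and attained (the
distribution's top bin is always nonzero).  A looser bound (e.g. n) may
be forced for cross-checking; it only adds evaluation points.

## 5ʹ–3ʹ distance gains

The distance is the walk through the exterior loop: g1(i,j) = j−i (open
chain), g2 = 1 for the junction bond of a nonempty exterior split (0 for
the empty-prefix boundary term, where no junction exists — the boundary
term is absent from the scheme's printed form and must carry gain 0 for
the walk to come out right), g3(i,j,k) = 1 + j − k (one bridge plus the
unpaired tail), and g4..g9 = 0 since interior transitions never touch
the exterior walk.  Because g4..g9 vanish, Zb/Zm/Zm1 contain no x; the
optimized driver computes them once with the scalar DP and per point
recomputes only Z1 and the Z row from position 1, with expressions and
summation order copied verbatim from the full kernel — the test suite
asserts bitwise identity between the two paths.  S_max = n − 1 exactly
(the open chain realizes it).

## Brute-force reference path

`oracle_distribution` enumerates all structures (recursive decomposition
on the leftmost position, deterministic order, refused above n = 25),
weighs each with `structure_weight` — an independent whole-structure
loop classification that shares no recursion code with the engine — and
bins by a direct structure-level score function.  The single identity
"DP partition function = Σ structure weights" validates enumeration,
loop decomposition and DP simultaneously; the engine distributions are
then compared elementwise against this path on a battery of 30
deterministic fixtures (10 seeds × n ∈ {8, 10, 12}), in counting mode
and under random thermodynamic draws (coefficients uniform in ±1.5 kT —
wide enough to make weights vary by orders of magnitude across the
ensemble while keeping linear-space arithmetic comfortably exact).

## Fixture generation

Fixtures are deterministic in (n, seed): sequences uniform over ACGU;
references drawn uniformly from the enumerated ensemble when n ≤ 25 and
otherwise greedily assembled from admissible pairs in random order
(always a valid structure, typically dense in pairs).  The generator
emulates the "random sequences" evaluation style; it does not emulate
biological base composition, conserved helices, or naturally sparse
reference structures, so passing tests demonstrate algorithmic
correctness of the distributions, not biological realism of any
particular landscape.

## Problem sizes and the scaling check

Oracle comparisons run at n ≤ 12 (ensembles up to a few thousand
structures); oracle-free structural identities (normalization, 2D
marginals vs 1D, triangle-inequality support, reference-probability
identity) run at n = 60.  The DFT backend's cost model is n³·S_max per
distribution; the suite measures the log-log slope over
n ∈ {40, 60, 80, 120} and requires agreement with the model within 0.5
slope units.  The scaling measurement uses an interior span cap of 4:
the cost model treats the span cap as a constant ≪ n, and at these
moderate lengths the default cap of 30 would still dominate the count
of interior-loop terms (an n² term with a large constant), masking the
cubic regime the model describes.  The timed slope is about 4.0 against
a theoretical 4.1 on the shipped fixtures.

## Known limitations

* No Turner-style tabulated energies, dangles or coaxial stacking; the
  model family is linear per loop class.
* Linear-space arithmetic overflows for long sequences with strongly
  stabilizing parameters (guarded with a warning near 1e290).
* The polynomial backend is 1D only; 2D correctness is established
  against enumeration and the marginal identities instead.
* Gains must be non-negative integers with a separable interior term;
  features violating this need a different cell algebra.
* `--jobs` uses threads around the (GIL-releasing) kernels; it helps
  only on multi-core machines and never changes results.
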