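"""Hamming-distance feature: prefix sums, gain functions, exact d_max and
the full distribution."""

import numpy as np
import pytest

import rnascoredist as rsd
from rnascoredist import (
    ReferencePrefixSums,
    SecondaryStructure,
    compute_dmax,
    hamming_distance,
    hamming_distribution,
    make_hamming_scheme,
    parse_dot_bracket,
    region_pair_count,
)
from rnascoredist.score_engine import ScoringScheme, distribution_dft

from _support import COUNTING, fixture


class TestPrefixSums:
    def test_empty_reference(self):
        P = ReferencePrefixSums(SecondaryStructure(n=8))
        assert region_pair_count(P, 1, 8, 1, 8) == 0

    def test_full_range_counts_all_pairs(self):
        ref = parse_dot_bracket("((...))")
        P = ReferencePrefixSums(ref)
        assert region_pair_count(P, 1, 7, 1, 7) == 2

    def test_rectangle_query(self):
        P = ReferencePrefixSums(parse_dot_bracket("((...))"))
        # pairs {(1,7),(2,6)}: p in [2,2] selects only (2,6)
        assert region_pair_count(P, 2, 2, 1, 7) == 1
        assert region_pair_count(P, 1, 1, 7, 7) == 1
        assert region_pair_count(P, 3, 5, 1, 7) == 0

    def test_degenerate_ranges(self):
        P = ReferencePrefixSums(parse_dot_bracket("((...))"))
        assert region_pair_count(P, 4, 2, 1, 7) == 0
        assert region_pair_count(P, 1, 7, 9, 12) == 0


def _g6_direct(S, n, i, j, k):
    """Literal double-sum form of the multiloop-closure gain."""
    total = sum(S[p, j] for p in range(k, j))
    total += sum(S[i, q] for q in range(i + 1, j + 1))
    total += sum(
        S[p, q] for p in range(i + 1, k) for q in range(k, j + 1)
    )
    return total + 1 - 2 * S[i, j]


class TestGainFunctions:
    def test_g6_matches_direct_structure_vector_sum(self):
        for seed in range(6):
            _, ref = fixture(12, seed)
            scheme = make_hamming_scheme(ref)
            S = ref.pair_matrix()
            for i in range(1, 11):
                for j in range(i + 4, 13):
                    for k in range(i + 2, j):
                        assert scheme.g6(i, j, k) == _g6_direct(S, 12, i, j, k)

    def test_g6_empty_reference(self):
        scheme = make_hamming_scheme(SecondaryStructure(n=10))
        assert scheme.g6(1, 10, 4) == 1  # only the newly created pair

    def test_g6_reference_pair_created(self):
        # creating a pair present in the reference adds no distance when no
        # other reference pair is touched
        ref = SecondaryStructure(n=12, pairs={(2, 11)})
        scheme = make_hamming_scheme(ref)
        assert scheme.g6(2, 11, 6) == 0

    def test_all_gain_totals_nonnegative(self):
        for seed in range(4):
            _, ref = fixture(10, seed)
            scheme = make_hamming_scheme(ref)
            n = 10
            for i in range(1, n + 1):
                for j in range(i, n + 1):
                    assert scheme.g1(i, j) >= 0
                    if j > i:
                        assert scheme.g4(i, j) >= 0
                    for k in range(i - 1, j):
                        assert scheme.g2(i, j, k) >= 0
                    for k in range(i + 1, j + 1):
                        assert scheme.g3(i, j, k) >= 0
                        assert scheme.g9(i, j, k) >= 0
                    for k in range(i, j):
                        assert scheme.g7(i, j, k) >= 0
                        assert scheme.g8(i, j, k) >= 0
                    for k in range(i + 2, j):
                        assert scheme.g6(i, j, k) >= 0
                    for k in range(i + 1, j - 1):
                        for l in range(k + 1, j):
                            assert scheme.g5(i, j, k, l) >= 0

    def test_vectorized_tables_match_callables(self):
        _, ref = fixture(12, 3)
        scheme = make_hamming_scheme(ref)
        fast = scheme.tables()
        slow = ScoringScheme.tables(scheme)
        n = 12
        for i in range(1, n + 1):
            for j in range(i, n + 1):
                assert fast.G1[i, j] == slow.G1[i, j]
                if j > i:
                    assert fast.G4[i, j] == slow.G4[i, j]
                for k in range(i - 1, j):
                    assert fast.G2[i, j, k] == slow.G2[i, j, k]
                for k in range(i + 1, j + 1):
                    assert fast.G3[i, j, k] == slow.G3[i, j, k]
                for k in range(i, j):
                    assert fast.G7[i, j, k] == slow.G7[i, j, k]
                    assert fast.G8[i, j, k] == slow.G8[i, j, k]
                for k in range(i + 2, j):
                    assert fast.G6[i, j, k] == slow.G6[i, j, k]
                for k in range(i + 1, j - 1):
                    for l in range(k + 1, j):
                        assert (
                            fast.G5a[i, j] + fast.G5b[k, l]
                            == slow.G5a[i, j] + slow.G5b[k, l]
                        )


class TestDmax:
    def test_unique_structure(self):
        seq = rsd.RnaSequence("AAAA")
        assert compute_dmax(seq, SecondaryStructure(n=4), COUNTING) == 0

    def test_open_chain_reference(self, ggaaacc):
        ref = SecondaryStructure(n=7)
        assert compute_dmax(ggaaacc, ref, COUNTING) == 2

    def test_nested_reference(self, ggaaacc):
        ref = parse_dot_bracket("((...))")
        assert compute_dmax(ggaaacc, ref, COUNTING) == 3

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumerated_maximum(self, seed):
        seq, ref = fixture(12, seed)
        for model in (COUNTING, rsd.random_model(seed)):
            enum_max = max(
                hamming_distance(s, ref)
                for s in rsd.enumerate_structures(seq, COUNTING)
                if model.structure_weight(seq, s) > 0
            )
            assert compute_dmax(seq, ref, model) == enum_max


class _PairCountScheme(ScoringScheme):
    """Trivial scheme: +1 per created pair (number of base pairs)."""

    def g4(self, i, j):
        return 1

    def g5_outer(self, i, j):
        return 1

    def g6(self, i, j, k):
        return 1


class TestDistribution:
    def test_worked_example(self, ggaaacc):
        ref = parse_dot_bracket("((...))")
        dist = hamming_distribution(ggaaacc, ref, COUNTING)
        assert dist.s_max == 3
        assert dist.p == pytest.approx([1 / 6, 2 / 6, 1 / 6, 2 / 6], abs=1e-10)

    def test_p0_is_reference_probability(self):
        seq, ref = fixture(12, 4)
        model = rsd.random_model(21)
        dist = hamming_distribution(seq, ref, model)
        Z = rsd.compute_partition(seq, model)[1]
        assert dist.p[0] == pytest.approx(
            model.structure_weight(seq, ref) / Z, rel=1e-8
        )

    def test_support_bound_attained(self):
        seq, ref = fixture(12, 7)
        dist = hamming_distribution(seq, ref, COUNTING)
        assert dist.z[dist.s_max] > 0.5  # counting weights are integers

    def test_open_chain_reference_counts_pairs(self):
        seq, _ = fixture(12, 5)
        ref = SecondaryStructure(n=12)
        dist = hamming_distribution(seq, ref, COUNTING)
        scheme = _PairCountScheme(12, s_max=dist.s_max)
        other = distribution_dft(seq, COUNTING, scheme)
        assert np.abs(dist.p - other.p).max() < 1e-10

    def test_loose_smax_bound_agrees(self, ggaaacc):
        ref = parse_dot_bracket("((...))")
        exact = hamming_distribution(ggaaacc, ref, COUNTING)
        loose = hamming_distribution(ggaaacc, ref, COUNTING, s_max=7)
        assert np.abs(loose.z[:4] - exact.z).max() < 1e-9
        assert np.all(loose.z[4:] < 1e-9)
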