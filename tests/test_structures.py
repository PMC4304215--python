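"""Structure representation, dot-bracket I/O, structure-level features and
exhaustive enumeration."""

import itertools

import pytest
from hypothesis import given, strategies as st

from rnascoredist import (
    InputError,
    RnaSequence,
    SecondaryStructure,
    end_to_end_distance,
    enumerate_structures,
    hamming_distance,
    parse_dot_bracket,
    to_dot_bracket,
)

from _support import COUNTING, fixture


class TestSequence:
    def test_normalization(self):
        assert RnaSequence.from_string("ggaaatt").residues == "GGAAAUU"

    def test_invalid_residue_names_position(self):
        with pytest.raises(InputError, match="position 3"):
            RnaSequence("GGNAA")

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            RnaSequence("")


class TestDotBracket:
    @pytest.mark.parametrize(
        "text,pairs",
        [
            (".......", set()),
            ("((...))", {(1, 7), (2, 6)}),
            ("(...)..", {(1, 5)}),
            ("(..(...)...)", {(1, 12), (4, 8)}),
        ],
    )
    def test_parse(self, text, pairs):
        s = parse_dot_bracket(text)
        assert s.n == len(text)
        assert set(s.pairs) == pairs

    @pytest.mark.parametrize("bad", ["(.))", "((..", "(x)"])
    def test_parse_errors(self, bad):
        with pytest.raises(InputError):
            parse_dot_bracket(bad)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            parse_dot_bracket("...", n=5)

    def test_to_dot_bracket(self):
        assert to_dot_bracket(SecondaryStructure(n=4)) == "...."
        s = SecondaryStructure(n=7, pairs={(1, 7), (2, 6)})
        assert to_dot_bracket(s) == "((...))"

    @given(st.integers(0, 19))
    def test_round_trip_over_random_structures(self, seed):
        _, ref = fixture(12, seed)
        assert parse_dot_bracket(to_dot_bracket(ref)) == ref


class TestStructureValidity:
    def test_crossing_rejected(self):
        with pytest.raises(InputError, match="crossing"):
            SecondaryStructure(n=10, pairs={(1, 6), (3, 9)})

    def test_shared_base_rejected(self):
        with pytest.raises(InputError):
            SecondaryStructure(n=10, pairs={(1, 6), (6, 10)})

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            SecondaryStructure(n=5, pairs={(1, 6)})


class TestHammingDistance:
    def test_identity_and_empty(self):
        s = parse_dot_bracket("((...))")
        assert hamming_distance(s, s) == 0
        empty = SecondaryStructure(n=7)
        assert hamming_distance(empty, s) == s.num_pairs

    def test_symmetric_difference_count(self):
        s1 = SecondaryStructure(n=7, pairs={(1, 6)})
        s2 = SecondaryStructure(n=7, pairs={(1, 7), (2, 6)})
        assert hamming_distance(s1, s2) == 3

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            hamming_distance(SecondaryStructure(n=5), SecondaryStructure(n=6))

    def test_metric_axioms_on_enumerated_ensemble(self):
        seq = RnaSequence("GGACAUGUCC")
        structs = list(enumerate_structures(seq, COUNTING))
        assert len(structs) > 3
        for a, b in itertools.combinations(structs, 2):
            assert hamming_distance(a, b) == hamming_distance(b, a) > 0
        for a, b, c in itertools.combinations(structs, 3):
            assert hamming_distance(a, c) <= (
                hamming_distance(a, b) + hamming_distance(b, c)
            )


class TestEndToEndDistance:
    def test_open_chain(self):
        assert end_to_end_distance(SecondaryStructure(n=9)) == 8

    def test_terminal_pair_gives_one(self):
        assert end_to_end_distance(SecondaryStructure(n=7, pairs={(1, 7)})) == 1
        s = SecondaryStructure(n=7, pairs={(1, 7), (2, 6)})
        assert end_to_end_distance(s) == 1

    def test_exterior_walk(self):
        # bond 1-2, bridge 2-6, bond 6-7
        assert end_to_end_distance(SecondaryStructure(n=7, pairs={(2, 6)})) == 3


class TestEnumeration:
    def test_unpairable_sequence(self):
        structs = list(enumerate_structures(RnaSequence("AAAA"), COUNTING))
        assert structs == [SecondaryStructure(n=4)]

    def test_worked_ensemble(self, ggaaacc):
        structs = {s.pairs for s in enumerate_structures(ggaaacc, COUNTING)}
        expected = [
            set(), {(1, 6)}, {(1, 7)}, {(2, 6)}, {(2, 7)}, {(1, 7), (2, 6)},
        ]
        assert structs == {frozenset(e) for e in expected}

    def test_single_admissible_pair(self):
        structs = list(enumerate_structures(RnaSequence("GAAAC"), COUNTING))
        assert len(structs) == 2

    def test_open_chain_comes_first(self, ggaaacc):
        first = next(iter(enumerate_structures(ggaaacc, COUNTING)))
        assert first.num_pairs == 0

    def test_count_monotone_in_theta_and_pairing_rule(self, ggaaacc):
        def count(model):
            return sum(1 for _ in enumerate_structures(ggaaacc, model))

        loose = count(COUNTING.with_(theta=2))
        base = count(COUNTING)
        tight = count(COUNTING.with_(theta=5))
        assert loose >= base >= tight
        gc_only = count(COUNTING.with_(allowed_pairs=frozenset({"GC", "CG"})))
        assert base >= gc_only

    def test_cap_refused(self):
        with pytest.raises(InputError, match="cap"):
            list(enumerate_structures(RnaSequence("A" * 30), COUNTING))
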