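"""The palette bijection: oligo order, subset order, and encode/decode."""

import itertools
from functools import cmp_to_key

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnapalette.errors import (
    CapacityError,
    InconsistentSubsetError,
    InvalidSequenceError,
    NotFoundError,
    RangeError,
)
from dnapalette.subset_codec import (
    OligoSubset,
    OligoUniverse,
    decode_subset,
    encode_bits,
    enumerate_subsets,
    oligo_less,
    oligo_rank,
    oligo_unrank,
    subset_less,
    subset_rank,
    subset_unrank,
)


class TestOligoOrder:
    def test_printed_chain(self):
        assert oligo_less("AAT", "AAG")
        assert oligo_less("AAG", "ATT")
        assert oligo_less("AAT", "ATT")  # transitivity along the chain

    def test_irreflexive(self):
        for o in ("A", "ACGT", "TTTT"):
            assert not oligo_less(o, o)

    def test_dinucleotides_sort_as_base4(self):
        # independent oracle: base-4 value with digit map A=0, T=1, G=2, C=3
        dinucs = ["".join(p) for p in itertools.product("ATGC", repeat=2)]
        digit = {"A": 0, "T": 1, "G": 2, "C": 3}
        by_value = sorted(dinucs, key=lambda o: digit[o[0]] * 4 + digit[o[1]])
        by_order = sorted(dinucs, key=cmp_to_key(lambda a, b: -1 if oligo_less(a, b) else 1))
        assert by_order == by_value

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidSequenceError):
            oligo_less("AA", "AAA")

    def test_non_dna_symbol_rejected(self):
        with pytest.raises(InvalidSequenceError):
            oligo_less("AN", "AA")


class TestUniverseRanking:
    def test_all_a_is_minimum(self):
        u = OligoUniverse(m=4)
        assert oligo_rank("AAAA", u) == 0
        assert oligo_unrank(0, u) == "AAAA"

    def test_explicit_three_oligo_universe(self):
        u = OligoUniverse(m=1, members=("A", "T", "G"))
        assert [oligo_rank(o, u) for o in "ATG"] == [0, 1, 2]

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_rank_matches_enumerated_sort(self, m):
        u = OligoUniverse(m=m)
        everything = ["".join(p) for p in itertools.product("ATGC", repeat=m)]
        ordered = sorted(everything, key=cmp_to_key(lambda a, b: -1 if oligo_less(a, b) else 1))
        for i, o in enumerate(ordered):
            assert oligo_rank(o, u) == i
            assert oligo_unrank(i, u) == o

    def test_unrank_examples(self):
        u = OligoUniverse(m=2)
        assert oligo_unrank(5, u) == "TT"  # base-4 digits 1,1

    def test_errors(self):
        u = OligoUniverse(m=1, members=("A", "T", "G"))
        with pytest.raises(NotFoundError):
            oligo_rank("C", u)
        with pytest.raises(RangeError):
            oligo_unrank(3, u)

    def test_roundtrip_random(self, rng):
        u = OligoUniverse(m=6)
        for i in rng.integers(0, u.n, 200):
            assert oligo_rank(oligo_unrank(int(i), u), u) == int(i)


class TestSubsetOrder:
    def test_empty_set_is_minimum(self):
        u = OligoUniverse(m=1, members=("A", "T", "G"))
        empty = OligoSubset(u, ())
        first = OligoSubset(u, (0,))
        assert subset_less(empty, first)
        assert not subset_less(first, empty)

    def test_singleton_enumeration(self):
        u = OligoUniverse(m=1, members=("A", "T", "G"))
        o1 = OligoSubset(u, (0,))
        o2 = OligoSubset(u, (1,))
        assert subset_less(o1, o2)

    def test_equal_sets_neither_less(self):
        u = OligoUniverse(m=2)
        s = OligoSubset(u, (0, 3))
        assert not subset_less(s, s)

    @pytest.mark.parametrize("n", [1, 4, 8, 12])
    def test_comparator_equals_rank_order_exhaustive(self, n):
        # brute-force oracle: sorting all 2**n subsets with the comparator
        # must reproduce the indicator-rank order exactly
        u = OligoUniverse(m=2, size=n) if n <= 16 else None
        subsets = list(enumerate_subsets(u))
        shuffled = list(reversed(subsets))
        resorted = sorted(
            shuffled, key=cmp_to_key(lambda a, b: -1 if subset_less(a, b) else 1)
        )
        assert [subset_rank(s) for s in resorted] == list(range(2**n))

    def test_cross_universe_comparison_rejected(self):
        a = OligoSubset(OligoUniverse(m=1), (0,))
        b = OligoSubset(OligoUniverse(m=2), (0,))
        with pytest.raises(ValueError):
            subset_less(a, b)


class TestRankUnrank:
    def test_printed_enumeration(self):
        u = OligoUniverse(m=1, members=("A", "T", "G"))
        assert subset_rank(OligoSubset(u, ())) == 0
        assert subset_rank(OligoSubset.from_members(["A"], u)) == 1
        assert subset_rank(OligoSubset.from_members(["A", "T", "G"], u)) == 7
        assert subset_unrank(0, u).members == ()
        assert subset_unrank(2, u).members == ("T",)

    def test_roundtrip_exhaustive_n12(self):
        u = OligoUniverse(m=2, size=12)
        for j in range(2**12):
            assert subset_rank(subset_unrank(j, u)) == j

    def test_out_of_range(self):
        u = OligoUniverse(m=1, members=("A", "T"))
        with pytest.raises(RangeError):
            subset_unrank(4, u)


class TestEncodeDecode:
    def test_published_toy_example(self):
        u = OligoUniverse(m=1, members=("A", "T", "G"))
        assert encode_bits("001", u).members == ("A",)
        assert encode_bits("000", u).members == ()
        assert encode_bits("111", u).members == ("A", "T", "G")
        assert decode_subset(OligoSubset.from_members(["A"], u), 3) == "001"
        assert decode_subset(OligoSubset(u, ()), 3) == "000"

    def test_capacity_error(self):
        u = OligoUniverse(m=1, members=("A", "T", "G"))
        with pytest.raises(CapacityError):
            encode_bits("0101", u)

    def test_spurious_oligo_detected(self):
        u = OligoUniverse(m=2)
        s = OligoSubset(u, (5,))
        with pytest.raises(InconsistentSubsetError):
            decode_subset(s, 3)

    def test_codeword_size_is_popcount(self, rng):
        u = OligoUniverse(m=3)
        for _ in range(50):
            bits = "".join(rng.choice(["0", "1"], 20))
            assert len(encode_bits(bits, u)) == bits.count("1")

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(min_value=1, max_value=64).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, 2**n - 1))))
    def test_bijection_roundtrip(self, n_and_value):
        n, value = n_and_value
        u = OligoUniverse(m=3)
        bits = format(value, f"0{n}b")
        subset = encode_bits(bits, u)
        assert subset_rank(subset) == value
        assert decode_subset(subset, n) == bits

    def test_roundtrip_many_random_messages(self, rng):
        # high-volume seeded sweep complementing the hypothesis cases
        u = OligoUniverse(m=3)
        values = rng.integers(0, 2**63, 10_000, dtype=np.uint64)
        for v in values:
            bits = format(int(v), "064b")
            assert decode_subset(encode_bits(bits, u), 64) == bits
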