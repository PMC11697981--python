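"""Quaternary VT structure: syndromes, systematic encoding, single-edit repair."""

import itertools

import numpy as np
import pytest

from dnapalette.errors import EncodingError, InvalidSequenceError
from dnapalette.vt_codec import (
    VTParams,
    payload_of,
    seq_to_values,
    values_to_seq,
    vt_check,
    vt_correct,
    vt_encode,
    vt_encode_batch,
    vt_syndrome,
)

ALPHABET = "ATGC"


@pytest.fixture(scope="module")
def params8():
    """Short, fully enumerable code: L=8, five tail checks, 3-nt payload."""
    return VTParams(length=8, scheme="tail", n_tail_checks=5)


@pytest.fixture(scope="module")
def codebook8(params8):
    return {
        vt_encode("".join(p), params8)
        for p in itertools.product(ALPHABET, repeat=params8.payload_length)
    }


@pytest.fixture(scope="module")
def params155():
    return VTParams(length=155)


class TestSyndrome:
    @pytest.mark.parametrize("L", [4, 8, 20])
    def test_all_a_closed_form(self, L):
        # alpha all ones (equal symbols count as ascents): a = L(L-1)/2 mod L, b = 0
        a, b = vt_syndrome("A" * L)
        assert a == (L * (L - 1) // 2) % L
        assert b == 0

    def test_single_symbol(self):
        for i, s in enumerate(ALPHABET):
            assert vt_syndrome(s, modulus=7) == (0, i)

    def test_pure_function(self):
        assert vt_syndrome("ATGCCA") == vt_syndrome("ATGCCA")

    def test_invalid_symbol(self):
        with pytest.raises(InvalidSequenceError):
            vt_syndrome("ATNX")


class TestEncoding:
    def test_systematic_and_valid(self, params8):
        for pay in ("AAA", "CGT", "TTG"):
            cw = vt_encode(pay, params8)
            assert vt_check(cw, params8)
            assert payload_of(cw, params8) == pay
            assert cw[: len(pay)] == pay  # tail checks leave the prefix alone

    def test_exhaustive_unique_codewords(self, codebook8, params8):
        assert len(codebook8) == 4**params8.payload_length

    def test_guarded_155_systematic(self, params155, rng):
        payloads = rng.integers(0, 4, (50, params155.payload_length)).astype(np.uint8)
        words = vt_encode_batch(payloads, params155)
        for p, w in zip(payloads, words):
            s = values_to_seq(w)
            assert vt_check(s, params155)
            assert payload_of(s, params155) == values_to_seq(p)

    def test_check_budget_155(self, params155):
        # rate accounting: 23 check symbols -> 132-nt payload per 155-nt oligo
        assert params155.n_checks == 23
        assert params155.payload_length == 132

    def test_infeasible_layout_rejected(self):
        # four tail checks cannot force every syndrome pair at L=8
        with pytest.raises(EncodingError):
            VTParams(length=8, scheme="tail", n_tail_checks=4)


class TestCheck:
    def test_wrong_length_fails(self, codebook8, params8):
        cw = next(iter(codebook8))
        assert not vt_check(cw[:-1], params8)
        assert not vt_check(cw + "A", params8)

    def test_substitution_changing_b_always_detected(self, codebook8, params8):
        # a value change is never 0 mod 4, so b shifts on every substitution
        for cw in codebook8:
            for i in range(8):
                for v in ALPHABET:
                    if v == cw[i]:
                        continue
                    assert not vt_check(cw[:i] + v + cw[i + 1:], params8)


class TestCorrection:
    def test_clean_passthrough(self, codebook8, params8):
        for cw in itertools.islice(codebook8, 10):
            assert vt_correct(cw, params8) == cw

    def test_exhaustive_single_deletion(self, codebook8, params8):
        for cw in codebook8:
            for i in range(8):
                assert vt_correct(cw[:i] + cw[i + 1:], params8) == cw

    def test_exhaustive_single_insertion(self, codebook8, params8):
        for cw in codebook8:
            for i in range(9):
                for v in ALPHABET:
                    assert vt_correct(cw[:i] + v + cw[i:], params8) == cw

    def test_exhaustive_substitution_never_miscorrects(self, codebook8, params8):
        # the defining safety property: corrected to the original or flagged,
        # never silently replaced by a different codeword
        for cw in codebook8:
            for i in range(8):
                for v in ALPHABET:
                    if v == cw[i]:
                        continue
                    out = vt_correct(cw[:i] + v + cw[i + 1:], params8)
                    assert out in (cw, None)

    def test_single_edits_at_155(self, params155, rng):
        payloads = rng.integers(0, 4, (20, params155.payload_length)).astype(np.uint8)
        for w in vt_encode_batch(payloads, params155):
            cw = values_to_seq(w)
            i = int(rng.integers(0, 155))
            v = ALPHABET[int(rng.integers(0, 4))]
            assert vt_correct(cw[:i] + cw[i + 1:], params155) == cw
            assert vt_correct(cw[:i] + v + cw[i:], params155) == cw
            sub = cw[:i] + v + cw[i + 1:]
            if sub != cw:
                assert vt_correct(sub, params155) in (cw, None)

    def test_hopeless_lengths_rejected(self, codebook8, params8):
        cw = next(iter(codebook8))
        assert vt_correct(cw[:5], params8) is None
        assert vt_correct(cw + "AAA", params8) is None
        assert vt_correct(cw.replace("A", "N"), params8) is None
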