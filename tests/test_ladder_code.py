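"""Ladder transform: alignment, XOR differencing, RS protection, reversibility."""

import numpy as np
import pytest

from dnapalette.errors import ConfigError, InvalidSequenceError
from dnapalette.ladder_code import (
    AlignmentProfile,
    LadderGeometry,
    align_labels,
    diff_decode,
    diff_encode,
    ladder_decode,
    ladder_encode,
    unalign,
)
from dnapalette.rs_code import RSParams


@pytest.fixture
def series(rng):
    return [rng.integers(0, 256, 700, dtype=np.uint8).tobytes() for _ in range(5)]


class TestAlignment:
    def test_identical_files_stay_identical(self):
        profile = AlignmentProfile(label_spans=((4, 8),))
        files = [b"\x11" * 64] * 3
        aligned, _ = align_labels(files, profile)
        assert aligned[0] == aligned[1] == aligned[2]

    def test_roundtrip_with_ragged_lengths(self, rng):
        profile = AlignmentProfile(label_spans=((0, 4), (16, 8)), pad_byte=0)
        files = [rng.integers(0, 256, n, dtype=np.uint8).tobytes() for n in (64, 100, 80)]
        aligned, geom = align_labels(files, profile)
        assert len({len(a) for a in aligned}) == 1
        assert unalign(aligned, geom) == files

    def test_single_byte_difference_preserved(self):
        profile = AlignmentProfile(label_spans=((8, 4),))
        base = bytearray(range(64))
        other = bytearray(base)
        other[40] ^= 0xFF
        aligned, _ = align_labels([bytes(base), bytes(other)], profile)
        diff = [i for i, (x, y) in enumerate(zip(*aligned)) if x != y]
        assert len(diff) == 1

    def test_span_outside_padded_length(self):
        with pytest.raises(ConfigError):
            align_labels([b"\x00" * 16], AlignmentProfile(label_spans=((10, 20),)))

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ConfigError):
            AlignmentProfile(label_spans=((0, 8), (4, 8)))


class TestDiff:
    def test_identical_files_give_zero_segments(self):
        files = [b"\xaa" * 32] * 4
        stream = diff_encode(files)
        assert stream[:32] == files[0]
        assert set(stream[32:]) == {0}

    def test_roundtrip(self, series):
        profile = AlignmentProfile()
        aligned, geom = align_labels(series, profile)
        assert diff_decode(diff_encode(aligned), geom) == aligned

    def test_segment_weight_matches_hamming_difference(self, rng):
        a = rng.integers(0, 256, 128, dtype=np.uint8)
        b = a.copy()
        flip = rng.choice(128, 10, replace=False)
        b[flip] ^= rng.integers(1, 256, 10).astype(np.uint8)
        stream = diff_encode([a.tobytes(), b.tobytes()])
        seg1 = np.frombuffer(stream[128:], dtype=np.uint8)
        expected = np.unpackbits(a ^ b).sum()
        assert np.unpackbits(seg1).sum() == expected

    def test_zero_stream_means_all_files_equal_first(self):
        geom = LadderGeometry((16, 16, 16), 16, AlignmentProfile())
        stream = bytes(range(16)) + bytes(32)
        files = diff_decode(stream, geom)
        assert files[0] == files[1] == files[2] == bytes(range(16))

    def test_corruption_propagates_forward_only(self, series):
        aligned, geom = align_labels(series, AlignmentProfile())
        stream = bytearray(diff_encode(aligned))
        t, offset = 2, 123
        stream[t * 700 + offset] ^= 0x40
        decoded = diff_decode(bytes(stream), geom)
        for i, (got, want) in enumerate(zip(decoded, aligned)):
            diffs = [j for j, (x, y) in enumerate(zip(got, want)) if x != y]
            assert diffs == ([offset] if i >= t else [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidSequenceError):
            diff_encode([b"\x00" * 8, b"\x00" * 9])


class TestFullLadder:
    def test_identity_roundtrip(self, series):
        profile = AlignmentProfile(label_spans=((2, 6),), pad_byte=0)
        protected, geom = ladder_encode(series, profile, RSParams(255, 223))
        files, failed = ladder_decode(protected, geom)
        assert failed == [] and files == series

    def test_sparsification_monotone_in_diff_rate(self, rng):
        # the post-diff one-bit density tracks the inter-file change rate
        densities = []
        for delta in (0.0, 0.02, 0.2):
            base = rng.integers(0, 256, 2048, dtype=np.uint8)
            nxt = base.copy()
            n = int(delta * 2048)
            if n:
                off = rng.choice(2048, n, replace=False)
                nxt[off] = rng.integers(0, 256, n, dtype=np.uint8)
            stream = diff_encode([base.tobytes(), nxt.tobytes()])
            seg = np.frombuffer(stream[2048:], dtype=np.uint8)
            densities.append(np.unpackbits(seg).mean())
        assert densities[0] == 0.0
        assert densities[0] < densities[1] < densities[2]

    def test_error_localization(self, series):
        protected, geom = ladder_encode(series, None, RSParams(15, 11))
        noisy = bytearray(protected)
        for i in range(11, 11 + 8):  # block 1 data region: beyond capacity
            noisy[i] ^= 0xFF
        files, failed = ladder_decode(bytes(noisy), geom)
        assert 1 in failed
        # damage confined to the flagged block's bytes (plus diff propagation
        # at those offsets); everything before the block is untouched
        assert files[0][:11] == series[0][:11]
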