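"""Ladder pre-transform: label alignment, differential encoding, block RS.

Time-series archives (e.g. consecutive MRI slices) are highly redundant
between files.  The ladder transform concentrates that redundancy into zeros:

1. *label alignment* — pad every file to a common length and gather the
   volatile label fields (timestamps, instance numbers, ...) into a contiguous
   prefix, so corresponding payload bytes sit at identical offsets;
2. *differential encoding* — file 0 is stored verbatim, file t (t >= 1) as the
   byte-wise XOR with file t-1, which zeroes everything that did not change;
3. *block Reed–Solomon* — parity bytes that later absorb residual byte errors
   and dropout-induced bit losses, per block, so damage stays local.

Stages 1 and 2 are exactly reversible and add no redundancy; only stage 3
appends parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InvalidSequenceError
from .rs_code import RSParams, rs_protect, rs_repair


@dataclass(frozen=True)
class AlignmentProfile:
    """Byte-level layout shared by all files of a series.

    ``label_spans`` are (offset, length) regions holding per-file volatile
    fields; everything else is treated as payload.  Spans must not overlap and
    must fit inside the common padded length.
    """

    label_spans: tuple[tuple[int, int], ...] = ()
    pad_byte: int = 0

    def __post_init__(self):
        spans = tuple(sorted((int(o), int(l)) for o, l in self.label_spans))
        for (o1, l1), (o2, _) in zip(spans, spans[1:]):
            if o1 + l1 > o2:
                raise ConfigError(f"label spans overlap at offset {o2}")
        if any(o < 0 or l <= 0 for o, l in spans):
            raise ConfigError("label spans must have non-negative offset, positive length")
        if not 0 <= self.pad_byte <= 255:
            raise ConfigError("pad byte out of range")
        object.__setattr__(self, "label_spans", spans)


@dataclass(frozen=True)
class LadderGeometry:
    """Everything needed to invert the ladder transform."""

    file_lengths: tuple[int, ...]
    padded_length: int
    profile: AlignmentProfile
    rs: RSParams | None = None

    @property
    def n_files(self) -> int:
        return len(self.file_lengths)

    @property
    def stream_length(self) -> int:
        """Pre-RS stream length in bytes."""
        return self.n_files * self.padded_length


def _span_permutation(profile: AlignmentProfile, length: int) -> np.ndarray:
    """Byte permutation moving label spans to a contiguous prefix."""
    in_label = np.zeros(length, dtype=bool)
    for off, ln in profile.label_spans:
        if off + ln > length:
            raise ConfigError(
                f"label span ({off}, {ln}) exceeds padded file length {length}"
            )
        in_label[off: off + ln] = True
    return np.concatenate([np.flatnonzero(in_label), np.flatnonzero(~in_label)])


def align_labels(
    files: list[bytes], profile: AlignmentProfile
) -> tuple[list[bytes], LadderGeometry]:
    """Pad files to a common length and gather label fields into a prefix.

    Reversible given the returned geometry; identical files stay identical and
    a single differing payload byte stays a single differing byte.
    """
    if not files:
        raise ConfigError("series must contain at least one file")
    lengths = tuple(len(f) for f in files)
    padded_len = max(lengths)
    perm = _span_permutation(profile, padded_len)
    out = []
    for f in files:
        buf = np.full(padded_len, profile.pad_byte, dtype=np.uint8)
        buf[: len(f)] = np.frombuffer(f, dtype=np.uint8)
        out.append(buf[perm].tobytes())
    return out, LadderGeometry(lengths, padded_len, profile)


def unalign(aligned: list[bytes], geometry: LadderGeometry) -> list[bytes]:
    """Exact inverse of :func:`align_labels` (truncates padding)."""
    perm = _span_permutation(geometry.profile, geometry.padded_length)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    out = []
    for f, orig_len in zip(aligned, geometry.file_lengths):
        buf = np.frombuffer(f, dtype=np.uint8)[inv]
        out.append(buf[:orig_len].tobytes())
    return out


def diff_encode(aligned: list[bytes]) -> bytes:
    """Byte-wise XOR differencing: segment 0 verbatim, segment t = f_t ^ f_{t-1}."""
    lengths = {len(f) for f in aligned}
    if len(lengths) != 1:
        raise InvalidSequenceError("aligned files must share one length")
    mat = np.stack([np.frombuffer(f, dtype=np.uint8) for f in aligned])
    out = mat.copy()
    out[1:] = mat[1:] ^ mat[:-1]
    return out.reshape(-1).tobytes()


def diff_decode(stream: bytes, geometry: LadderGeometry) -> list[bytes]:
    """Prefix-XOR inverse of :func:`diff_encode`.

    A corrupted byte in segment t corrupts files t..T-1 at that offset only
    (until the next absolute segment — here only segment 0 is absolute).
    """
    n, plen = geometry.n_files, geometry.padded_length
    buf = np.frombuffer(stream, dtype=np.uint8)
    if buf.size != n * plen:
        raise InvalidSequenceError(
            f"stream length {buf.size} != {n} files x {plen} bytes"
        )
    mat = buf.reshape(n, plen).copy()
    np.bitwise_xor.accumulate(mat, axis=0, out=mat)
    return [row.tobytes() for row in mat]


def ladder_encode(
    files: list[bytes],
    profile: AlignmentProfile | None = None,
    rs: RSParams | None = RSParams(255, 223),
) -> tuple[bytes, LadderGeometry]:
    """Full forward transform: align, diff, RS-protect."""
    profile = profile or AlignmentProfile()
    aligned, geom = align_labels(files, profile)
    stream = diff_encode(aligned)
    geom = LadderGeometry(geom.file_lengths, geom.padded_length, profile, rs)
    if rs is not None:
        stream = rs_protect(stream, rs)
    return stream, geom


def ladder_decode(
    protected: bytes, geometry: LadderGeometry
) -> tuple[list[bytes], list[int]]:
    """Inverse transform; returns files and the indices of unrepairable RS blocks."""
    failed: list[int] = []
    stream = protected
    if geometry.rs is not None:
        stream, failed = rs_repair(protected, geometry.rs)
    stream = stream[: geometry.stream_length]
    if len(stream) < geometry.stream_length:  # truncated input: pad, keep going
        stream = stream + bytes(geometry.stream_length - len(stream))
    aligned = diff_decode(stream, geometry)
    return unalign(aligned, geometry), failed
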