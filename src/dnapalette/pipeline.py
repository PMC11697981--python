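"""The full palette codec: ladder stream -> labelled VT oligos and back.

Encoding pipeline
-----------------
1. ladder transform (align, XOR-diff, block RS) -> protected byte stream;
2. the stream, read as bits (least-significant bit of each byte first), is cut
   into blocks of ``block_bits`` positions;
3. within block ``t`` the positions of one-bits are the indicator subset of
   the block's address universe (the palette bijection); the one positions,
   reordered by ``(byte mod 4096, position)``, are chunked ``K`` at a time
   into ``ceil(w / K)`` oligos, each laid out as
   ``label(t) | address_1 .. address_K | VT checks`` and padded with the
   reserved null address (all C) when the block weight is not a multiple of K;
4. every oligo is made a quaternary VT codeword (syndrome forcing).

The packing order in step 3 is chosen for dropout resilience: bits of the
*same* stream byte travel together (losing an oligo then costs one byte error,
not up to eight), while successive byte groups of one oligo sit 4096 stream
bytes apart — many RS blocks away — so a dropped oligo becomes a handful of
isolated single-byte errors scattered over distant RS blocks.  The expected
damage per RS block is then bounded by ``p_drop x nonzero-bytes-per-block``
regardless of how dense the data is, which the default RS(255, 191) absorbs
with a wide margin.

Decoding is trace reconstruction: VT-filter/correct each read, group identical
survivors, majority-vote (multiplicity threshold plus strict plurality within
each label+first-address group), union the accepted addresses into bits, then
invert RS, diff, and alignment.  Decoding never aborts on partial data.
"""

from __future__ import annotations

import hashlib
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import CapacityError, ConfigError, DnaPaletteError
from .ladder_code import AlignmentProfile, LadderGeometry, ladder_decode, ladder_encode
from .rs_code import RSParams
from .subset_codec import OligoUniverse, oligo_from_value, oligo_value
from .vt_codec import VTParams, seq_to_values, values_to_seq, vt_correct, vt_encode_batch

NULL_SYMBOL_VALUE = 3  # 'C'

#: Byte-interleave period of the address packing order (see module docstring).
PACKING_PERIOD_BYTES = 4096


@dataclass(frozen=True)
class CodecConfig:
    """All lengths, redundancy levels and thresholds of the codec.

    The oligo payload is ``label_len + addrs_per_oligo * addr_len`` symbols;
    together with the VT check symbols it must equal ``payload_len`` (155 nt
    by default).  ``block_bits`` is the number of addressable bit positions
    per label block.  ``address_universe`` may name an explicit ordered oligo
    set (used by small/teaching configurations); by default addresses are the
    first ``block_bits`` length-``addr_len`` sequences, with the all-C
    sequence reserved as the null (padding) address.
    """

    payload_len: int = 155
    label_len: int = 12
    addr_len: int = 10
    addrs_per_oligo: int = 12
    vt: VTParams | None = field(default_factory=lambda: VTParams(length=155))
    block_bits: int = 2**19
    rs: RSParams | None = field(default_factory=lambda: RSParams(255, 191))
    vote_threshold: int | None = None
    address_universe: OligoUniverse | None = None

    def __post_init__(self):
        n_checks = self.vt.n_checks if self.vt is not None else 0
        expect = self.label_len + self.addrs_per_oligo * self.addr_len + n_checks
        if expect != self.payload_len:
            raise ConfigError(
                f"label_len + K*addr_len + vt checks = {expect} "
                f"!= payload_len {self.payload_len}"
            )
        if self.vt is not None and self.vt.length != self.payload_len:
            raise ConfigError("VT codeword length must equal payload_len")
        if self.addrs_per_oligo < 1:
            raise ConfigError("need at least one address per oligo")
        if self.address_universe is not None:
            u = self.address_universe
            if u.m != self.addr_len:
                raise ConfigError("address universe oligo length must equal addr_len")
            if self.block_bits > u.n:
                raise ConfigError("block_bits exceeds the address universe size")
            if self.addrs_per_oligo > 1 and "C" * self.addr_len in u:
                raise ConfigError(
                    "the all-C null address must stay outside the universe when K > 1"
                )
        elif self.block_bits > 4**self.addr_len - 1:
            raise ConfigError(
                f"block_bits {self.block_bits} exceeds addressable space "
                f"4**{self.addr_len} - 1 (all-C is the reserved null address)"
            )

    @classmethod
    def toy(cls) -> "CodecConfig":
        """The three-oligo teaching configuration: universe {A, T, G}, K=1,
        no label, no VT checks, no ladder — '001' encodes to the pool {A}."""
        return cls(
            payload_len=1,
            label_len=0,
            addr_len=1,
            addrs_per_oligo=1,
            vt=None,
            block_bits=3,
            rs=None,
            address_universe=OligoUniverse(m=1, members=("A", "T", "G")),
        )

    # -- address <-> symbol helpers --------------------------------------

    @property
    def null_address(self) -> str:
        return "C" * self.addr_len

    def address_seq(self, index: int) -> str:
        if self.address_universe is not None:
            return self.address_universe.unrank(index)
        return oligo_from_value(index, self.addr_len)

    def address_index(self, seq: str) -> int | None:
        """Index of an address segment, or None for the null address."""
        if seq == self.null_address and self.address_universe is None:
            return None
        if self.address_universe is not None:
            if seq == self.null_address and seq not in self.address_universe:
                return None
            return self.address_universe.rank(seq)  # may raise NotFoundError
        return oligo_value(seq)


@dataclass
class DecodeReport:
    """Per-run decoding statistics (rates in [0, 1])."""

    n_reads: int
    discarded_reads: int
    accepted_oligos: int
    pool_size: int
    mean_coverage: float
    dropout_rate: float
    flagged_blocks: list[int]
    recovered_bytes: int


@dataclass(frozen=True)
class Metrics:
    """Storage metrics on the scale the field reports them."""

    r_bn: float                      # net information density, bits per nucleotide
    byte_error_rate: float | None
    dropout_rate: float | None
    mean_coverage: float | None
    oligo_count: int


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def _digit_matrix(values: np.ndarray, width: int) -> np.ndarray:
    """Base-4 digits (most significant first) of each value, as uint8 rows."""
    shifts = 2 * np.arange(width - 1, -1, -1, dtype=np.int64)
    return ((values[:, None] >> shifts[None, :]) & 3).astype(np.uint8)


def encode_stream_bits(bits: np.ndarray, cfg: CodecConfig) -> list[str]:
    """Palette-encode a 0/1 bit array into an oligo pool (no ladder stage).

    Deterministic; oligo count is ``sum_t ceil(weight_t / K)`` and an all-zero
    block emits no oligos at all.
    """
    bits = np.asarray(bits, dtype=np.uint8)
    B, K = cfg.block_bits, cfg.addrs_per_oligo
    n_blocks = max(1, -(-bits.size // B))
    if cfg.label_len == 0:
        if n_blocks > 1:
            raise CapacityError("label-less configuration fits a single block only")
    elif n_blocks > 4**cfg.label_len:
        raise CapacityError(
            f"{n_blocks} blocks exceed label capacity 4**{cfg.label_len}; "
            "raise label_len or block_bits"
        )
    explicit = cfg.address_universe is not None
    rows = []
    for t in range(n_blocks):
        ones = np.flatnonzero(bits[t * B: (t + 1) * B]).astype(np.int64)
        w = ones.size
        if w == 0:
            continue
        n_oligos = -(-w // K)
        label = _digit_matrix(np.full(n_oligos, t, dtype=np.int64), cfg.label_len)
        # byte-grouped interleaved packing, see module docstring
        residue = (ones >> 3) % PACKING_PERIOD_BYTES
        packed = ones[np.lexsort((ones, residue))]
        addr_rows = np.full((n_oligos * K,), -1, dtype=np.int64)
        addr_rows[: w] = packed
        addr_rows = addr_rows.reshape(n_oligos, K)
        if explicit:
            addr_digits = np.empty((n_oligos, K * cfg.addr_len), dtype=np.uint8)
            for j in range(n_oligos):
                segs = [
                    seq_to_values(cfg.address_seq(int(a))) if a >= 0
                    else np.full(cfg.addr_len, NULL_SYMBOL_VALUE, np.uint8)
                    for a in addr_rows[j]
                ]
                addr_digits[j] = np.concatenate(segs)
        else:
            flat = addr_rows.reshape(-1)
            digs = _digit_matrix(np.where(flat >= 0, flat, 0), cfg.addr_len)
            digs[flat < 0] = NULL_SYMBOL_VALUE
            addr_digits = digs.reshape(n_oligos, K * cfg.addr_len)
        rows.append(np.hstack([label, addr_digits]))
    if not rows:
        return []
    payloads = np.vstack(rows)
    if cfg.vt is not None:
        words = vt_encode_batch(payloads, cfg.vt)
    else:
        words = payloads
    return [values_to_seq(w) for w in words]


def encode(
    files: Sequence[bytes],
    cfg: CodecConfig | None = None,
    profile: AlignmentProfile | None = None,
) -> tuple[list[str], "Manifest"]:
    """Encode a file series into an unordered oligo pool plus its manifest."""
    from .manifest import Manifest  # local import to avoid a cycle

    cfg = cfg or CodecConfig()
    files = [bytes(f) for f in files]
    if not files:
        raise ConfigError("series must contain at least one file")
    protected, geometry = ladder_encode(files, profile, cfg.rs)
    bits = np.unpackbits(np.frombuffer(protected, dtype=np.uint8), bitorder="little")
    pool = encode_stream_bits(bits, cfg)
    digest = hashlib.sha256(b"".join(files)).hexdigest()
    manifest = Manifest(
        config=cfg,
        geometry=geometry,
        protected_len=len(protected),
        pool_size=len(pool),
        input_sha256=digest,
    )
    return pool, manifest


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def majority_vote(
    corrected: Iterable[str],
    cfg: CodecConfig,
    threshold: int,
) -> list[str]:
    """Select oligos from VT-validated reads.

    A sequence is accepted iff its multiplicity is at least ``threshold`` and
    it is the strict plurality among candidates sharing its label +
    first-address prefix; tied groups are discarded entirely (treated as
    dropout).  Linear in the number of reads.
    """
    counts = Counter(corrected)
    prefix_len = cfg.label_len + cfg.addr_len
    groups: dict[str, list[tuple[int, str]]] = {}
    for seq, cnt in counts.items():
        if cnt < threshold:
            continue
        if cfg.vt is not None:
            payload_cols = cfg.vt._payload_cols()
            payload = values_to_seq(seq_to_values(seq)[payload_cols])
        else:
            payload = seq
        groups.setdefault(payload[:prefix_len], []).append((cnt, seq))
    accepted = []
    for cands in groups.values():
        if len(cands) == 1:
            accepted.append(cands[0][1])
            continue
        cands.sort(reverse=True)
        if cands[0][0] > cands[1][0]:
            accepted.append(cands[0][1])
        # tied top counts: conflicting evidence, drop the whole group
    return accepted


def _parse_oligo(seq: str, cfg: CodecConfig, total_bits: int) -> list[int] | None:
    """Label + addresses -> absolute bit positions; None if inconsistent."""
    vals = seq_to_values(seq)
    payload = vals[cfg.vt._payload_cols()] if cfg.vt is not None else vals
    pos = 0
    t = 0
    for _ in range(cfg.label_len):
        t = (t << 2) | int(payload[pos])
        pos += 1
    base = t * cfg.block_bits
    if base >= total_bits:
        return None
    block_len = min(cfg.block_bits, total_bits - base)
    out = []
    for _ in range(cfg.addrs_per_oligo):
        seg = values_to_seq(payload[pos: pos + cfg.addr_len])
        pos += cfg.addr_len
        try:
            idx = cfg.address_index(seg)
        except DnaPaletteError:
            return None
        if idx is None:
            continue
        if idx >= block_len:
            return None
        out.append(base + idx)
    return out


def decode(
    reads: Sequence[str],
    manifest: "Manifest",
) -> tuple[list[bytes], DecodeReport]:
    """Trace-reconstruct the file series from unordered, noisy reads.

    Never raises on partial or empty data: whatever survives VT filtering,
    majority voting and RS repair is returned, with quality conveyed in the
    report.
    """
    cfg = manifest.config
    total_bits = 8 * manifest.protected_len
    corrected = []
    discarded = 0
    for read in reads:
        seq = read.upper()
        if cfg.vt is not None:
            fixed = vt_correct(seq, cfg.vt)
        else:
            fixed = seq if len(seq) == cfg.payload_len else None
        if fixed is None:
            discarded += 1
        else:
            corrected.append(fixed)
    pool_size = max(1, manifest.pool_size)
    coverage = len(reads) / pool_size
    threshold = cfg.vote_threshold or (2 if coverage >= 3.0 else 1)
    accepted = majority_vote(corrected, cfg, threshold)

    bits = np.zeros(total_bits, dtype=np.uint8)
    n_valid = 0
    for seq in accepted:
        positions = _parse_oligo(seq, cfg, total_bits)
        if positions is None:
            continue
        n_valid += 1
        bits[positions] = 1
    protected = np.packbits(bits, bitorder="little").tobytes()
    files, flagged = ladder_decode(protected, manifest.geometry)
    report = DecodeReport(
        n_reads=len(reads),
        discarded_reads=discarded,
        accepted_oligos=n_valid,
        pool_size=manifest.pool_size,
        mean_coverage=coverage,
        dropout_rate=max(0, manifest.pool_size - n_valid) / pool_size,
        flagged_blocks=flagged,
        recovered_bytes=sum(len(f) for f in files),
    )
    return files, report


# ---------------------------------------------------------------------------
# baseline and metrics
# ---------------------------------------------------------------------------


def encode_indexed_baseline(
    files: Sequence[bytes],
    cfg: CodecConfig | None = None,
    profile: AlignmentProfile | None = None,
) -> list[str]:
    """Sequentially indexed encoding at matched error-correcting redundancy.

    The same ladder stream is packed densely at 2 bits/nt into oligos of the
    same length, each prepended with a sequential index and carrying the same
    VT check symbols — the classic index-added construction the palette code
    is compared against.  The comparison baseline only; it has no decoder
    here.
    """
    cfg = cfg or CodecConfig()
    protected, _ = ladder_encode([bytes(f) for f in files], profile, cfg.rs)
    bits = np.unpackbits(np.frombuffer(protected, dtype=np.uint8), bitorder="little")
    n_checks = cfg.vt.n_checks if cfg.vt is not None else 0
    index_len = 1
    while True:
        data_nt = cfg.payload_len - n_checks - index_len
        if data_nt <= 0:
            raise CapacityError("payload too small for the indexed baseline")
        n_oligos = -(-bits.size // (2 * data_nt))
        if 4**index_len >= n_oligos:
            break
        index_len += 1
    padded = np.zeros(n_oligos * 2 * data_nt, dtype=np.uint8)
    padded[: bits.size] = bits
    pairs = padded.reshape(n_oligos, data_nt, 2)
    data_digits = (pairs[:, :, 0] | (pairs[:, :, 1] << 1)).astype(np.uint8)
    index_digits = _digit_matrix(np.arange(n_oligos, dtype=np.int64), index_len)
    payloads = np.hstack([index_digits, data_digits])
    if cfg.vt is not None and payloads.shape[1] == cfg.vt.payload_length:
        words = vt_encode_batch(payloads, cfg.vt)
    else:  # index width differs from K*addr_len + label: emit unchecked payloads
        words = payloads
    return [values_to_seq(w) for w in words]


def compute_metrics(
    input_data: bytes | Sequence[bytes] | int | float,
    pool: Sequence[str] | int,
    reads: Sequence[str] | int | None = None,
    decoded: bytes | Sequence[bytes] | None = None,
    payload_len: int = 155,
) -> Metrics:
    """Net information density and channel statistics.

    ``r(b/n)`` is input bits over synthesized payload nucleotides; the dropout
    rate is the fraction of pool oligos with no exact surviving read; the byte
    error rate compares decoded output with the input byte-for-byte.  Integer
    shorthands are accepted where only counts matter (e.g. reproducing
    published density arithmetic from oligo counts).
    """

    def _as_bytes(x):
        if isinstance(x, (bytes, bytearray)):
            return bytes(x)
        return b"".join(bytes(f) for f in x)

    input_bytes = (
        input_data if isinstance(input_data, (int, float)) else len(_as_bytes(input_data))
    )
    if isinstance(pool, int):
        oligo_count = pool
    else:
        oligo_count = len(pool)
        if pool:
            payload_len = len(pool[0])
    if oligo_count == 0:
        raise ConfigError("empty pool: net information density is undefined")
    r_bn = input_bytes * 8 / (oligo_count * payload_len)

    mean_coverage = dropout = None
    if reads is not None:
        n_reads = reads if isinstance(reads, int) else len(reads)
        mean_coverage = n_reads / oligo_count
        if not isinstance(reads, int) and not isinstance(pool, int):
            seen = set(reads)
            dropout = sum(1 for o in pool if o not in seen) / oligo_count

    ber = None
    if decoded is not None and not isinstance(input_data, (int, float)):
        a = np.frombuffer(_as_bytes(input_data), dtype=np.uint8)
        b = np.frombuffer(_as_bytes(decoded), dtype=np.uint8)
        n = min(a.size, b.size)
        mismatches = int((a[:n] != b[:n]).sum()) + abs(a.size - b.size)
        ber = mismatches / max(1, a.size)

    return Metrics(
        r_bn=r_bn,
        byte_error_rate=ber,
        dropout_rate=dropout,
        mean_coverage=mean_coverage,
        oligo_count=oligo_count,
    )
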