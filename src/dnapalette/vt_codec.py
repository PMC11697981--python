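"""Quaternary Varshamov–Tenengolts structure for single-edit protection.

Every synthesized oligo is a word ``s`` of length ``L`` over A/T/G/C whose two
Tenengolts syndromes are forced to fixed targets:

* ascent syndrome ``a(s) = sum_{i=1}^{L-1} i * alpha_i  (mod L)`` where
  ``alpha_i = 1`` iff ``s_{i+1} >= s_i`` under A=0 < T=1 < G=2 < C=3;
* sum syndrome ``b(s) = sum_i value(s_i)  (mod 4)``.

Words with equal ``(a, b)`` form a single-deletion-correcting (hence also
single-insertion-correcting) code, which is what lets the decoder realign a
155-nt read that lost or gained one base.  Substitutions always disturb ``b``
and are corrected when a unique consistent repair exists.

Systematic encoding (placing check symbols so that both syndromes hit their
targets) is non-trivial because a check symbol influences ``a`` only through
the ascents at its two flanks, whose weights are its neighbour positions.  Two
layouts are provided:

``tail``
    All ``c`` check symbols at the end of the word, chosen by exhaustive
    search over the ``4**c`` assignments.  Feasible only for short words
    (validated exhaustively at construction); used for small, fully
    enumerable codes.

``guarded``
    Check symbols grouped into ``(C, x, A)`` triples — a high guard, a free
    symbol, a low guard — plus one ``(C, x)`` tail pair.  The guards pin the
    flanking ascents regardless of payload, so each free symbol contributes a
    payload-independent, precomputable shift to ``(a, b)``.  With triple
    centres spread across the word the shifts span every residue pair, giving
    O(1) syndrome forcing at any length.  This is the layout used for the
    155-nt pipeline oligos.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EncodingError, InvalidSequenceError
from .subset_codec import NUCLEOTIDE_ORDER, SYMBOL_VALUE

#: Default triple centres for the 155-nt pipeline codeword (1-based positions).
DEFAULT_TRIPLE_CENTERS_155 = (24, 44, 64, 84, 104, 124, 144)

_SEQ_TO_VAL = np.full(256, 255, dtype=np.uint8)
for _s, _v in SYMBOL_VALUE.items():
    _SEQ_TO_VAL[ord(_s)] = _v
_VAL_TO_SEQ = np.frombuffer(NUCLEOTIDE_ORDER.encode(), dtype=np.uint8)


def seq_to_values(seq: str) -> np.ndarray:
    """Map a DNA string to its uint8 value array (A=0, T=1, G=2, C=3)."""
    raw = np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)
    vals = _SEQ_TO_VAL[raw]
    if vals.max(initial=0) > 3:
        bad = seq[int(np.argmax(vals > 3))]
        raise InvalidSequenceError(f"non-DNA symbol {bad!r} in sequence")
    return vals


def values_to_seq(vals: np.ndarray) -> str:
    """Inverse of :func:`seq_to_values`."""
    return _VAL_TO_SEQ[np.asarray(vals, dtype=np.uint8)].tobytes().decode("ascii")


def vt_syndrome(seq: str | np.ndarray, modulus: int | None = None) -> tuple[int, int]:
    """Tenengolts syndrome pair ``(a, b)`` of a non-empty segment.

    ``a`` is taken modulo ``modulus`` (the segment length by default) and ``b``
    modulo 4.
    """
    vals = seq_to_values(seq) if isinstance(seq, str) else np.asarray(seq)
    if vals.size == 0:
        raise InvalidSequenceError("empty segment has no syndrome")
    mod = vals.size if modulus is None else modulus
    asc = (vals[1:] >= vals[:-1]).astype(np.int64)
    a = int(np.arange(1, vals.size, dtype=np.int64) @ asc) % mod
    b = int(vals.sum(dtype=np.int64)) % 4
    return a, b


def _syndromes_matrix(vals: np.ndarray, modulus: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise syndromes of a (rows x L) value matrix."""
    asc = (vals[:, 1:] >= vals[:, :-1]).astype(np.int64)
    weights = np.arange(1, vals.shape[1], dtype=np.int64)
    a = (asc @ weights) % modulus
    b = vals.sum(axis=1, dtype=np.int64) % 4
    return a, b


@dataclass(frozen=True)
class VTParams:
    """Parameters of the systematic quaternary VT code.

    ``guard_positions``/``guard_values`` are fixed symbols, ``free_positions``
    the searchable check symbols; together they form the check region.  All
    positions are 1-based, matching the syndrome weight convention.
    """

    length: int
    a_target: int = 0
    b_target: int = 0
    scheme: str = "guarded"
    triple_centers: tuple[int, ...] = ()
    n_tail_checks: int = 0
    guard_positions: tuple[int, ...] = field(init=False, default=())
    guard_values: tuple[int, ...] = field(init=False, default=())
    free_positions: tuple[int, ...] = field(init=False, default=())
    _table: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        L = self.length
        if L < 4:
            raise ValueError("codeword length must be at least 4")
        if self.scheme == "guarded":
            centers = self.triple_centers or (
                DEFAULT_TRIPLE_CENTERS_155 if L == 155 else self._auto_centers(L)
            )
            object.__setattr__(self, "triple_centers", tuple(centers))
            guards, gvals, free = [], [], []
            for p in centers:
                if not 3 <= p <= L - 3:
                    raise ValueError(f"triple centre {p} too close to the word edge")
                guards += [p - 1, p + 1]
                gvals += [3, 0]
                free.append(p)
            guards.append(L - 1)
            gvals.append(3)
            free.append(L)
            occupied = sorted(guards + free)
            if len(set(occupied)) != len(occupied):
                raise ValueError("check triples/pair overlap")
            object.__setattr__(self, "guard_positions", tuple(guards))
            object.__setattr__(self, "guard_values", tuple(gvals))
            object.__setattr__(self, "free_positions", tuple(free))
            object.__setattr__(self, "_table", self._build_guarded_table())
        elif self.scheme == "tail":
            c = self.n_tail_checks or 5
            if c >= L:
                raise ValueError("tail check count must be below the word length")
            object.__setattr__(self, "n_tail_checks", c)
            object.__setattr__(
                self, "free_positions", tuple(range(L - c + 1, L + 1))
            )
            self._validate_tail()
        else:
            raise ValueError(f"unknown VT scheme {self.scheme!r}")

    @staticmethod
    def _auto_centers(L: int) -> tuple[int, ...]:
        # seven evenly spread triples, mirroring the validated 155-nt layout
        if L < 48:
            raise ValueError(
                f"guarded scheme needs length >= 48 (got {L}); use scheme='tail'"
            )
        lo, hi = max(4, L // 6), L - 11
        return tuple(round(lo + k * (hi - lo) / 6) for k in range(7))

    # -- layout helpers ---------------------------------------------------

    @property
    def n_checks(self) -> int:
        """Total check symbols (guards + free) per codeword."""
        return len(self.guard_positions) + len(self.free_positions)

    @property
    def payload_length(self) -> int:
        return self.length - self.n_checks

    @property
    def check_positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.guard_positions + self.free_positions))

    @property
    def payload_positions(self) -> tuple[int, ...]:
        occupied = set(self.check_positions)
        return tuple(p for p in range(1, self.length + 1) if p not in occupied)

    def _payload_cols(self) -> np.ndarray:
        return np.array([p - 1 for p in self.payload_positions], dtype=np.intp)

    # -- construction-time validation ------------------------------------

    def _scaffold(self, n_rows: int) -> np.ndarray:
        """Word matrix with guards placed, payload and free slots zeroed."""
        w = np.zeros((n_rows, self.length), dtype=np.uint8)
        if self.guard_positions:
            w[:, [p - 1 for p in self.guard_positions]] = np.array(
                self.guard_values, dtype=np.uint8
            )
        return w

    def _build_guarded_table(self) -> dict:
        """Map (da, db) -> free-slot values; payload-independent thanks to guards."""
        L = self.length
        free_cols = [p - 1 for p in self.free_positions]
        w = self._scaffold(1)[0]
        base = vt_syndrome(w, L)
        table: dict[tuple[int, int], tuple[int, ...]] = {}
        for xs in itertools.product(range(4), repeat=len(free_cols)):
            w[free_cols] = xs
            a, b = vt_syndrome(w, L)
            key = ((a - base[0]) % L, (b - base[1]) % 4)
            table.setdefault(key, xs)
        w[free_cols] = 0
        if len(table) != 4 * L:
            raise EncodingError(
                f"guarded layout covers {len(table)}/{4 * L} syndrome classes; "
                "choose different triple centres"
            )
        return table

    def _validate_tail(self):
        """Check the 4**c tail search can hit every target from every context.

        Only the payload symbol adjacent to the check run influences which
        syndrome shifts the run can realise, so four boundary contexts cover
        all payloads.
        """
        L, c = self.length, self.n_tail_checks
        for boundary in range(4):
            seen = set()
            w = np.zeros(L, dtype=np.uint8)
            w[L - c - 1] = boundary
            for xs in itertools.product(range(4), repeat=c):
                w[L - c:] = xs
                seen.add(vt_syndrome(w, L))
            if len(seen) != 4 * L:
                raise EncodingError(
                    f"tail layout with c={c} cannot force all syndromes at "
                    f"L={L} (boundary symbol {NUCLEOTIDE_ORDER[boundary]}): "
                    f"{len(seen)}/{4 * L} classes reachable"
                )


def vt_encode_batch(payloads: np.ndarray, params: VTParams) -> np.ndarray:
    """Encode a (rows x payload_length) value matrix into full codewords."""
    payloads = np.asarray(payloads, dtype=np.uint8)
    if payloads.ndim != 2 or payloads.shape[1] != params.payload_length:
        raise InvalidSequenceError(
            f"payload must be (rows x {params.payload_length}), got {payloads.shape}"
        )
    n = payloads.shape[0]
    words = params._scaffold(n)
    words[:, params._payload_cols()] = payloads
    free_cols = [p - 1 for p in params.free_positions]
    a, b = _syndromes_matrix(words, params.length)
    da = (params.a_target - a) % params.length
    db = (params.b_target - b) % 4
    if params.scheme == "guarded":
        xs = np.array(
            [params._table[(int(x), int(y))] for x, y in zip(da, db)], dtype=np.uint8
        )
        words[:, free_cols] = xs
    else:  # tail search, row by row
        c = params.n_tail_checks
        combos = np.array(
            list(itertools.product(range(4), repeat=c)), dtype=np.uint8
        )
        for r in range(n):
            cand = np.repeat(words[r][None, :], len(combos), axis=0)
            cand[:, free_cols] = combos
            ca, cb = _syndromes_matrix(cand, params.length)
            hit = np.flatnonzero((ca == params.a_target) & (cb == params.b_target))
            if hit.size == 0:
                raise EncodingError("tail syndrome forcing failed")  # pragma: no cover
            words[r, free_cols] = combos[hit[0]]
    return words


def vt_encode(payload: str, params: VTParams) -> str:
    """Systematic encode: payload symbols appear unchanged at payload positions."""
    vals = seq_to_values(payload)
    return values_to_seq(vt_encode_batch(vals[None, :], params)[0])


def payload_of(codeword: str | np.ndarray, params: VTParams) -> str:
    """Read the payload back out of a codeword (systematic property)."""
    vals = seq_to_values(codeword) if isinstance(codeword, str) else codeword
    return values_to_seq(vals[params._payload_cols()])


def _check_matrix(cand: np.ndarray, params: VTParams) -> np.ndarray:
    """Boolean mask of candidate rows that are valid codewords."""
    a, b = _syndromes_matrix(cand, params.length)
    ok = (a == params.a_target) & (b == params.b_target)
    if params.guard_positions:
        gcols = [p - 1 for p in params.guard_positions]
        gvals = np.array(params.guard_values, dtype=np.uint8)
        ok &= (cand[:, gcols] == gvals).all(axis=1)
    return ok


def vt_check(seq: str | np.ndarray, params: VTParams) -> bool:
    """True iff ``seq`` has length L and both syndromes (and guards) match."""
    try:
        vals = seq_to_values(seq) if isinstance(seq, str) else np.asarray(seq)
    except InvalidSequenceError:
        return False
    if vals.size != params.length:
        return False
    return bool(_check_matrix(vals[None, :], params)[0])


def _insertion_candidates(vals: np.ndarray, L: int) -> np.ndarray:
    """All words obtained by inserting one symbol into a length L-1 read."""
    J = np.arange(L)[None, :]
    K = np.arange(L)[:, None]
    src = np.clip(J - (J > K), 0, L - 2)
    M = vals[src]
    cand = np.repeat(M, 4, axis=0)
    rows = np.arange(4 * L)
    cand[rows, np.repeat(np.arange(L), 4)] = np.tile(
        np.arange(4, dtype=np.uint8), L
    )
    return cand


def _deletion_candidates(vals: np.ndarray, L: int) -> np.ndarray:
    """All words obtained by deleting one symbol from a length L+1 read."""
    J = np.arange(L)[None, :]
    K = np.arange(L + 1)[:, None]
    return vals[J + (J >= K)]


def _substitution_candidates(vals: np.ndarray, L: int) -> np.ndarray:
    """All words at Hamming distance one from a length-L read."""
    cand = np.repeat(vals[None, :], 3 * L, axis=0)
    rows = np.arange(3 * L)
    pos = np.repeat(np.arange(L), 3)
    shift = np.tile(np.arange(1, 4, dtype=np.uint8), L)
    cand[rows, pos] = (vals[pos] + shift) % 4
    return cand


def vt_correct(seq: str | np.ndarray, params: VTParams) -> str | None:
    """Correct a single insertion, deletion, or substitution.

    Returns the unique consistent codeword, or ``None`` when no candidate or
    several distinct candidates exist (ambiguity: the read is discarded
    upstream rather than risk planting a wrong oligo).  For true single
    insertions/deletions the VT distance property guarantees the survivor is
    unique and equals the original codeword.
    """
    try:
        vals = seq_to_values(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    except InvalidSequenceError:
        return None
    L = params.length
    if vals.size == L:
        if bool(_check_matrix(vals[None, :], params)[0]):
            return values_to_seq(vals)
        cand = _substitution_candidates(vals, L)
    elif vals.size == L - 1:
        cand = _insertion_candidates(vals, L)
    elif vals.size == L + 1:
        cand = _deletion_candidates(vals, L)
    else:
        return None
    ok = _check_matrix(cand, params)
    survivors = np.unique(cand[ok], axis=0)
    if survivors.shape[0] == 1:
        return values_to_seq(survivors[0])
    return None
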