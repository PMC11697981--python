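"""Bijection between binary strings and unordered oligo subsets.

The palette code identifies an N-bit message ``x`` (bit ``x_1`` is the least
significant, i.e. the *rightmost* character of the written string) with the
integer ``v = sum_i 2**(i-1) x_i`` and maps it to the ``v``-th subset of an
ordered oligo universe ``O = {o_1 < o_2 < ... < o_n}``.  The subset order is
chosen so that the rank of a subset equals its indicator value
``sum_{o_i in S} 2**(i-1)``; consequently the set of *positions* of one-bits in
``x`` is exactly the set of universe indices present in the codeword, which is
what makes encoding and decoding linear in the number of set bits.

Nucleotides are ordered ``A < T < G < C`` and oligos lexicographically under
that symbol order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .errors import (
    CapacityError,
    InconsistentSubsetError,
    InvalidSequenceError,
    NotFoundError,
    RangeError,
)

#: Nucleotide alphabet in ascending palette order (A < T < G < C).
NUCLEOTIDE_ORDER = "ATGC"

#: Symbol -> numeric value under the palette order (A=0, T=1, G=2, C=3).
SYMBOL_VALUE = {s: i for i, s in enumerate(NUCLEOTIDE_ORDER)}


def oligo_value(oligo: str) -> int:
    """Base-4 integer value of an oligo under A=0, T=1, G=2, C=3."""
    v = 0
    try:
        for s in oligo:
            v = (v << 2) | SYMBOL_VALUE[s]
    except KeyError as exc:
        raise InvalidSequenceError(f"non-DNA symbol {exc.args[0]!r} in oligo {oligo!r}")
    return v


def oligo_from_value(v: int, m: int) -> str:
    """Inverse of :func:`oligo_value` for a length-``m`` oligo."""
    if not 0 <= v < 4**m:
        raise RangeError(f"value {v} out of range for length-{m} oligo")
    out = []
    for _ in range(m):
        out.append(NUCLEOTIDE_ORDER[v & 3])
        v >>= 2
    return "".join(reversed(out))


def oligo_less(a: str, b: str) -> bool:
    """Strict lexicographic order on equal-length oligos under A < T < G < C."""
    if len(a) != len(b):
        raise InvalidSequenceError(
            f"cannot compare oligos of different lengths ({len(a)} vs {len(b)})"
        )
    return oligo_value(a) < oligo_value(b)


@dataclass(frozen=True)
class OligoUniverse:
    """An ordered preset oligo set ``O = {o_1 < o_2 < ... < o_n}``.

    Either *explicit* (``members`` holds the sorted oligos) or *implicit*, in
    which case the universe is the first ``n`` sequences of length ``m`` in
    lexicographic order (all ``4**m`` of them by default).
    """

    m: int
    members: tuple[str, ...] | None = None
    size: int | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("oligo length m must be positive")
        if self.members is not None:
            ordered = tuple(sorted(set(self.members), key=oligo_value))
            if len(ordered) != len(self.members):
                raise ValueError("universe members must be distinct")
            for o in ordered:
                if len(o) != self.m:
                    raise InvalidSequenceError(
                        f"universe oligo {o!r} does not have length m={self.m}"
                    )
                oligo_value(o)  # symbol validation
            object.__setattr__(self, "members", ordered)
            object.__setattr__(self, "size", len(ordered))
            object.__setattr__(self, "_index", {o: i for i, o in enumerate(ordered)})
        else:
            n = 4**self.m if self.size is None else self.size
            if not 1 <= n <= 4**self.m:
                raise ValueError(f"implicit universe size {n} out of range for m={self.m}")
            object.__setattr__(self, "size", n)
            object.__setattr__(self, "_index", None)

    @property
    def n(self) -> int:
        """Number of oligos in the universe."""
        return self.size

    def rank(self, oligo: str) -> int:
        """0-based position of ``oligo`` in the universe order."""
        if self.members is not None:
            try:
                return self._index[oligo]
            except KeyError:
                raise NotFoundError(f"oligo {oligo!r} is not in the universe")
        if len(oligo) != self.m:
            raise NotFoundError(f"oligo {oligo!r} does not have length m={self.m}")
        v = oligo_value(oligo)
        if v >= self.size:
            raise NotFoundError(f"oligo {oligo!r} is outside the implicit universe")
        return v

    def unrank(self, i: int) -> str:
        """The oligo at 0-based position ``i``; inverse of :meth:`rank`."""
        if not 0 <= i < self.size:
            raise RangeError(f"rank {i} out of range for universe of size {self.size}")
        if self.members is not None:
            return self.members[i]
        return oligo_from_value(i, self.m)

    def __iter__(self) -> Iterator[str]:
        return (self.unrank(i) for i in range(self.size))


def oligo_rank(oligo: str, universe: OligoUniverse) -> int:
    """0-based position of ``oligo`` in ``universe``'s total order."""
    return universe.rank(oligo)


def oligo_unrank(i: int, universe: OligoUniverse) -> str:
    """Oligo at position ``i`` of ``universe``; inverse of :func:`oligo_rank`."""
    return universe.unrank(i)


@dataclass(frozen=True)
class OligoSubset:
    """A subset of one universe, stored as sorted 0-based member indices."""

    universe: OligoUniverse
    indices: tuple[int, ...]

    def __post_init__(self):
        idx = tuple(sorted(set(int(i) for i in self.indices)))
        if len(idx) != len(self.indices):
            raise ValueError("subset members must be distinct")
        if idx and not (0 <= idx[0] and idx[-1] < self.universe.n):
            raise RangeError("subset index outside the universe")
        object.__setattr__(self, "indices", idx)

    @classmethod
    def from_members(cls, members: Iterable[str], universe: OligoUniverse) -> "OligoSubset":
        return cls(universe, tuple(universe.rank(o) for o in members))

    @property
    def members(self) -> tuple[str, ...]:
        """Member oligos in ascending universe order."""
        return tuple(self.universe.unrank(i) for i in self.indices)

    @property
    def rank(self) -> int:
        """Indicator value ``sum_{i in S} 2**i`` (arbitrary precision)."""
        return sum(1 << i for i in self.indices)

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, oligo: str) -> bool:
        return self.universe.rank(oligo) in self.indices


def subset_rank(subset: OligoSubset) -> int:
    """Position of ``subset`` in the total order on the subset family."""
    return subset.rank


def subset_unrank(j: int, universe: OligoUniverse) -> OligoSubset:
    """The ``j``-th subset (0-based, ``O_0`` empty) of ``universe``."""
    if not 0 <= j < (1 << universe.n):
        raise RangeError(f"subset rank {j} out of range for universe of size {universe.n}")
    indices = []
    i = 0
    while j:
        if j & 1:
            indices.append(i)
        j >>= 1
        i += 1
    return OligoSubset(universe, tuple(indices))


def subset_less(a: OligoSubset, b: OligoSubset) -> bool:
    """Strict subset order: compare largest members downward.

    The subset whose first differing element (scanning from the largest down)
    is smaller — or which runs out of elements first while the scanned tails
    match — precedes the other.  Equal subsets compare as neither-less.  The
    order coincides with comparing indicator ranks as integers.
    """
    if a.universe != b.universe:
        raise ValueError("cannot compare subsets over different universes")
    ra, rb = a.indices[::-1], b.indices[::-1]
    for xa, xb in zip(ra, rb):
        if xa != xb:
            return xa < xb
    return len(ra) < len(rb)


def message_value(bits: str) -> int:
    """Integer value of a written bitstring (rightmost character is ``x_1``)."""
    if not bits:
        return 0
    if set(bits) - {"0", "1"}:
        raise ValueError(f"message {bits!r} is not binary")
    return int(bits, 2)


def encode_bits(bits: str, universe: OligoUniverse) -> OligoSubset:
    """Encode an N-bit message into its oligo subset ``f(x)``.

    The i-th oligo of the universe is present exactly when bit ``x_i`` (1-based
    from the right of the written string) is one, so the subset's rank equals
    the message value and all-zero messages cost zero oligos.
    """
    n = len(bits)
    if n > universe.n:
        raise CapacityError(
            f"message of {n} bits exceeds universe capacity n={universe.n}"
        )
    if set(bits) - {"0", "1"}:
        raise ValueError(f"message {bits!r} is not binary")
    indices = tuple(n - 1 - k for k, c in enumerate(bits) if c == "1")
    return OligoSubset(universe, indices)


def decode_subset(subset: OligoSubset, n_bits: int) -> str:
    """Recover the message from its subset; inverse of :func:`encode_bits`."""
    if subset.indices and subset.indices[-1] >= n_bits:
        raise InconsistentSubsetError(
            f"subset rank >= 2**{n_bits}: member index {subset.indices[-1]} "
            "signals a spurious oligo"
        )
    chars = ["0"] * n_bits
    for i in subset.indices:
        chars[n_bits - 1 - i] = "1"
    return "".join(chars)


def enumerate_subsets(universe: OligoUniverse) -> Iterator[OligoSubset]:
    """All ``2**n`` subsets in rank order (small universes only)."""
    for j in range(1 << universe.n):
        yield subset_unrank(j, universe)
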