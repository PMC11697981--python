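"""Block Reed–Solomon code over GF(256) with bounded-distance decoding.

Systematic RS(n, k): each k-byte data block is extended with ``n - k`` parity
bytes and up to ``t = (n - k) // 2`` byte errors per block are corrected
(Berlekamp–Massey + Chien + Forney).  Uncorrectable blocks are returned
as-received and flagged, so decoding degrades per-block instead of failing
globally.  Parity generation and syndrome evaluation are vectorised across
blocks; only blocks with non-zero syndromes take the scalar decoding path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gf256 import EXP, LOG, MUL, gf_div, poly_mul


@dataclass(frozen=True)
class RSParams:
    """Geometry of the block code: ``n`` total bytes, ``k`` data bytes."""

    n: int = 255
    k: int = 223
    _gen: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if not 1 <= self.k < self.n <= 255:
            raise ValueError(f"require 1 <= k < n <= 255, got n={self.n} k={self.k}")
        g = [1]
        for i in range(self.nsym):
            g = poly_mul(g, [1, EXP[i]])
        object.__setattr__(self, "_gen", tuple(g))

    @property
    def nsym(self) -> int:
        return self.n - self.k

    @property
    def t(self) -> int:
        """Bytes correctable per block."""
        return self.nsym // 2

    @property
    def generator(self) -> tuple:
        """Generator polynomial, highest-degree coefficient first (monic)."""
        return self._gen


def rs_encode_blocks(data: np.ndarray, params: RSParams) -> np.ndarray:
    """Parity of each row of a (blocks x k) byte matrix."""
    data = np.ascontiguousarray(data, dtype=np.uint8)
    if data.ndim != 2 or data.shape[1] != params.k:
        raise ValueError(f"data must be (blocks x {params.k}), got {data.shape}")
    nb = data.shape[0]
    nsym = params.nsym
    gtail = np.array(params.generator[1:], dtype=np.uint8)
    par = np.zeros((nb, nsym), dtype=np.uint8)
    for i in range(params.k):  # polynomial long division, vectorised over blocks
        fb = data[:, i] ^ par[:, 0]
        par[:, :-1] = par[:, 1:]
        par[:, -1] = 0
        par ^= MUL[fb[:, None], gtail[None, :]]
    return par


def rs_syndromes(blocks: np.ndarray, params: RSParams) -> np.ndarray:
    """Syndromes S_j = R(alpha^j), j = 0..nsym-1, per block (Horner, vectorised)."""
    blocks = np.ascontiguousarray(blocks, dtype=np.uint8)
    nb = blocks.shape[0]
    alphas = EXP[np.arange(params.nsym)][None, :]
    S = np.zeros((nb, params.nsym), dtype=np.uint8)
    for i in range(params.n):
        S = MUL[S, alphas] ^ blocks[:, i][:, None]
    return S


def _berlekamp_massey(S: list[int], nsym: int) -> list[int] | None:
    """Error locator polynomial (low-to-high coefficients) or None on failure."""
    C, B = [1], [1]
    Lh, mm, bb = 0, 1, 1
    for nn in range(nsym):
        d = S[nn]
        for i in range(1, Lh + 1):
            if i < len(C):
                d ^= MUL[C[i], S[nn - i]]
        d = int(d)
        if d == 0:
            mm += 1
            continue
        coef = gf_div(d, bb)
        shifted = [0] * mm + [int(MUL[coef, x]) for x in B]
        newC = [0] * max(len(C), len(shifted))
        for i, x in enumerate(C):
            newC[i] ^= x
        for i, x in enumerate(shifted):
            newC[i] ^= x
        if 2 * Lh <= nn:
            B, bb = C, d
            Lh = nn + 1 - Lh
            C, mm = newC, 1
        else:
            C, mm = newC, mm + 1
    while len(C) > 1 and C[-1] == 0:
        C.pop()
    if len(C) - 1 != Lh:
        return None
    return C


def _decode_block(block: np.ndarray, S: np.ndarray, params: RSParams) -> np.ndarray | None:
    """Correct one block in place; return the block or None if uncorrectable."""
    n, nsym = params.n, params.nsym
    synd = [int(s) for s in S]
    lam = _berlekamp_massey(synd, nsym)
    if lam is None or not 1 <= len(lam) - 1 <= params.t:
        return None
    nerr = len(lam) - 1
    # Chien search: error at byte p iff Lambda(beta_p^{-1}) = 0, beta_p = alpha^{n-1-p}
    err_pos = []
    for p in range(n):
        xinv = EXP[(255 - (n - 1 - p)) % 255]
        acc, xp = 0, 1
        for c in lam:
            acc ^= MUL[c, xp]
            xp = MUL[xp, xinv]
        if acc == 0:
            err_pos.append(p)
    if len(err_pos) != nerr:
        return None
    # Omega = S(x) * Lambda(x) mod x^nsym  (both low-to-high)
    omega = [0] * nsym
    for i, s in enumerate(synd):
        for j, c in enumerate(lam):
            if i + j < nsym:
                omega[i + j] ^= MUL[s, c]
    # Forney with fcr = 0: e_p = beta_p * Omega(beta_p^{-1}) / Lambda'(beta_p^{-1})
    out = block.copy()
    for p in err_pos:
        beta = EXP[(n - 1 - p) % 255]
        xinv = EXP[(255 - (n - 1 - p)) % 255]
        num, xp = 0, 1
        for c in omega:
            num ^= MUL[c, xp]
            xp = MUL[xp, xinv]
        den, xp = 0, 1
        for i in range(1, len(lam), 2):  # formal derivative: odd-degree terms
            den ^= MUL[lam[i], xp]
            xp = MUL[xp, MUL[xinv, xinv]]
        if den == 0:
            return None
        mag = MUL[beta, gf_div(num, den)]
        out[p] ^= mag
    # verify
    if rs_syndromes(out[None, :], params).any():
        return None
    return out


def rs_protect(stream: bytes, params: RSParams) -> bytes:
    """Split into k-byte blocks (zero-padded tail) and append block parities.

    Output layout: the zero-padded data region followed by all parity bytes in
    block order, so sparse data regions keep their offsets and all-zero blocks
    contribute all-zero parity (code linearity).
    """
    data = np.frombuffer(stream, dtype=np.uint8)
    nb = max(1, -(-data.size // params.k))
    padded = np.zeros(nb * params.k, dtype=np.uint8)
    padded[: data.size] = data
    parity = rs_encode_blocks(padded.reshape(nb, params.k), params)
    return padded.tobytes() + parity.tobytes()


def rs_repair(protected: bytes, params: RSParams) -> tuple[bytes, list[int]]:
    """Bounded-distance decode each block; never aborts.

    Returns the (still padded) data region with corrections applied and the
    indices of blocks that could not be corrected (returned as-received).
    """
    buf = np.frombuffer(protected, dtype=np.uint8)
    if buf.size % params.n:
        raise ValueError(
            f"protected stream length {buf.size} is not a multiple of n={params.n}"
        )
    nb = buf.size // params.n
    data = buf[: nb * params.k].reshape(nb, params.k).copy()
    parity = buf[nb * params.k:].reshape(nb, params.nsym)
    blocks = np.hstack([data, parity])
    S = rs_syndromes(blocks, params)
    failed: list[int] = []
    for r in np.flatnonzero(S.any(axis=1)):
        fixed = _decode_block(blocks[r], S[r], params)
        if fixed is None:
            failed.append(int(r))
        else:
            data[r] = fixed[: params.k]
    return data.reshape(-1).tobytes(), failed
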