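"""GF(256) arithmetic tables (primitive polynomial 0x11d), numpy-vectorised."""

from __future__ import annotations

import numpy as np

_PRIM = 0x11D

# exp table over two periods so exp[i+j] never needs an explicit mod 255
EXP = np.zeros(512, dtype=np.uint8)
LOG = np.zeros(256, dtype=np.int64)
_x = 1
for _i in range(255):
    EXP[_i] = _x
    LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
EXP[255:510] = EXP[:255]

# full 256x256 multiplication table: 64 KiB buys branch-free vector lookups
_a = np.arange(256)
MUL = np.zeros((256, 256), dtype=np.uint8)
MUL[1:, 1:] = EXP[(LOG[_a[1:, None]] + LOG[_a[None, 1:]]) % 255]


def gf_mul(a, b):
    """Element-wise product in GF(256); accepts scalars or uint8 arrays."""
    return MUL[a, b]


def gf_inv(a: int) -> int:
    if a == 0:
        raise ZeroDivisionError("GF(256) inverse of zero")
    return int(EXP[255 - LOG[a]])


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("GF(256) division by zero")
    if a == 0:
        return 0
    return int(EXP[(LOG[a] - LOG[b]) % 255])


def poly_eval(poly, x: int) -> int:
    """Evaluate a polynomial (highest-degree coefficient first) at ``x``."""
    y = 0
    for c in poly:
        y = int(MUL[y, x]) ^ int(c)
    return y


def poly_mul(p, q):
    """Product of two coefficient lists (highest degree first)."""
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        if a:
            for j, b in enumerate(q):
                out[i + j] ^= int(MUL[a, b])
    return out
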