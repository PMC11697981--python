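"""Synthetic time-series archive generators.

Two fixture families:

* :func:`generate_series` — a format-agnostic series: a random first file, a
  shared (optionally jittered) header region, and a controlled fraction of
  payload bytes rewritten at random offsets between consecutive files.  Used
  to exercise correctness paths on worst-case (incompressible) content.

* :func:`generate_dicom_like` — a medical-imaging-flavoured series: each file
  is a small tag-length-value header followed by a 12-bit grayscale phantom
  image (little-endian uint16 pixels, dark background, smooth foreground),
  with successive files differing in a few localised regions.  This mimics the
  statistical structure of archival slice series — sparse pixel content and
  clustered inter-file changes — which is exactly the structure the ladder +
  palette pipeline exploits for >2 bits/nt densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ladder_code import AlignmentProfile

HEADER_LEN = 128  # bytes, generate_dicom_like


@dataclass(frozen=True)
class SeriesSpec:
    """Shape and dynamics of a synthetic archive.

    ``diff_rate`` is the fraction of payload bytes rewritten between
    consecutive files; ``header_jitter`` the per-file fraction of header bytes
    rewritten (volatile label fields).
    """

    n_files: int = 21
    file_size: int = 262144
    header_fraction: float = 0.01
    diff_rate: float = 0.003
    header_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_files < 1:
            raise ValueError("series needs at least one file")
        if not 0.0 <= self.diff_rate <= 1.0:
            raise ValueError("diff_rate must be in [0, 1]")
        if not 0.0 <= self.header_jitter <= 1.0:
            raise ValueError("header_jitter must be in [0, 1]")
        if not 0.0 <= self.header_fraction < 1.0:
            raise ValueError("header_fraction must be in [0, 1)")


def generate_series(spec: SeriesSpec) -> list[bytes]:
    """Random-content series with shared header and random payload edits."""
    rng = np.random.default_rng(spec.seed)
    size = spec.file_size
    hlen = round(spec.header_fraction * size)
    current = rng.integers(0, 256, size, dtype=np.uint8)
    files = [current.tobytes()]
    n_payload_edits = round(spec.diff_rate * (size - hlen))
    n_header_edits = round(spec.header_jitter * hlen)
    for _ in range(1, spec.n_files):
        current = current.copy()
        if n_payload_edits:
            off = rng.choice(size - hlen, n_payload_edits, replace=False) + hlen
            current[off] = rng.integers(0, 256, n_payload_edits, dtype=np.uint8)
        if n_header_edits:
            off = rng.choice(hlen, n_header_edits, replace=False)
            current[off] = rng.integers(0, 256, n_header_edits, dtype=np.uint8)
        files.append(current.tobytes())
    return files


def _phantom(side: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth 12-bit phantom on a dark background (values 0..4095, uint16)."""
    y, x = np.mgrid[0:side, 0:side]
    cy = cx = (side - 1) / 2
    ry, rx = 0.42 * side, 0.36 * side
    r2 = ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2
    mask = r2 <= 1.0
    img = np.zeros((side, side), dtype=np.float64)
    img[mask] = 500.0 + 1200.0 * (1.0 - r2[mask])
    for _ in range(6):  # internal structures
        by, bx = rng.uniform(0.25, 0.75, 2) * side
        s = rng.uniform(0.04, 0.12) * side
        amp = rng.uniform(-900, 1800)
        img += amp * np.exp(-(((y - by) ** 2 + (x - bx) ** 2) / (2 * s * s)))
    img[~mask] = 0.0
    return np.clip(img, 0, 4095).astype(np.uint16)


def _tlv(tag: int, value: bytes) -> bytes:
    return tag.to_bytes(2, "little") + len(value).to_bytes(2, "little") + value


def generate_dicom_like(
    spec: SeriesSpec,
) -> tuple[list[bytes], AlignmentProfile]:
    """Imaging-archive series plus its matching alignment profile.

    Each file: a fixed 128-byte tag-length-value header (shared study fields,
    per-file instance number and timestamp — declared as label spans) and a
    little-endian uint16 pixel payload.  Consecutive files differ in a few
    localised disc-shaped regions whose total area is chosen so that about
    ``diff_rate`` of the payload bytes change.
    """
    rng = np.random.default_rng(spec.seed)
    payload_bytes = spec.file_size - HEADER_LEN
    if payload_bytes < 512:
        raise ValueError("file_size too small for a header plus pixel payload")
    side = int(math.isqrt(payload_bytes // 2))
    img = _phantom(side, rng).astype(np.int32)

    study_uid = rng.integers(0, 256, 12, dtype=np.uint8).tobytes()
    rows_cols = side.to_bytes(2, "little") * 2
    fixed_header = (
        b"TSAR"                                   # magic
        + _tlv(0x0010, study_uid)                 # study identifier (shared)
        + _tlv(0x0028, rows_cols)                 # rows/cols (shared)
    )
    # per-file fields sit at a fixed offset right after the shared part
    instance_off = len(fixed_header) + 4          # skip tag+len of the TLV
    timestamp_off = instance_off + 4 + 4

    # disc radius ~6 px; pick region count to hit the target changed-byte budget
    radius = 6
    disc_px = int(math.pi * radius * radius)
    target_bytes = spec.diff_rate * payload_bytes
    n_regions = max(1, round(target_bytes / (2 * disc_px))) if spec.diff_rate > 0 else 0

    files = []
    yy, xx = np.mgrid[0:side, 0:side]
    for t in range(spec.n_files):
        header = bytearray(HEADER_LEN)
        body = (
            fixed_header
            + _tlv(0x0013, int(t + 1).to_bytes(4, "little"))            # instance no.
            + _tlv(0x0033, int(1700000000 + 97 * t).to_bytes(8, "little"))  # timestamp
        )
        header[: len(body)] = body
        if t > 0 and n_regions:
            for _ in range(n_regions):
                cy = rng.integers(radius, side - radius)
                cx = rng.integers(radius, side - radius)
                sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
                img[sel] = np.clip(
                    img[sel] + int(rng.integers(-800, 801) | 1), 0, 4095
                )
        payload = np.zeros(payload_bytes, dtype=np.uint8)
        pix = img.astype(np.uint16).tobytes()
        payload[: len(pix)] = np.frombuffer(pix, dtype=np.uint8)[:payload_bytes]
        files.append(bytes(header) + payload.tobytes())

    profile = AlignmentProfile(
        label_spans=((instance_off, 4), (timestamp_off, 8)), pad_byte=0
    )
    return files, profile
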