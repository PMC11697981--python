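"""Structured-text configuration and manifest serialization.

The manifest is the only side information a decoder needs besides the reads:
a codec-config snapshot, the ladder geometry, the protected stream length and
the pool size, plus an input checksum used for verification only.  Unknown
keys are rejected so that silent schema drift cannot corrupt a decode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .ladder_code import AlignmentProfile, LadderGeometry
from .pipeline import CodecConfig
from .rs_code import RSParams
from .subset_codec import OligoUniverse
from .vt_codec import VTParams

FORMAT_VERSION = 1


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in {where}")


def _vt_to_dict(vt: VTParams | None):
    if vt is None:
        return None
    out = {
        "length": vt.length,
        "scheme": vt.scheme,
        "a_target": vt.a_target,
        "b_target": vt.b_target,
    }
    if vt.scheme == "guarded":
        out["triple_centers"] = list(vt.triple_centers)
    else:
        out["n_tail_checks"] = vt.n_tail_checks
    return out


def _vt_from_dict(d) -> VTParams | None:
    if d is None:
        return None
    _check_keys(
        d,
        {"length", "scheme", "a_target", "b_target", "triple_centers", "n_tail_checks"},
        "vt",
    )
    kwargs = dict(d)
    if "triple_centers" in kwargs:
        kwargs["triple_centers"] = tuple(kwargs["triple_centers"])
    return VTParams(**kwargs)


def _rs_to_dict(rs: RSParams | None):
    return None if rs is None else {"n": rs.n, "k": rs.k}


def _rs_from_dict(d) -> RSParams | None:
    if d is None:
        return None
    _check_keys(d, {"n", "k"}, "rs")
    return RSParams(**d)


_CONFIG_KEYS = {
    "payload_len", "label_len", "addr_len", "addrs_per_oligo",
    "vt", "block_bits", "rs", "vote_threshold", "address_universe",
}


def config_to_dict(cfg: CodecConfig) -> dict:
    u = cfg.address_universe
    return {
        "payload_len": cfg.payload_len,
        "label_len": cfg.label_len,
        "addr_len": cfg.addr_len,
        "addrs_per_oligo": cfg.addrs_per_oligo,
        "vt": _vt_to_dict(cfg.vt),
        "block_bits": cfg.block_bits,
        "rs": _rs_to_dict(cfg.rs),
        "vote_threshold": cfg.vote_threshold,
        "address_universe": None if u is None else {
            "m": u.m, "members": None if u.members is None else list(u.members),
            "size": u.size,
        },
    }


def config_from_dict(d: dict) -> CodecConfig:
    if not isinstance(d, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(d, _CONFIG_KEYS, "config")
    kwargs = dict(d)
    if "vt" in kwargs:
        kwargs["vt"] = _vt_from_dict(kwargs["vt"])
    if "rs" in kwargs:
        kwargs["rs"] = _rs_from_dict(kwargs["rs"])
    if kwargs.get("address_universe") is not None:
        u = kwargs["address_universe"]
        _check_keys(u, {"m", "members", "size"}, "address_universe")
        members = u.get("members")
        kwargs["address_universe"] = OligoUniverse(
            m=u["m"],
            members=None if members is None else tuple(members),
            size=u.get("size") if members is None else None,
        )
    try:
        return CodecConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc))


def load_config(path: str | Path) -> CodecConfig:
    """Load and validate a codec configuration from YAML (defaults filled)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def _geometry_to_dict(g: LadderGeometry) -> dict:
    return {
        "file_lengths": list(g.file_lengths),
        "padded_length": g.padded_length,
        "label_spans": [list(s) for s in g.profile.label_spans],
        "pad_byte": g.profile.pad_byte,
        "rs": _rs_to_dict(g.rs),
    }


def _geometry_from_dict(d: dict) -> LadderGeometry:
    _check_keys(
        d, {"file_lengths", "padded_length", "label_spans", "pad_byte", "rs"}, "geometry"
    )
    profile = AlignmentProfile(
        label_spans=tuple(tuple(s) for s in d.get("label_spans", ())),
        pad_byte=d.get("pad_byte", 0),
    )
    return LadderGeometry(
        file_lengths=tuple(d["file_lengths"]),
        padded_length=d["padded_length"],
        profile=profile,
        rs=_rs_from_dict(d.get("rs")),
    )


@dataclass(frozen=True)
class Manifest:
    """Decode-side sidecar: config snapshot + geometry + pool bookkeeping."""

    config: CodecConfig
    geometry: LadderGeometry
    protected_len: int
    pool_size: int
    input_sha256: str | None = None
    version: int = FORMAT_VERSION

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": config_to_dict(self.config),
            "geometry": _geometry_to_dict(self.geometry),
            "protected_len": self.protected_len,
            "pool_size": self.pool_size,
            "input_sha256": self.input_sha256,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Manifest":
        _check_keys(
            d,
            {"version", "config", "geometry", "protected_len", "pool_size", "input_sha256"},
            "manifest",
        )
        if d.get("version") != FORMAT_VERSION:
            raise ConfigError(f"unsupported manifest version {d.get('version')!r}")
        return cls(
            config=config_from_dict(d["config"]),
            geometry=_geometry_from_dict(d["geometry"]),
            protected_len=int(d["protected_len"]),
            pool_size=int(d["pool_size"]),
            input_sha256=d.get("input_sha256"),
        )


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest.to_dict(), fh, sort_keys=False)


def load_manifest(path: str | Path) -> Manifest:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"manifest {path} is not a mapping")
    return Manifest.from_dict(data)
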