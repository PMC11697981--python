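"""Synthesis–storage–sequencing channel simulator.

Models the three impairments that matter to the decoder:

* per-oligo *dropout* (probability ``p_drop`` that no read of an oligo
  survives),
* *duplication* — each surviving oligo is read a fixed ``M`` times or a
  Poisson-distributed number of times,
* per-base *IDS errors* — at each scanned position at most one event occurs:
  substitution (uniform over the three alternatives), deletion, or insertion
  of a uniform base before the current symbol.

All randomness flows from a single seeded generator, so a run is
bit-reproducible from (pool, params, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .vt_codec import seq_to_values, values_to_seq


@dataclass(frozen=True)
class ChannelParams:
    """IDS + dropout + duplication channel parameters.

    Exactly one duplication mode is active: fixed ``duplication`` M, or
    Poisson with mean ``mean_coverage``.
    """

    p_ins: float = 0.0
    p_del: float = 0.0
    p_sub: float = 0.0
    p_drop: float = 0.0
    duplication: int | None = 1
    mean_coverage: float | None = None

    def __post_init__(self):
        for name in ("p_ins", "p_del", "p_sub", "p_drop"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pr > 1.0:
            raise ValueError("p_ins + p_del + p_sub must not exceed 1")
        if (self.duplication is None) == (self.mean_coverage is None):
            raise ValueError("set exactly one of duplication / mean_coverage")
        if self.duplication is not None and self.duplication < 0:
            raise ValueError("duplication must be non-negative")

    @property
    def pr(self) -> float:
        """Total per-base IDS error rate."""
        return self.p_ins + self.p_del + self.p_sub

    @classmethod
    def ids(cls, pr: float, p_drop: float = 0.0, duplication: int = 1) -> "ChannelParams":
        """Equal-split IDS channel: p_ins = p_del = p_sub = pr / 3."""
        return cls(pr / 3, pr / 3, pr / 3, p_drop=p_drop, duplication=duplication)


def corrupt(oligo: str, params: ChannelParams, rng: np.random.Generator) -> str:
    """One noisy read of one oligo under the IDS model."""
    vals = seq_to_values(oligo)
    m = vals.size
    if params.pr == 0.0:
        return oligo
    r = rng.random(m)
    ps, pd, pi = params.p_sub, params.p_del, params.p_ins
    sub = r < ps
    dele = (r >= ps) & (r < ps + pd)
    ins = (r >= ps + pd) & (r < ps + pd + pi)
    vals = vals.copy()
    n_sub = int(sub.sum())
    if n_sub:
        vals[sub] = (vals[sub] + rng.integers(1, 4, n_sub)) % 4
    counts = np.ones(m, dtype=np.intp)
    counts[dele] = 0
    counts[ins] = 2
    out = vals[np.repeat(np.arange(m), counts)]
    n_ins = int(ins.sum())
    if n_ins:
        starts = np.cumsum(counts) - counts  # output offset of each input position
        out[starts[ins]] = rng.integers(0, 4, n_ins)
    return values_to_seq(out)


def sequence_pool(
    pool: list[str],
    params: ChannelParams,
    rng: np.random.Generator | int | None = 0,
) -> list[str]:
    """Simulate sequencing of an oligo pool into an unordered read set.

    Each oligo is independently dropped with ``p_drop``; survivors are emitted
    ``M`` (or Poisson) times, each copy independently corrupted; the output
    order is shuffled.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not pool:
        raise ValueError("pool must be non-empty")
    survive = rng.random(len(pool)) >= params.p_drop
    if params.duplication is not None:
        copies = np.full(len(pool), params.duplication)
    else:
        copies = rng.poisson(params.mean_coverage, len(pool))
    reads = []
    for oligo, ok, c in zip(pool, survive, copies):
        if not ok:
            continue
        for _ in range(int(c)):
            reads.append(corrupt(oligo, params, rng))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def subsample(
    reads: list[str],
    target_coverage: float,
    pool_size: int,
    rng: np.random.Generator | int | None = 0,
) -> list[str]:
    """Uniform without-replacement subsample to ``target_coverage x pool_size`` reads."""
    if target_coverage < 0:
        raise ValueError("target coverage must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    want = round(target_coverage * pool_size)
    if want >= len(reads):
        if want > len(reads):
            warnings.warn(
                f"requested {want} reads but only {len(reads)} available; returning all"
            )
        return list(reads)
    idx = rng.choice(len(reads), want, replace=False)
    return [reads[i] for i in idx]
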