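"""Rarefaction: subsampling without replacement and diversity-vs-depth curves.

Rarefaction proper draws reads without replacement, so the subsampled
counts follow a multivariate hypergeometric law and the curve at full
depth reproduces the direct index value exactly. Depth schedules are
arithmetic (k * step_size for k = 1..n_steps, capped at max_depth and at
the sample's own total); two presets mirror common practice for soil 16S
data, a deep Shannon schedule (250 x 200 up to 50,000 reads) and a shallow
Simpson schedule (80 x 50 capped at 3,600 reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError, InsufficientReadsError

__all__ = [
    "RarefactionConfig",
    "RarefactionCurve",
    "SHANNON_SCHEDULE",
    "SIMPSON_SCHEDULE",
    "subsample_without_replacement",
    "rarefaction_curve",
]


@dataclass(frozen=True)
class RarefactionConfig:
    """Depth schedule and replication for one rarefaction run.

    Scheduled depths are ``min(k * step_size, max_depth)`` for
    k = 1..n_steps, deduplicated; depths beyond a sample's total reads are
    dropped when the curve is computed. ``replicates`` subsamples are
    averaged at each depth.
    """

    max_depth: int
    n_steps: int
    step_size: int
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1 or self.n_steps < 1 or self.step_size < 1:
            raise DomainError("max_depth, n_steps and step_size must be >= 1")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")

    def depths(self) -> np.ndarray:
        d = np.minimum(np.arange(1, self.n_steps + 1) * self.step_size, self.max_depth)
        return np.unique(d)


#: Deep schedule used for the slowly-saturating Shannon index.
SHANNON_SCHEDULE = RarefactionConfig(max_depth=50_000, n_steps=200, step_size=250)
#: Shallow schedule used for the quickly-saturating Simpson index.
SIMPSON_SCHEDULE = RarefactionConfig(max_depth=3_600, n_steps=50, step_size=80)


@dataclass
class RarefactionCurve:
    """A diversity index traced over subsampling depths for one sample."""

    depths: np.ndarray
    values: np.ndarray
    replicate_sd: np.ndarray
    index_name: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        self.values = np.asarray(self.values, dtype=float)
        self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise DomainError("depths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("curve values must be finite")

    @property
    def final_value(self) -> float:
        return float(self.values[-1])

    @property
    def max_depth(self) -> int:
        return int(self.depths[-1])


def subsample_without_replacement(
    v, depth: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``depth`` reads without replacement from count vector ``v``.

    The result is a multivariate hypergeometric draw: totals equal
    ``depth`` and no taxon exceeds its original count. ``depth`` equal to
    the sample total returns the original counts; depth 0 returns zeros.
    Deterministic for a fixed ``seed`` (or pass an explicit ``rng`` to
    share a generator across calls).
    """
    counts = np.asarray(v)
    if not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(np.int64)
    if np.any(counts < 0):
        raise DomainError("counts must be non-negative integers")
    total = int(counts.sum())
    if depth < 0:
        raise DomainError("depth must be >= 0")
    if depth > total:
        raise InsufficientReadsError(
            f"requested depth {depth} exceeds sample total {total}"
        )
    if depth == total:
        return counts.copy()
    if depth == 0:
        return np.zeros_like(counts)
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth, method="marginals")


def rarefaction_curve(
    v,
    cfg: RarefactionConfig,
    index: Callable[[Sequence[int]], float],
    index_name: str = "",
    sample_id: str = "",
) -> RarefactionCurve:
    """Average ``index`` over replicate subsamples at each scheduled depth.

    Depths exceeding the sample total are truncated, so the curve ends at
    ``min(max scheduled depth, total reads)``; with a single replicate the
    value at full depth equals the direct index of ``v`` exactly.
    """
    counts = np.asarray(v, dtype=np.int64)
    total = int(counts.sum())
    depths = cfg.depths()
    depths = depths[depths <= total]
    if depths.size == 0:
        raise InsufficientReadsError(
            f"sample total {total} is below the smallest scheduled depth"
        )
    rng = np.random.default_rng(cfg.seed)
    means = np.empty(depths.size)
    sds = np.empty(depths.size)
    for j, d in enumerate(depths):
        vals = np.empty(cfg.replicates)
        for r in range(cfg.replicates):
            vals[r] = index(subsample_without_replacement(counts, int(d), rng=rng))
        means[j] = vals.mean()
        sds[j] = vals.std(ddof=1) if cfg.replicates > 1 else 0.0
    return RarefactionCurve(
        depths=depths,
        values=means,
        replicate_sd=sds,
        index_name=index_name,
        sample_id=sample_id,
    )
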