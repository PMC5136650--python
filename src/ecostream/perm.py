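"""Chunked, reproducibly seeded permutation execution.

Permutation tests here can involve very large budgets (the motivating
workloads run 10^7 - 1 permutations), so the budget is split into chunks
handed to a worker pool.  The contract that makes this safe is
*per-permutation seeding*: the random stream used by permutation ``t``
depends only on ``(master_seed, t)``, never on which chunk or worker ran
it.  Exceedance counts are integers summed over chunks, so the full
result — counts, p-values, everything — is bitwise identical for any
worker count and any chunk layout.

The p-value convention is ``(1 + #{perm stat >= observed}) / (1 + nperm)``
with ties counting as exceedances, so a reported p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence, Union

import numpy as np
from joblib import Parallel, delayed

from .errors import ValidationError

__all__ = ["ChunkPlan", "PermTestResult", "perm_rng", "run_permutations",
           "chunked_outer", "chunk_items"]

DEFAULT_NPERM = 999
DEFAULT_CHUNK_SIZE = 10_000


@dataclass
class ChunkPlan:
    """Partition of a permutation budget into deterministic chunks."""

    master_seed: int
    nperm: int
    chunk_size: int = DEFAULT_CHUNK_SIZE
    workers: int = 1

    def __post_init__(self) -> None:
        if self.nperm < 0:
            raise ValidationError("nperm must be >= 0")
        if self.chunk_size < 1:
            raise ValidationError("chunk_size must be >= 1")
        if self.workers < 1:
            raise ValidationError("workers must be >= 1")

    @property
    def chunks(self) -> list[tuple[int, int]]:
        return [(start, min(start + self.chunk_size, self.nperm))
                for start in range(0, self.nperm, self.chunk_size)]


@dataclass
class PermTestResult:
    """Observed statistic(s) with a permutation null summary.

    ``observed``/``exceed_count``/``p_value`` are scalars for scalar
    statistics and aligned arrays for vector statistics (e.g. one p per
    species).
    """

    observed: Union[float, np.ndarray]
    nperm: int
    exceed_count: Union[int, np.ndarray]
    p_value: Union[float, np.ndarray]
    master_seed: int


def perm_rng(master_seed: int, perm_index: int) -> np.random.Generator:
    """The random stream of permutation ``perm_index``.

    Seeded from the entropy pair ``(master_seed, perm_index)`` via numpy's
    SeedSequence hash, so the stream is independent of chunk layout and
    worker count, and distinct indices give independent streams.
    """
    if perm_index < 0:
        raise ValidationError("perm_index must be >= 0")
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([master_seed, perm_index])))


def _chunk_exceed(stat_fn: Callable[[np.random.Generator], Union[float, np.ndarray]],
                  observed: np.ndarray, master_seed: int,
                  start: int, stop: int, chunk_id: int):
    exceed = np.zeros(observed.shape, dtype=np.int64)
    try:
        for t in range(start, stop):
            stat = np.asarray(stat_fn(perm_rng(master_seed, t)), dtype=float)
            exceed += stat >= observed
    except Exception as exc:
        raise RuntimeError(
            f"permutation statistic failed in chunk {chunk_id} "
            f"(permutations [{start}, {stop}))") from exc
    return exceed


def run_permutations(
    stat_fn: Callable[[np.random.Generator], Union[float, np.ndarray]],
    observed: Union[float, np.ndarray],
    plan: ChunkPlan,
) -> PermTestResult:
    """Evaluate a permutation null in chunks.

    ``stat_fn(rng)`` must draw its permutation from ``rng`` alone and
    return the statistic (scalar or vector) of that permuted dataset.
    """
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    scalar = np.isscalar(observed) or np.ndim(observed) == 0
    chunks = plan.chunks
    if plan.workers == 1 or len(chunks) <= 1:
        parts = [_chunk_exceed(stat_fn, obs, plan.master_seed, a, b, i)
                 for i, (a, b) in enumerate(chunks)]
    else:
        parts = Parallel(n_jobs=plan.workers, backend="threading")(
            delayed(_chunk_exceed)(stat_fn, obs, plan.master_seed, a, b, i)
            for i, (a, b) in enumerate(chunks))
    exceed = np.zeros(obs.shape, dtype=np.int64)
    for part in parts:
        exceed += part
    p = (1.0 + exceed) / (1.0 + plan.nperm)
    if scalar:
        return PermTestResult(float(obs[0]), plan.nperm, int(exceed[0]),
                              float(p[0]), plan.master_seed)
    return PermTestResult(obs, plan.nperm, exceed, p, plan.master_seed)


def chunked_outer(x: np.ndarray, y: np.ndarray,
                  block: int) -> Iterator[np.ndarray]:
    """Outer product streamed as row blocks.

    The elementary out-of-core pattern: the concatenation of the yielded
    blocks equals ``np.outer(x, y)`` but only ``block`` rows are ever
    resident.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0 or y.size == 0:
        raise ValidationError("vectors must be non-empty")
    if block < 1:
        raise ValidationError("block must be >= 1")
    for r0 in range(0, x.size, block):
        yield np.outer(x[r0:r0 + block], y)


def chunk_items(items: Sequence, chunk_size: int) -> list[Sequence]:
    """Split a work list into contiguous chunks (for non-permutation
    chunked searches such as the environmental subset scan)."""
    if chunk_size < 1:
        raise ValidationError("chunk_size must be >= 1")
    return [items[i:i + chunk_size] for i in range(0, len(items), chunk_size)]
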