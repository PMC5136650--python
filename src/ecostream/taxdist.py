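"""Taxonomic distances between species from a classification table.

The distance ``omega(i, j)`` between two species is the cumulative path
length through the taxonomic hierarchy up to the lowest rank at which
they agree, scaled so that the maximum attainable distance is 100.  Two
distinct species sharing even the lowest kept rank are separated by one
increment (the species level itself is the first step), so ``omega`` is
zero only on the diagonal.

Step lengths come in two flavours:

* equal steps — every level, from species up to the implicit root,
  contributes the same increment ``100 / (K + 1)`` for ``K`` kept ranks;
* ``varstep`` — the increment between consecutive levels is proportional
  to the relative drop in category richness, raw steps
  ``(S - r_1)/S, (r_1 - r_2)/r_1, ..., (r_K - 1)/r_K`` for category
  counts ``r_k`` (lowest rank first), normalised to sum to 100.

With ``check`` enabled, ranks that are uninformative — every species
distinct (count == S) or every species identical (count == 1) — are
dropped before the steps are computed.

The full ``S x S`` matrix is quadratic in the species count, so the
module's primitive is a *row block*: a contiguous band of rows computed
on demand.  Concatenating blocks of any size reproduces the full matrix
exactly, which is what lets downstream consumers stream over pools far
too large to hold in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import MemoryBudgetError, ValidationError
from .io import AggregationTable

__all__ = [
    "StepLengths",
    "TaxDistBlock",
    "compute_steps",
    "rank_codes",
    "taxa2dist_block",
    "iter_taxdist_blocks",
    "taxa2dist_full",
    "default_block_rows",
]

SCALE_MAX = 100.0
DEFAULT_MEMORY_BUDGET = 2 << 30  # dense-matrix guard, bytes
DEFAULT_BLOCK_BYTES = 64 << 20


@dataclass
class StepLengths:
    """Path-length increments through the kept taxonomic levels.

    ``kept_rank_names`` are ordered by decreasing category count (ties
    keep input low-to-high order), which for a hierarchical
    classification is the lowest rank first.  ``increments`` has one
    entry more than the kept ranks: the leading entry is the species
    level step, the trailing entry the step to the implicit root.
    ``cumulative[k]`` is the distance between species that first agree
    at level ``k`` (0 = lowest kept rank); the last entry is 100.
    """

    kept_rank_names: list[str]
    kept_richness: list[int]
    increments: np.ndarray
    cumulative: np.ndarray
    scale_max: float = SCALE_MAX

    def __post_init__(self) -> None:
        self.increments = np.asarray(self.increments, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if (self.increments <= 0).any():
            raise ValidationError("step increments must be positive")
        if not np.all(np.diff(self.cumulative) > 0):
            raise ValidationError("cumulative steps must strictly increase")
        if abs(self.cumulative[-1] - self.scale_max) > 1e-9:
            raise ValidationError("cumulative steps must end at scale_max")


@dataclass
class TaxDistBlock:
    """A contiguous band of rows of the species distance matrix."""

    row_range: tuple[int, int]
    values: np.ndarray  # (r1 - r0, S)
    species_ids: list[str]

    @property
    def nbytes(self) -> int:
        return self.values.nbytes


def compute_steps(agg: AggregationTable, varstep: bool = False,
                  check: bool = True) -> StepLengths:
    """Derive step lengths from the category richness of each rank."""
    S = agg.n_species
    richness = [len(set(map(str, agg.labels[:, k]))) for k in range(agg.n_ranks)]
    if check:
        kept = [k for k, r in enumerate(richness) if 1 < r < S]
    else:
        kept = list(range(agg.n_ranks))
    if not kept:
        raise ValidationError(
            "no informative taxonomic levels: every rank is either "
            "all-distinct or all-identical")
    # decreasing category count; stable sort preserves input (low->high)
    # order on ties
    kept.sort(key=lambda k: -richness[k])
    rich = np.array([richness[k] for k in kept], dtype=float)
    if varstep:
        levels = np.concatenate([[S], rich, [1.0]])
        raw = -np.diff(levels) / levels[:-1]
        if (raw < 0).any():
            raise ValidationError(
                "category richness must not increase from low to high ranks")
        if raw.sum() <= 0:
            raise ValidationError("degenerate classification: zero total step")
        increments = raw / raw.sum() * SCALE_MAX
    else:
        k1 = len(kept) + 1
        increments = np.full(k1, SCALE_MAX / k1)
    if (increments <= 0).any():
        raise ValidationError(
            "zero-length taxonomic step; re-run with check enabled to drop "
            "uninformative ranks")
    return StepLengths(
        kept_rank_names=[agg.rank_names[k] for k in kept],
        kept_richness=[richness[k] for k in kept],
        increments=increments,
        cumulative=np.cumsum(increments),
    )


def rank_codes(agg: AggregationTable, steps: StepLengths) -> np.ndarray:
    """Integer category codes per kept rank, shape (K, S)."""
    cols = []
    name_to_col = {r: k for k, r in enumerate(agg.rank_names)}
    for rank in steps.kept_rank_names:
        col = agg.labels[:, name_to_col[rank]]
        codes, _ = pd.factorize(np.asarray([str(c) for c in col], dtype=object))
        cols.append(codes.astype(np.int64))
    return np.vstack(cols)


def taxa2dist_block(agg: AggregationTable, steps: StepLengths,
                    row_range: tuple[int, int],
                    codes: np.ndarray | None = None) -> TaxDistBlock:
    """Compute rows ``[r0, r1)`` of the distance matrix.

    ``omega[i, j] = base + sum_k step_k * [i, j differ at kept rank k]``
    for ``i != j``, zero on the diagonal.
    """
    r0, r1 = row_range
    S = agg.n_species
    if not (0 <= r0 < r1 <= S):
        raise ValidationError(f"invalid row range [{r0}, {r1}) for S={S}")
    if codes is None:
        codes = rank_codes(agg, steps)
    base = steps.increments[0]
    block = np.full((r1 - r0, S), base)
    for k in range(codes.shape[0]):
        block += steps.increments[k + 1] * (
            codes[k, r0:r1, None] != codes[k, None, :])
    rows = np.arange(r0, r1)
    block[rows - r0, rows] = 0.0
    return TaxDistBlock((r0, r1), block, list(agg.species_ids))


def default_block_rows(S: int, block_bytes: int = DEFAULT_BLOCK_BYTES) -> int:
    """Rows per block so one block is about ``block_bytes`` of float64."""
    return max(1, int(block_bytes // (8 * max(S, 1))))


def iter_taxdist_blocks(agg: AggregationTable, steps: StepLengths,
                        block_rows: int | None = None) -> Iterator[TaxDistBlock]:
    """Stream the distance matrix as successive row blocks."""
    S = agg.n_species
    if block_rows is None:
        block_rows = default_block_rows(S)
    if block_rows < 1:
        raise ValidationError("block_rows must be >= 1")
    codes = rank_codes(agg, steps)
    for r0 in range(0, S, block_rows):
        yield taxa2dist_block(agg, steps, (r0, min(r0 + block_rows, S)), codes)


def taxa2dist_full(agg: AggregationTable, varstep: bool = False,
                   check: bool = True, block_rows: int | None = None,
                   memory_budget: int = DEFAULT_MEMORY_BUDGET
                   ) -> tuple[np.ndarray, list[str]]:
    """Assemble the full square distance matrix from blocks.

    Guarded by a memory budget: pools whose dense matrix would not fit
    should go through the streaming diversity pipeline instead, which
    works with input data of any size.
    """
    S = agg.n_species
    if S == 1:
        # a single species is at distance zero from itself; no steps exist
        return np.zeros((1, 1)), list(agg.species_ids)
    need = S * S * 8
    if need > memory_budget:
        raise MemoryBudgetError(
            f"dense {S}x{S} distance matrix needs {need / 2**30:.1f} GiB "
            f"(budget {memory_budget / 2**30:.1f} GiB); use the streaming "
            "taxondive pipeline, which handles input data of any size")
    steps = compute_steps(agg, varstep=varstep, check=check)
    out = np.empty((S, S))
    for block in iter_taxdist_blocks(agg, steps, block_rows):
        r0, r1 = block.row_range
        out[r0:r1, :] = block.values
    return out, list(agg.species_ids)
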