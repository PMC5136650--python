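"""Dissimilarity kernels and condensed-form plumbing.

Every analysis in the package works on a *condensed* dissimilarity: the
length ``n(n-1)/2`` vector of upper-triangle pairwise values under the
lexicographic pair order where pair ``(i, j)`` with ``i < j`` lives at
index ``k = i*(2n - i - 1)/2 + (j - i - 1)`` (the scipy ``pdist``
convention).  Square matrices exist only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import ValidationError
from .io import CommunityMatrix, EnvMatrix

__all__ = [
    "CondensedDissimilarity",
    "bray_curtis",
    "euclidean_scaled",
    "rank_with_ties",
    "pair_index",
    "pair_of",
]


@dataclass
class CondensedDissimilarity:
    """Pairwise sample dissimilarities in condensed (upper triangle) form."""

    n: int
    values: np.ndarray
    metric: str
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        m = self.n * (self.n - 1) // 2
        if self.values.shape != (m,):
            raise ValidationError(
                f"condensed vector has length {self.values.shape}, "
                f"expected {m} for n={self.n}")
        if len(self.labels) != self.n:
            raise ValidationError("label count does not match n")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite dissimilarity value")
        if (self.values < 0).any():
            raise ValidationError("negative dissimilarity value")

    def squareform(self) -> np.ndarray:
        """Expand to the symmetric square matrix (small n only)."""
        return squareform(self.values, checks=False)

    @classmethod
    def from_square(cls, labels: Sequence[str], matrix: np.ndarray,
                    metric: str = "external") -> "CondensedDissimilarity":
        matrix = np.asarray(matrix, dtype=float)
        n = matrix.shape[0]
        if matrix.shape != (n, n):
            raise ValidationError("distance matrix must be square")
        if not np.allclose(matrix, matrix.T, rtol=0, atol=1e-8):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(matrix), 0, atol=1e-8):
            raise ValidationError("distance matrix diagonal is not zero")
        sym = 0.5 * (matrix + matrix.T)
        np.fill_diagonal(sym, 0.0)
        return cls(n, squareform(sym, checks=False), metric, list(labels))

    def permuted(self, order: np.ndarray) -> "CondensedDissimilarity":
        """Apply one sample permutation to rows and columns simultaneously."""
        order = np.asarray(order)
        sq = self.squareform()[np.ix_(order, order)]
        return CondensedDissimilarity(
            self.n, squareform(sq, checks=False), self.metric,
            [self.labels[i] for i in order])

    def write_pairs_csv(self, path: Union[str, Path]) -> None:
        """Export as a 2-column CSV of (pair label, value)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pair,value\n")
            for k, v in enumerate(self.values):
                i, j = pair_of(k, self.n)
                fh.write(f"{self.labels[i]}|{self.labels[j]},{v:.17g}\n")


def bray_curtis(comm: CommunityMatrix) -> CondensedDissimilarity:
    """Bray-Curtis dissimilarity between all sample pairs.

    ``d(u, v) = sum_k |u_k - v_k| / sum_k (u_k + v_k)``, in [0, 1].
    Undefined (error) when a pair of samples is jointly all-zero.
    """
    x = comm.abundance
    if comm.n_samples < 2:
        raise ValidationError("need at least 2 samples for a dissimilarity")
    empty = np.flatnonzero(x.sum(axis=1) == 0)
    if empty.size >= 2:
        bad = [comm.sample_ids[i] for i in empty]
        raise ValidationError(
            f"Bray-Curtis undefined: samples with zero total abundance {bad}")
    return CondensedDissimilarity(
        comm.n_samples, pdist(x, metric="braycurtis"), "bray-curtis",
        list(comm.sample_ids))


def euclidean_scaled(env: EnvMatrix,
                     columns: Sequence[str] | None = None) -> CondensedDissimilarity:
    """Euclidean distance on centred, unit-sd (sample sd, n-1) variables."""
    if columns is None:
        columns = list(env.var_names)
    pos = {v: i for i, v in enumerate(env.var_names)}
    try:
        idx = [pos[c] for c in columns]
    except KeyError as exc:
        raise ValidationError(f"unknown environmental variable {exc.args[0]!r}")
    if not idx:
        raise ValidationError("no environmental columns selected")
    x = env.values[:, idx]
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance environmental column(s): "
            f"{[columns[i] for i in zero]}")
    z = (x - x.mean(axis=0)) / sd
    return CondensedDissimilarity(
        env.n_samples, pdist(z, metric="euclidean"), "euclidean",
        list(env.sample_ids))


def rank_with_ties(values: np.ndarray) -> np.ndarray:
    """Midranks (average rank for ties); ranks sum to m(m+1)/2."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot rank an empty vector")
    return rankdata(values, method="average")


def pair_index(i: int, j: int, n: int) -> int:
    """Condensed index of pair ``(i, j)`` with ``0 <= i < j < n``."""
    if not (0 <= i < j < n):
        raise ValidationError(f"invalid pair ({i}, {j}) for n={n}")
    return i * (2 * n - i - 1) // 2 + (j - i - 1)


def pair_of(k: int, n: int) -> tuple[int, int]:
    """Inverse of :func:`pair_index`."""
    m = n * (n - 1) // 2
    if not (0 <= k < m):
        raise ValidationError(f"condensed index {k} out of range for n={n}")
    # largest i whose first pair (i, i+1) has condensed index <= k
    def offset(i: int) -> int:
        return i * (2 * n - i - 1) // 2

    i = int((2 * n - 1 - math.isqrt((2 * n - 1) ** 2 - 8 * k)) // 2)
    i = max(0, min(i, n - 2))
    while i > 0 and offset(i) > k:  # guard against isqrt edge cases
        i -= 1
    while i < n - 2 and offset(i + 1) <= k:
        i += 1
    j = k - offset(i) + i + 1
    return i, j
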