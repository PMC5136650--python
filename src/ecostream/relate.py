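"""Matrix-correlation tests: Mantel, partial Mantel, and the BioEnv
search for the environmental variable subset best matching community
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from joblib import Parallel, delayed
from scipy.spatial.distance import pdist, squareform

from .dissim import CondensedDissimilarity, rank_with_ties
from .errors import ValidationError
from .io import EnvMatrix
from .perm import ChunkPlan, PermTestResult, chunk_items, run_permutations

__all__ = ["MantelResult", "BioEnvResult", "mantel", "partial_mantel", "bioenv"]

BIOENV_NCOL_CAP = 15  # exhaustive search guard; override with force=True


@dataclass
class MantelResult:
    """Matrix correlation between condensed dissimilarities."""

    r: float
    method: str
    perm: PermTestResult
    partial: bool = False
    control_metric: str | None = None


def _prepare(values: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        values = rank_with_ties(values)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    sd = values.std()
    if sd == 0:
        raise ValidationError("zero variance in a dissimilarity vector")
    return (values - values.mean()) / sd


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float((a * b).mean())


def _check_compatible(*dists: CondensedDissimilarity) -> None:
    first = dists[0]
    for d in dists[1:]:
        if d.n != first.n:
            raise ValidationError("dissimilarities have different sample counts")
        if d.labels != first.labels:
            raise ValidationError("dissimilarities have different sample labels")


def mantel(dx: CondensedDissimilarity, dy: CondensedDissimilarity,
           method: str = "pearson", plan: ChunkPlan | None = None
           ) -> MantelResult:
    """Mantel statistic: correlation of two dissimilarity matrices.

    ``r`` is the Pearson correlation of the condensed vectors (for
    Spearman, of their midranks).  The null permutes rows and columns of
    the first matrix simultaneously by one sample permutation.
    """
    _check_compatible(dx, dy)
    zy = _prepare(dy.values, method)
    zx = _prepare(dx.values, method)
    observed = _corr(zx, zy)
    if plan is None:
        plan = ChunkPlan(master_seed=0, nperm=0)
    n = dx.n
    sx = squareform(dx.values, checks=False)

    def perm_stat(rng: np.random.Generator) -> float:
        order = rng.permutation(n)
        v = squareform(sx[np.ix_(order, order)], checks=False)
        return _corr(_prepare(v, method), zy)

    perm = run_permutations(perm_stat, observed, plan)
    return MantelResult(r=float(observed), method=method, perm=perm)


def partial_mantel(dx: CondensedDissimilarity, dy: CondensedDissimilarity,
                   dz: CondensedDissimilarity, method: str = "pearson",
                   plan: ChunkPlan | None = None) -> MantelResult:
    """Partial Mantel statistic controlling for a third matrix:

    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``;
    the null permutes the first matrix only.
    """
    _check_compatible(dx, dy, dz)
    zy = _prepare(dy.values, method)
    zz = _prepare(dz.values, method)
    r_yz = _corr(zy, zz)

    def partial_r(zx: np.ndarray) -> float:
        r_xy = _corr(zx, zy)
        r_xz = _corr(zx, zz)
        numer = r_xy - r_xz * r_yz
        denom = (1 - r_xz ** 2) * (1 - r_yz ** 2)
        if denom <= 1e-24:
            # a control correlation of +-1 forces the numerator to zero
            # as well (the control is an affine copy of one matrix); the
            # partial correlation degenerates to 0/0 and is reported as 0
            if abs(numer) < 1e-9:
                return 0.0
            raise ValidationError(
                "partial Mantel undefined: a control correlation is +-1")
        return numer / np.sqrt(denom)

    observed = partial_r(_prepare(dx.values, method))
    if plan is None:
        plan = ChunkPlan(master_seed=0, nperm=0)
    n = dx.n
    sx = squareform(dx.values, checks=False)

    def perm_stat(rng: np.random.Generator) -> float:
        order = rng.permutation(n)
        v = squareform(sx[np.ix_(order, order)], checks=False)
        return partial_r(_prepare(v, method))

    perm = run_permutations(perm_stat, observed, plan)
    return MantelResult(r=float(observed), method=method, perm=perm,
                        partial=True, control_metric=dz.metric)


@dataclass
class BioEnvResult:
    """Best environmental subset per size and overall."""

    best_by_size: dict[int, tuple[tuple[str, ...], float]]
    best_subset: tuple[str, ...]
    best_rho: float
    n_evaluated: int

    def to_rows(self) -> list[dict]:
        return [
            {"size": k, "subset": " ".join(sub), "rho": rho,
             "best": sub == self.best_subset}
            for k, (sub, rho) in sorted(self.best_by_size.items())
        ]


def _subset_rho(z: np.ndarray, cols: tuple[int, ...],
                comm_ranks_z: np.ndarray) -> float:
    d = pdist(z[:, cols], metric="euclidean")
    r = rank_with_ties(d)
    sd = r.std()
    if sd == 0:
        return np.nan
    r = (r - r.mean()) / sd
    return float((r * comm_ranks_z).mean())


def bioenv(comm_dist: CondensedDissimilarity, env: EnvMatrix,
           max_size: int | None = None, chunk_size: int = 64,
           workers: int = 1, force: bool = False) -> BioEnvResult:
    """Exhaustive best-subset search over environmental variables.

    For every non-empty variable subset up to ``max_size``, computes
    Euclidean distances of the scaled (centred, unit sample-sd)
    variables and their Spearman rank correlation with the community
    dissimilarities; reports the best subset per size and overall.

    The subset list, flattened in size-then-lexicographic order, is
    split into chunks evaluated by a worker pool; the result is
    independent of chunk layout and worker count.  Because the work is
    bounded by the number of variable combinations, using more workers
    than there are variables buys nothing — a warning is emitted.
    """
    ncol = env.n_vars
    if env.n_samples != comm_dist.n or env.sample_ids != comm_dist.labels:
        raise ValidationError(
            "environmental samples do not match dissimilarity labels; "
            "align with align_by_sample first")
    if max_size is None:
        max_size = ncol
    if not (1 <= max_size <= ncol):
        raise ValidationError(f"max_size must be in [1, {ncol}]")
    if ncol > BIOENV_NCOL_CAP and not force:
        raise ValidationError(
            f"{ncol} environmental variables means "
            f"{sum(comb(ncol, k) for k in range(1, max_size + 1))} subsets; "
            "pass force=True to run an exhaustive search this large")
    if workers > ncol:
        warnings.warn(
            f"using {workers} workers for {ncol} environmental variables is "
            "not useful: parallelism is bounded by the number of variables",
            stacklevel=2)

    sd = env.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance environmental column(s): "
            f"{[env.var_names[i] for i in zero]}")
    z = (env.values - env.values.mean(axis=0)) / sd

    cr = rank_with_ties(comm_dist.values)
    cr_sd = cr.std()
    if cr_sd == 0:
        raise ValidationError("community dissimilarities are all tied")
    cr = (cr - cr.mean()) / cr_sd

    subsets = [cols for k in range(1, max_size + 1)
               for cols in combinations(range(ncol), k)]

    def eval_chunk(chunk: list[tuple[int, ...]]) -> list[float]:
        return [_subset_rho(z, cols, cr) for cols in chunk]

    chunks = chunk_items(subsets, chunk_size)
    if workers == 1 or len(chunks) <= 1:
        parts = [eval_chunk(c) for c in chunks]
    else:
        parts = Parallel(n_jobs=workers, backend="threading")(
            delayed(eval_chunk)(c) for c in chunks)
    rhos = [r for part in parts for r in part]

    best_by_size: dict[int, tuple[tuple[str, ...], float]] = {}
    for cols, rho in zip(subsets, rhos):
        k = len(cols)
        named = tuple(env.var_names[c] for c in cols)
        if np.isnan(rho):
            continue
        if k not in best_by_size or rho > best_by_size[k][1]:
            best_by_size[k] = (named, rho)
    if not best_by_size:
        raise ValidationError("no valid subset (all correlations undefined)")
    best_subset, best_rho = max(
        best_by_size.values(), key=lambda t: (t[1], -len(t[0])))
    return BioEnvResult(best_by_size=best_by_size, best_subset=best_subset,
                        best_rho=float(best_rho), n_evaluated=len(subsets))
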