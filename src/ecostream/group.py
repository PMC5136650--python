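"""Grouped-design permutation tests: ANOSIM, one-way PERMANOVA, SIMPER.

All three permute group labels over samples through the chunked
permutation engine, so their p-values are reproducible for a given
master seed and invariant to worker count and chunk layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissim import CondensedDissimilarity, bray_curtis, rank_with_ties
from .errors import ValidationError
from .io import CommunityMatrix, FactorVector
from .perm import ChunkPlan, PermTestResult, run_permutations

__all__ = ["AnosimResult", "PermanovaTable", "SimperTable",
           "anosim", "permanova_oneway", "simper"]


def _group_codes(dist_labels: list[str], groups: FactorVector) -> np.ndarray:
    if list(groups.sample_ids) != list(dist_labels):
        raise ValidationError(
            "factor sample order does not match dissimilarity labels; "
            "align with align_by_sample first")
    codes, _ = pd.factorize(np.asarray(groups.levels, dtype=object))
    if len(set(groups.levels)) < 2:
        raise ValidationError("need at least 2 groups")
    return codes.astype(np.int64)


@dataclass
class AnosimResult:
    """ANOSIM statistic R in [-1, 1] with its permutation null."""

    R: float
    perm: PermTestResult


def _anosim_r(ranks: np.ndarray, same: np.ndarray, m: int) -> float:
    # R = (mean between-group rank - mean within-group rank) / (M/2)
    mean_within = ranks[same].mean() if same.any() else 0.0
    mean_between = ranks[~same].mean() if (~same).any() else 0.0
    return (mean_between - mean_within) / (m / 2.0)


def anosim(dist: CondensedDissimilarity, groups: FactorVector,
           plan: ChunkPlan) -> AnosimResult:
    """Analysis of similarities: do between-group dissimilarities rank
    higher than within-group ones?"""
    n = dist.n
    if n < 4:
        raise ValidationError("ANOSIM needs at least 4 samples")
    codes = _group_codes(dist.labels, groups)
    ranks = rank_with_ties(dist.values)
    m = ranks.size
    iu, ju = np.triu_indices(n, k=1)

    def same_mask(c: np.ndarray) -> np.ndarray:
        return c[iu] == c[ju]

    observed = _anosim_r(ranks, same_mask(codes), m)

    def perm_stat(rng: np.random.Generator) -> float:
        c = codes[rng.permutation(n)]
        return _anosim_r(ranks, same_mask(c), m)

    perm = run_permutations(perm_stat, observed, plan)
    return AnosimResult(R=float(observed), perm=perm)


@dataclass
class PermanovaTable:
    """One-way PERMANOVA partition with a pseudo-F permutation test."""

    terms: pd.DataFrame  # rows: factor, residual, total
    pseudo_f: float
    r_squared: float
    perm: PermTestResult

    @property
    def f_infinite(self) -> bool:
        return np.isinf(self.pseudo_f)


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, iu: np.ndarray,
                  ju: np.ndarray, n: int, counts: np.ndarray) -> tuple[float, float]:
    ss_total = d2.sum() / n
    within = codes[iu] == codes[ju]
    ss_within = 0.0
    for g in range(counts.size):
        mask = within & (codes[iu] == g)
        if mask.any():
            ss_within += d2[mask].sum() / counts[g]
    return ss_total, ss_within


def permanova_oneway(dist: CondensedDissimilarity, groups: FactorVector,
                     plan: ChunkPlan) -> PermanovaTable:
    """Partition squared dissimilarity among and within groups.

    ``SS_total = (1/n) sum_{i<j} d_ij^2``; ``SS_within`` sums each
    group's internal squared dissimilarities scaled by group size;
    ``pseudo-F = (SS_among / (a-1)) / (SS_within / (n-a))``.  A zero
    within-group sum of squares yields an infinite F, flagged rather
    than raised; permuted statistics that are also infinite count as
    exceedances.
    """
    n = dist.n
    codes = _group_codes(dist.labels, groups)
    a = codes.max() + 1
    if n - a < 1:
        raise ValidationError("no residual degrees of freedom (n == groups)")
    counts = np.bincount(codes, minlength=a).astype(float)
    d2 = dist.values ** 2
    iu, ju = np.triu_indices(n, k=1)

    def f_stat(c: np.ndarray) -> tuple[float, float, float]:
        ss_total, ss_within = _permanova_ss(d2, c, iu, ju, n, counts)
        ss_among = ss_total - ss_within
        if ss_within == 0.0:
            return np.inf, ss_total, ss_within
        return ((ss_among / (a - 1)) / (ss_within / (n - a)),
                ss_total, ss_within)

    observed_f, ss_total, ss_within = f_stat(codes)
    ss_among = ss_total - ss_within

    def perm_stat(rng: np.random.Generator) -> float:
        return f_stat(codes[rng.permutation(n)])[0]

    perm = run_permutations(perm_stat, observed_f, plan)
    r2 = ss_among / ss_total if ss_total > 0 else np.nan
    terms = pd.DataFrame(
        {
            "df": [a - 1, n - a, n - 1],
            "SS": [ss_among, ss_within, ss_total],
            "MS": [ss_among / (a - 1), ss_within / (n - a), np.nan],
            "F": [observed_f, np.nan, np.nan],
            "R2": [r2, np.nan, np.nan],
        },
        index=["factor", "residual", "total"],
    )
    return PermanovaTable(terms=terms, pseudo_f=float(observed_f),
                          r_squared=float(r2), perm=perm)


@dataclass
class SimperTable:
    """Per-species decomposition of between-group Bray-Curtis
    dissimilarity for one group pair."""

    group_a: str
    group_b: str
    species_ids: list[str]
    average: np.ndarray        # mean contribution per species (0-1 scale)
    sd: np.ndarray
    ratio: np.ndarray          # average / sd
    overall: float             # mean between-group dissimilarity
    perm: PermTestResult       # per-species permutation p-values

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.average, kind="stable")
        cum = np.cumsum(self.average[order]) / self.overall \
            if self.overall > 0 else np.zeros(self.average.size)
        df = pd.DataFrame(
            {
                "average": self.average[order],
                "sd": self.sd[order],
                "ratio": self.ratio[order],
                "cumulative": cum,
                "p": np.asarray(self.perm.p_value)[order],
            },
            index=[self.species_ids[i] for i in order],
        )
        return df


def _simper_contrib(x: np.ndarray, idx_a: np.ndarray,
                    idx_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-species contributions for every between-group pair.

    Returns (n_pairs x S contributions, per-species mean)."""
    rows = []
    for u in idx_a:
        for v in idx_b:
            denom = (x[u] + x[v]).sum()
            if denom == 0:
                raise ValidationError(
                    "Bray-Curtis undefined for a pair of all-zero samples")
            rows.append(np.abs(x[u] - x[v]) / denom)
    contrib = np.asarray(rows)
    return contrib, contrib.mean(axis=0)


def simper(comm: CommunityMatrix, groups: FactorVector,
           plan: ChunkPlan) -> list[SimperTable]:
    """Similarity percentages: which species drive between-group
    Bray-Curtis dissimilarity?

    For each between-group sample pair ``(u, v)`` species ``k``
    contributes ``|u_k - v_k| / sum_l (u_l + v_l)``; contributions are
    averaged over pairs (so they sum exactly to the mean between-group
    dissimilarity) and each species' average is tested by permuting
    group labels while keeping sample profiles intact.  One table per
    unordered group pair.
    """
    if list(groups.sample_ids) != list(comm.sample_ids):
        raise ValidationError(
            "factor sample order does not match community rows; "
            "align with align_by_sample first")
    levels = list(dict.fromkeys(groups.levels))  # first-appearance order
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    lv = np.asarray(groups.levels, dtype=object)
    x = comm.abundance
    n = comm.n_samples
    tables = []
    for ia in range(len(levels)):
        for ib in range(ia + 1, len(levels)):
            ga, gb = levels[ia], levels[ib]
            idx_a = np.flatnonzero(lv == ga)
            idx_b = np.flatnonzero(lv == gb)
            contrib, avg = _simper_contrib(x, idx_a, idx_b)
            sd = contrib.std(axis=0, ddof=1) if contrib.shape[0] > 1 \
                else np.zeros(avg.size)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(sd > 0, avg / sd, np.nan)
            na, nb = idx_a.size, idx_b.size

            def perm_stat(rng: np.random.Generator,
                          _na=na, _nb=nb) -> np.ndarray:
                order = rng.permutation(n)
                return _simper_contrib(x, order[:_na], order[_na:_na + _nb])[1]

            perm = run_permutations(perm_stat, avg, plan)
            tables.append(SimperTable(
                group_a=str(ga), group_b=str(gb),
                species_ids=list(comm.species_ids),
                average=avg, sd=sd, ratio=ratio,
                overall=float(avg.sum()), perm=perm))
    return tables
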