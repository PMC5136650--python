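"""Taxonomic diversity and distinctness indices per sample.

Indices are averaged taxonomic distances among the individuals or
species of each sample, for abundances ``x_i`` and species distances
``omega_ij`` (pairs ``i < j`` present in the sample, ``N`` individuals,
``S_s`` species present):

* ``Delta``  = sum omega_ij x_i x_j / (N (N - 1) / 2) — taxonomic
  diversity, the expected distance between two random individuals
  (including same-species draws in the denominator);
* ``Delta*`` = sum omega_ij x_i x_j / sum x_i x_j — taxonomic
  distinctness, conditioning on the two individuals being different
  species;
* ``Delta+`` = mean omega over species pairs present (presence/absence);
* ``sDelta+`` = S_s * Delta+;
* ``Lambda+`` = variance of omega over species pairs present;
* ``EDelta+`` = mean omega over the full species pool, the funnel-plot
  centre line.

Indices whose denominator vanishes (fewer than 2 species present for
Delta+/Lambda+, fewer than 2 individuals for Delta) are NaN with a
logged warning rather than an error, so batch runs survive sparse
samples.

Two execution paths produce identical numbers.  The naive path takes a
dense distance matrix.  The streaming path consumes distance row blocks
as they are produced and keeps only per-sample accumulators — the dense
matrix is never materialised, so the species pool can be arbitrarily
large.  Since the distances are consumed as soon as they are computed,
the distance and diversity stages share one pass over the data and no
pairwise distance is computed twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AggregationTable, CommunityMatrix
from .taxdist import (StepLengths, compute_steps, default_block_rows,
                      iter_taxdist_blocks)

logger = logging.getLogger(__name__)

__all__ = ["TaxonDiveResult", "FunnelTable", "taxondive_naive",
           "taxondive_streaming", "funnel"]


@dataclass
class TaxonDiveResult:
    """Per-sample diversity indices plus the pool expectation."""

    sample_ids: list[str]
    species_richness: np.ndarray  # S_s per sample
    delta: np.ndarray
    delta_star: np.ndarray
    delta_plus: np.ndarray
    s_delta_plus: np.ndarray
    lambda_plus: np.ndarray
    e_delta_plus: float
    # accounting: largest distance buffer resident at any point while
    # computing this result (the full matrix for the naive path, one
    # block for the streaming path)
    peak_block_nbytes: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_richness": self.species_richness,
                "delta": self.delta,
                "delta_star": self.delta_star,
                "delta_plus": self.delta_plus,
                "s_delta_plus": self.s_delta_plus,
                "lambda_plus": self.lambda_plus,
            },
            index=self.sample_ids,
        )


@dataclass
class FunnelTable:
    """Monte-Carlo expectation and quantile band of Delta+ vs richness."""

    sizes: list[int]
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_draws: int
    lower_q: float
    upper_q: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"m": self.sizes, "mean_delta_plus": self.mean,
             "lower": self.lower, "upper": self.upper},
        ).set_index("m")


@dataclass
class _Accumulators:
    """Per-sample running sums over species pairs i < j."""

    wxx: np.ndarray        # sum omega x_i x_j
    w_present: np.ndarray  # sum omega over present pairs
    w2_present: np.ndarray  # sum omega^2 over present pairs
    w_pool: float           # sum omega over all pool pairs
    # pair counts are cheap closed forms, computed at finalise time


def _finalise(comm: CommunityMatrix, acc: _Accumulators,
              peak_block_nbytes: int = 0) -> TaxonDiveResult:
    x = comm.abundance
    n_ind = x.sum(axis=1)                      # N per sample
    richness = (x > 0).sum(axis=1).astype(float)
    S = comm.n_species

    with np.errstate(invalid="ignore", divide="ignore"):
        ind_pairs = n_ind * (n_ind - 1) / 2.0
        xx = (n_ind ** 2 - (x ** 2).sum(axis=1)) / 2.0   # sum_{i<j} x_i x_j
        sp_pairs = richness * (richness - 1) / 2.0

        delta = np.where(ind_pairs > 0, acc.wxx / ind_pairs, np.nan)
        delta_star = np.where(xx > 0, acc.wxx / xx, np.nan)
        delta_plus = np.where(sp_pairs > 0, acc.w_present / sp_pairs, np.nan)
        lambda_plus = np.where(
            sp_pairs > 0, acc.w2_present / sp_pairs - delta_plus ** 2, np.nan)

    undefined = np.flatnonzero(~np.isfinite(delta_plus))
    if undefined.size:
        logger.warning(
            "Delta+/Lambda+ undefined (fewer than 2 species present) for "
            "samples: %s", [comm.sample_ids[i] for i in undefined])
    if np.any(ind_pairs <= 0):
        logger.warning(
            "Delta undefined (fewer than 2 individuals) for samples: %s",
            [comm.sample_ids[i] for i in np.flatnonzero(ind_pairs <= 0)])

    e_delta_plus = acc.w_pool / (S * (S - 1) / 2.0)
    return TaxonDiveResult(
        sample_ids=list(comm.sample_ids),
        species_richness=richness,
        delta=delta,
        delta_star=delta_star,
        delta_plus=delta_plus,
        s_delta_plus=richness * delta_plus,
        lambda_plus=lambda_plus,
        e_delta_plus=float(e_delta_plus),
        peak_block_nbytes=peak_block_nbytes,
    )


def taxondive_naive(comm: CommunityMatrix, omega: np.ndarray,
                    species_ids: list[str] | None = None) -> TaxonDiveResult:
    """Indices from a dense square distance matrix (small pools)."""
    omega = np.asarray(omega, dtype=float)
    S = comm.n_species
    if omega.shape != (S, S):
        raise ValidationError(
            f"distance matrix shape {omega.shape} does not match {S} species")
    if species_ids is not None and list(species_ids) != list(comm.species_ids):
        raise ValidationError(
            "distance matrix species labels do not match community columns")
    x = comm.abundance
    p = (x > 0).astype(float)
    # symmetric with zero diagonal: quadratic forms double-count i<j pairs
    acc = _Accumulators(
        wxx=np.einsum("si,ij,sj->s", x, omega, x) / 2.0,
        w_present=np.einsum("si,ij,sj->s", p, omega, p) / 2.0,
        w2_present=np.einsum("si,ij,sj->s", p, omega ** 2, p) / 2.0,
        w_pool=float(omega.sum()) / 2.0,
    )
    return _finalise(comm, acc, peak_block_nbytes=omega.nbytes)


def taxondive_streaming(comm: CommunityMatrix, agg: AggregationTable,
                        varstep: bool = False, check: bool = True,
                        block_rows: int | None = None,
                        store=None) -> TaxonDiveResult:
    """Combined distance + diversity pipeline over row blocks.

    Equivalent to ``taxondive_naive`` on the full matrix, but only one
    distance block is ever resident; blocks are optionally persisted to
    ``store`` (keys ``omega_<r0>_<r1>``) for later reuse.
    """
    if list(comm.species_ids) != list(agg.species_ids):
        missing = set(comm.species_ids) ^ set(agg.species_ids)
        raise ValidationError(
            "community and aggregation species do not match "
            f"(symmetric difference: {sorted(missing)[:10]}{'...' if len(missing) > 10 else ''})"
            if missing else
            "community and aggregation species are ordered differently")
    S = comm.n_species
    if block_rows is None:
        block_rows = default_block_rows(S)
    steps = compute_steps(agg, varstep=varstep, check=check)
    x = comm.abundance
    p = (x > 0).astype(float)
    n = comm.n_samples

    acc = _Accumulators(
        wxx=np.zeros(n), w_present=np.zeros(n), w2_present=np.zeros(n),
        w_pool=0.0)
    cols = np.arange(S)
    peak = 0
    for block in iter_taxdist_blocks(agg, steps, block_rows):
        r0, r1 = block.row_range
        peak = max(peak, block.nbytes)
        if store is not None:
            store.put(f"omega_{r0}_{r1}", block.values)
        # keep only the strict upper triangle of the full matrix:
        # columns j > global row index i
        upper = block.values * (cols[None, :] > np.arange(r0, r1)[:, None])
        xb = x[:, r0:r1]
        pb = p[:, r0:r1]
        acc.wxx += ((xb @ upper) * x).sum(axis=1)
        acc.w_present += ((pb @ upper) * p).sum(axis=1)
        acc.w2_present += ((pb @ upper ** 2) * p).sum(axis=1)
        acc.w_pool += float(upper.sum())
    return _finalise(comm, acc, peak_block_nbytes=peak)


def funnel(omega: np.ndarray, sizes: list[int], n_draws: int = 999,
           master_seed: int = 0, quantiles: tuple[float, float] = (0.025, 0.975)
           ) -> FunnelTable:
    """Null expectation of Delta+ for random subsamples of the pool.

    For each subsample size ``m``, draws ``n_draws`` uniform random
    m-species subsets of the pool, computes Delta+ of each and reports
    the mean with empirical quantile bounds — the funnel against which
    observed samples are judged.
    """
    omega = np.asarray(omega, dtype=float)
    S = omega.shape[0]
    if omega.shape != (S, S):
        raise ValidationError("omega must be square")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    lo_q, hi_q = quantiles
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([master_seed, 0x0F_0E_11])))
    means, lowers, uppers = [], [], []
    for m in sizes:
        if not (2 <= m <= S):
            raise ValidationError(f"subsample size {m} outside [2, {S}]")
        draws = np.empty(n_draws)
        for t in range(n_draws):
            idx = rng.choice(S, size=m, replace=False)
            sub = omega[np.ix_(idx, idx)]
            draws[t] = sub[np.triu_indices(m, k=1)].mean()
        means.append(draws.mean())
        lowers.append(float(np.quantile(draws, lo_q)))
        uppers.append(float(np.quantile(draws, hi_q)))
    return FunnelTable(list(sizes), np.asarray(means), np.asarray(lowers),
                       np.asarray(uppers), n_draws, lo_q, hi_q)
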