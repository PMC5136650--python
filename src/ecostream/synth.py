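"""Synthetic community datasets at controllable scale.

Generates the four input kinds — classification aggregation table,
abundance matrix, qualitative factor, quantitative environment — with
the structural features the analyses care about: a strictly nested
taxonomy with chosen per-rank category counts, zero-inflated log-normal
abundances (the typical right-skewed, sparse shape of community data),
an optional two-group abundance shift on a subset of species, and an
optional environmental variable planted to follow the leading ordination
axis of the community so subset-selection has a known right answer.

Named scales mirror the pool sizes the streaming pipeline is meant for:
``tiny`` (S=30) through ``small`` (1,700), ``medium`` (16,900),
``large`` (42,300) and ``xl`` (168,931) species.  Everything is
deterministic given ``master_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .io import AggregationTable, CommunityMatrix, EnvMatrix, FactorVector

__all__ = ["FixtureSpec", "SCALES", "gen_aggregation", "gen_community",
           "gen_env"]

SCALES: dict[str, int] = {
    "tiny": 30,
    "small": 1_700,
    "medium": 16_900,
    "large": 42_300,
    "xl": 168_931,
}

_DEFAULT_RANKS = ("genus", "family", "order", "class", "phylum")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``rank_richness`` gives category counts per rank, lowest rank first,
    strictly decreasing and below ``S`` (a rank with S categories would
    be uninformative and dropped by the distance step check anyway).
    ``group_effect`` is the log-scale mean shift applied in the second
    group to ``affected_frac`` of the species; zero gives exchangeable
    groups (a null fixture).
    """

    S: int = 100
    n_samples: int = 12
    rank_richness: tuple[int, ...] = (25, 8, 3)
    lognormal_mean: float = 1.0
    lognormal_sigma: float = 1.0
    zero_inflation: float = 0.3
    group_effect: float = 0.0
    affected_frac: float = 0.3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValidationError("need at least 2 species")
        if self.n_samples < 1:
            raise ValidationError("need at least 1 sample")
        rr = tuple(self.rank_richness)
        if not rr:
            raise ValidationError("need at least one taxonomic rank")
        if any(r < 1 for r in rr):
            raise ValidationError("rank richness must be positive")
        if rr[0] >= self.S:
            raise ValidationError(
                f"lowest-rank richness {rr[0]} must be below S={self.S} "
                "(an all-distinct rank carries no grouping information)")
        if any(b >= a for a, b in zip(rr, rr[1:])):
            raise ValidationError(
                "rank richness must strictly decrease from low to high ranks")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ValidationError("zero_inflation must be in [0, 1)")
        if not (0.0 <= self.affected_frac <= 1.0):
            raise ValidationError("affected_frac must be in [0, 1]")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([spec.master_seed, stream])))


def _surjective_assignment(n_children: int, n_parents: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Each child gets a parent; every parent gets at least one child."""
    if n_parents > n_children:
        raise ValidationError(
            f"cannot nest {n_children} categories under {n_parents} parents")
    parent = rng.integers(0, n_parents, size=n_children)
    # overwrite a random injective subset so all parents are hit
    chosen = rng.permutation(n_children)[:n_parents]
    parent[chosen] = np.arange(n_parents)
    return parent


def gen_aggregation(spec: FixtureSpec) -> AggregationTable:
    """Random nested classification honouring ``rank_richness``."""
    rng = _rng(spec, 1)
    rr = tuple(spec.rank_richness)
    K = len(rr)
    if K <= len(_DEFAULT_RANKS):
        rank_names = list(_DEFAULT_RANKS[:K])
    else:
        rank_names = [f"rank{k + 1}" for k in range(K)]
    # species -> lowest-rank category, then category -> parent per level
    assign = _surjective_assignment(spec.S, rr[0], rng)
    codes = np.empty((spec.S, K), dtype=np.int64)
    codes[:, 0] = assign
    for k in range(1, K):
        parent = _surjective_assignment(rr[k - 1], rr[k], rng)
        codes[:, k] = parent[codes[:, k - 1]]
    width = len(str(spec.S))
    labels = np.empty((spec.S, K), dtype=object)
    for k in range(K):
        prefix = rank_names[k][0]
        for i in range(spec.S):
            labels[i, k] = f"{prefix}{codes[i, k] + 1:0{width}d}"
    species = [f"sp{i + 1:0{width}d}" for i in range(spec.S)]
    return AggregationTable(species, rank_names, labels)


def gen_community(spec: FixtureSpec) -> tuple[CommunityMatrix, FactorVector]:
    """Zero-inflated log-normal abundances with a two-group design.

    Samples split into groups ``A`` (first half) and ``B``; in group B
    the log-mean of a random ``affected_frac`` subset of species is
    shifted by ``group_effect``.  With ``group_effect = 0`` the groups
    are exchangeable.
    """
    rng = _rng(spec, 2)
    n, S = spec.n_samples, spec.S
    n_a = n // 2 + n % 2
    group = np.array(["A"] * n_a + ["B"] * (n - n_a), dtype=object)
    n_affected = int(round(spec.affected_frac * S))
    affected = np.zeros(S, dtype=bool)
    affected[rng.permutation(S)[:n_affected]] = True

    species_mu = spec.lognormal_mean + rng.normal(0.0, 0.5, size=S)
    mu = np.tile(species_mu, (n, 1))
    mu[group == "B"] += spec.group_effect * affected
    abundance = rng.lognormal(mean=mu, sigma=spec.lognormal_sigma)
    keep = rng.random((n, S)) >= spec.zero_inflation
    abundance = np.where(keep, abundance, 0.0)
    # a sample with nothing in it breaks Bray-Curtis; give it one singleton
    empty = np.flatnonzero(abundance.sum(axis=1) == 0)
    for i in empty:
        abundance[i, rng.integers(0, S)] = 1.0

    width = len(str(n))
    samples = [f"s{i + 1:0{width}d}" for i in range(n)]
    wid_s = len(str(S))
    species = [f"sp{i + 1:0{wid_s}d}" for i in range(S)]
    comm = CommunityMatrix(samples, species, abundance)
    factor = FactorVector(samples, list(group), name="group")
    return comm, factor


def _pcoa_axis1(comm: CommunityMatrix) -> np.ndarray:
    """First principal-coordinate axis of Bray-Curtis distances."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(comm.abundance, metric="braycurtis"))
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(g)
    axis = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    # fix the sign deterministically
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def gen_env(spec: FixtureSpec, coupled_to: CommunityMatrix | None = None,
            n_vars: int = 5, coupling: float = 0.0,
            planted_name: str = "planted") -> EnvMatrix:
    """Quantitative environmental variables, optionally one planted.

    When ``coupled_to`` is given and ``coupling > 0``, the first
    variable is a monotone (linear) function of the community's leading
    ordination axis plus noise: ``coupling * axis + sqrt(1 - coupling^2)
    * noise`` on standardised scales.  At strong coupling the planted
    variable is the known best single predictor of community structure.
    Remaining variables are independent standard normals.
    """
    if not (0.0 <= coupling < 1.0):
        raise ValidationError("coupling must be in [0, 1)")
    rng = _rng(spec, 3)
    n = spec.n_samples
    values = rng.normal(0.0, 1.0, size=(n, n_vars))
    names = [f"var{k + 1}" for k in range(n_vars)]
    if coupled_to is not None and coupling > 0.0:
        if coupled_to.n_samples != n:
            raise ValidationError("coupled community has wrong sample count")
        axis = _pcoa_axis1(coupled_to)
        sd = axis.std()
        if sd > 0:
            z = (axis - axis.mean()) / sd
            values[:, 0] = coupling * z + np.sqrt(1 - coupling ** 2) * values[:, 0]
            names[0] = planted_name
    width = len(str(n))
    samples = [f"s{i + 1:0{width}d}" for i in range(n)]
    return EnvMatrix(samples, names, values)
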