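import numpy as np
import pytest

import ecostream as es


@pytest.fixture
def toy_agg():
    """Three species: A and B share a genus, C differs; family identical."""
    return es.AggregationTable(
        ["A", "B", "C"], ["genus", "family"],
        np.array([["g1", "f1"], ["g1", "f1"], ["g2", "f1"]], dtype=object))


@pytest.fixture
def toy_omega(toy_agg):
    omega, labels = es.taxa2dist_full(toy_agg)
    return omega


@pytest.fixture
def toy_comm():
    return es.CommunityMatrix(["s1"], ["A", "B", "C"], [[1.0, 1.0, 2.0]])


@pytest.fixture
def varstep_agg():
    """Four species with genus richness 3, family richness 2."""
    return es.AggregationTable(
        ["A", "B", "C", "D"], ["genus", "family"],
        np.array([["g1", "f1"], ["g1", "f1"], ["g2", "f1"], ["g3", "f2"]],
                 dtype=object))


def make_fixture(seed, S=40, n_samples=10, rank_richness=(12, 5, 2),
                 group_effect=0.0, **kwargs):
    spec = es.FixtureSpec(S=S, n_samples=n_samples,
                          rank_richness=rank_richness,
                          group_effect=group_effect, master_seed=seed,
                          **kwargs)
    agg = es.gen_aggregation(spec)
    comm, factor = es.gen_community(spec)
    return spec, agg, comm, factor


@pytest.fixture
def small_fixture():
    return make_fixture(seed=7, group_effect=0.8)
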