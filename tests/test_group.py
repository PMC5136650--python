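import itertools

import numpy as np
import pytest

import ecostream as es
from ecostream.dissim import CondensedDissimilarity
from tests.conftest import make_fixture


def _factor(labels, levels):
    return es.FactorVector(labels, levels)


def _perfect_toy():
    """4 samples, groups (1,1,2,2), all within-pair dissimilarities
    strictly below all between-pair ones."""
    sq = np.array([
        [0.0, 0.1, 0.9, 0.8],
        [0.1, 0.0, 0.7, 0.9],
        [0.9, 0.7, 0.0, 0.2],
        [0.8, 0.9, 0.2, 0.0],
    ])
    labels = ["s1", "s2", "s3", "s4"]
    d = CondensedDissimilarity.from_square(labels, sq)
    return d, _factor(labels, ["1", "1", "2", "2"])


class TestAnosim:
    def test_perfect_separation_r_one(self):
        d, f = _perfect_toy()
        res = es.anosim(d, f, es.ChunkPlan(master_seed=0, nperm=0))
        assert res.R == pytest.approx(1.0, abs=1e-12)

    def test_all_equal_dissimilarities_r_zero(self):
        labels = ["a", "b", "c", "d"]
        sq = np.full((4, 4), 0.5)
        np.fill_diagonal(sq, 0.0)
        d = CondensedDissimilarity.from_square(labels, sq)
        res = es.anosim(d, _factor(labels, ["1", "1", "2", "2"]),
                        es.ChunkPlan(master_seed=0, nperm=0))
        assert res.R == pytest.approx(0.0, abs=1e-12)

    def test_sampled_p_matches_exhaustive_enumeration(self):
        d, f = _perfect_toy()
        # enumerate all 4! orderings of the labels
        ranks = es.rank_with_ties(d.values)
        iu, ju = np.triu_indices(4, k=1)
        codes = np.array([0, 0, 1, 1])

        def r_of(c):
            same = c[iu] == c[ju]
            return (ranks[~same].mean() - ranks[same].mean()) / (6 / 2)

        observed = r_of(codes)
        exceed = sum(r_of(codes[list(p)]) >= observed
                     for p in itertools.permutations(range(4)))
        exact_fraction = exceed / 24
        assert exact_fraction == pytest.approx(1 / 3)

        res = es.anosim(d, f, es.ChunkPlan(master_seed=1, nperm=9999,
                                           chunk_size=1000))
        sampled = res.perm.exceed_count / res.perm.nperm
        assert abs(sampled - exact_fraction) < 0.03

    def test_r_invariant_to_monotone_transform(self, small_fixture):
        _, _, comm, factor = small_fixture
        d = es.bray_curtis(comm)
        plan = es.ChunkPlan(master_seed=0, nperm=0)
        r1 = es.anosim(d, factor, plan).R
        warped = CondensedDissimilarity(d.n, np.exp(3 * d.values) - 1,
                                        "external", d.labels)
        r2 = es.anosim(warped, factor, plan).R
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_single_group_errors(self):
        d, _ = _perfect_toy()
        with pytest.raises(es.ValidationError, match="2 groups"):
            es.anosim(d, _factor(d.labels, ["1"] * 4),
                      es.ChunkPlan(master_seed=0, nperm=0))


class TestPermanova:
    def test_univariate_matches_classical_anova(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        labels = [f"s{i}" for i in range(4)]
        sq = np.abs(y[:, None] - y[None, :])
        d = CondensedDissimilarity.from_square(labels, sq)
        res = es.permanova_oneway(d, _factor(labels, ["1", "1", "2", "2"]),
                                  es.ChunkPlan(master_seed=0, nperm=0))
        assert res.pseudo_f == pytest.approx(8.0, abs=1e-9)
        assert res.r_squared == pytest.approx(0.8, abs=1e-9)
        # degrees of freedom and the SS partition add up
        assert list(res.terms["df"]) == [1, 2, 3]
        ss = res.terms["SS"]
        assert ss["factor"] + ss["residual"] == pytest.approx(ss["total"],
                                                              rel=1e-9)

    def test_random_univariate_family_matches_classical_f(self):
        rng = np.random.default_rng(44)
        for _ in range(5):
            y = rng.normal(size=9)
            g = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
            labels = [f"s{i}" for i in range(9)]
            d = CondensedDissimilarity.from_square(
                labels, np.abs(y[:, None] - y[None, :]))
            res = es.permanova_oneway(d, _factor(labels, list(g)),
                                      es.ChunkPlan(master_seed=0, nperm=0))
            # classical one-way ANOVA F
            gm = y.mean()
            ss_a = sum(3 * (y[g == lev].mean() - gm) ** 2 for lev in "abc")
            ss_w = sum(((y[g == lev] - y[g == lev].mean()) ** 2).sum()
                       for lev in "abc")
            f_classic = (ss_a / 2) / (ss_w / 6)
            assert res.pseudo_f == pytest.approx(f_classic, rel=1e-9)

    def test_matches_dense_hat_matrix_oracle(self):
        # Gower-centred inner-product matrix with a projection onto group
        # dummies: F = (tr(HGH)/(a-1)) / (tr((I-H)G(I-H))/(n-a))
        rng = np.random.default_rng(11)
        n, a = 12, 3
        y = rng.normal(size=(n, 4))
        g = np.repeat(np.arange(a), n // a)
        labels = [f"s{i}" for i in range(n)]
        from scipy.spatial.distance import pdist, squareform
        sq = squareform(pdist(y))
        d = CondensedDissimilarity.from_square(labels, sq)
        res = es.permanova_oneway(
            d, _factor(labels, [str(x) for x in g]),
            es.ChunkPlan(master_seed=0, nperm=0))

        j = np.eye(n) - np.ones((n, n)) / n
        gmat = -0.5 * j @ (sq ** 2) @ j
        x = np.zeros((n, a))
        x[np.arange(n), g] = 1.0
        h = x @ np.linalg.pinv(x.T @ x) @ x.T
        ss_a = np.trace(h @ gmat @ h)
        ss_w = np.trace((np.eye(n) - h) @ gmat @ (np.eye(n) - h))
        f_oracle = (ss_a / (a - 1)) / (ss_w / (n - a))
        assert res.pseudo_f == pytest.approx(f_oracle, rel=1e-9)
        assert res.r_squared == pytest.approx(ss_a / (ss_a + ss_w), rel=1e-9)

    def test_zero_within_ss_infinite_f_flagged(self):
        labels = ["a", "b", "c", "d"]
        sq = np.array([
            [0.0, 0.0, 1.0, 1.0],
            [0.0, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
        ])
        d = CondensedDissimilarity.from_square(labels, sq)
        res = es.permanova_oneway(d, _factor(labels, ["1", "1", "2", "2"]),
                                  es.ChunkPlan(master_seed=0, nperm=99))
        assert res.f_infinite
        # permuted F can also be infinite; those count as exceedances,
        # so p is well defined and positive
        assert 0 < res.perm.p_value <= 1

    def test_no_residual_df_errors(self):
        labels = ["a", "b"]
        d = CondensedDissimilarity.from_square(
            labels, np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(es.ValidationError, match="residual"):
            es.permanova_oneway(d, _factor(labels, ["1", "2"]),
                                es.ChunkPlan(master_seed=0, nperm=0))


class TestSimper:
    def test_hand_single_pair(self):
        comm = es.CommunityMatrix(["u", "v"], ["sp1", "sp2"],
                                  [[3.0, 1.0], [1.0, 1.0]])
        f = _factor(["u", "v"], ["G1", "G2"])
        tables = es.simper(comm, f, es.ChunkPlan(master_seed=0, nperm=0))
        t = tables[0]
        np.testing.assert_allclose(t.average, [1 / 3, 0.0], rtol=1e-12)
        assert t.overall == pytest.approx(1 / 3, abs=1e-15)

    def test_identical_groups_zero_contributions(self):
        comm = es.CommunityMatrix(["a", "b"], ["sp1", "sp2"],
                                  [[2.0, 5.0], [2.0, 5.0]])
        f = _factor(["a", "b"], ["x", "y"])
        t = es.simper(comm, f, es.ChunkPlan(master_seed=0, nperm=0))[0]
        np.testing.assert_array_equal(t.average, 0.0)

    def test_contributions_sum_to_mean_between_group_dissimilarity(self):
        _, _, comm, factor = make_fixture(seed=31, S=25, n_samples=8,
                                          rank_richness=(8, 3, 2),
                                          group_effect=0.5)
        t = es.simper(comm, factor,
                      es.ChunkPlan(master_seed=0, nperm=0))[0]
        # dense double-loop oracle over between-group pairs
        lv = np.asarray(factor.levels, dtype=object)
        ia = np.flatnonzero(lv == t.group_a)
        ib = np.flatnonzero(lv == t.group_b)
        x = comm.abundance
        bc = [np.abs(x[u] - x[v]).sum() / (x[u] + x[v]).sum()
              for u in ia for v in ib]
        assert t.average.sum() == pytest.approx(np.mean(bc), abs=1e-12)
        assert t.overall == pytest.approx(np.mean(bc), abs=1e-12)
        # per-species oracle
        contrib = np.mean([np.abs(x[u] - x[v]) / (x[u] + x[v]).sum()
                           for u in ia for v in ib], axis=0)
        np.testing.assert_allclose(t.average, contrib, rtol=1e-12)

    def test_cumulative_ordered_and_nondecreasing(self, small_fixture):
        _, _, comm, factor = small_fixture
        t = es.simper(comm, factor, es.ChunkPlan(master_seed=0, nperm=9))[0]
        df = t.to_frame()
        assert (np.diff(df["cumulative"]) >= -1e-12).all()
        assert df["cumulative"].iloc[-1] == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(df["average"]) <= 1e-15).all()

    def test_three_groups_give_three_tables(self):
        _, _, comm, _ = make_fixture(seed=33, S=20, n_samples=9,
                                     rank_richness=(6, 2))
        f = _factor(comm.sample_ids, ["a", "a", "a", "b", "b", "b",
                                      "c", "c", "c"])
        tables = es.simper(comm, f, es.ChunkPlan(master_seed=0, nperm=0))
        assert [(t.group_a, t.group_b) for t in tables] == [
            ("a", "b"), ("a", "c"), ("b", "c")]
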