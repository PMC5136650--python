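import numpy as np
import pytest

import ecostream as es
from ecostream.dissim import CondensedDissimilarity
from tests.conftest import make_fixture


def _cond(values, labels=None, n=None):
    values = np.asarray(values, dtype=float)
    if n is None:
        # infer n from the condensed length
        m = values.size
        n = int((1 + np.sqrt(1 + 8 * m)) / 2)
    labels = labels or [f"s{i}" for i in range(n)]
    return CondensedDissimilarity(n, values, "external", labels)


class TestMantel:
    def test_identity_r_one(self):
        dx = _cond([1.0, 2.0, 4.0])
        res = es.mantel(dx, dx)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_hand_pearson_value(self):
        dx = _cond([1.0, 2.0, 4.0])
        dy = _cond([1.0, 3.0, 4.0])
        res = es.mantel(dx, dy)
        assert res.r == pytest.approx(13 / 14, abs=1e-12)

    def test_joint_relabeling_leaves_r_unchanged(self, small_fixture):
        spec, _, comm, _ = small_fixture
        env = es.gen_env(spec, n_vars=3)
        dx = es.bray_curtis(comm)
        dy = es.euclidean_scaled(env)
        dy = CondensedDissimilarity(dy.n, dy.values, dy.metric, dx.labels)
        r0 = es.mantel(dx, dy).r
        order = np.random.default_rng(4).permutation(dx.n)
        r1 = es.mantel(dx.permuted(order), dy.permuted(order)).r
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_symmetric_in_arguments_and_shift_invariant(self):
        rng = np.random.default_rng(6)
        dx = _cond(rng.random(15))
        dy = _cond(rng.random(15))
        assert es.mantel(dx, dy).r == pytest.approx(es.mantel(dy, dx).r,
                                                    abs=1e-12)
        shifted = _cond(dy.values + 3.5)
        assert es.mantel(dx, shifted).r == pytest.approx(
            es.mantel(dx, dy).r, abs=1e-12)

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        dx = _cond(rng.random(21))
        dy = _cond(rng.random(21))
        r0 = es.mantel(dx, dy, method="spearman").r
        warped = _cond(np.expm1(2 * dy.values))
        r1 = es.mantel(dx, warped, method="spearman").r
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_zero_variance_error(self):
        dx = _cond([1.0, 1.0, 1.0])
        dy = _cond([1.0, 2.0, 3.0])
        with pytest.raises(es.ValidationError, match="variance"):
            es.mantel(dx, dy)

    def test_size_mismatch_error(self):
        with pytest.raises(es.ValidationError):
            es.mantel(_cond([1.0, 2.0, 4.0]), _cond(np.arange(6.0)))

    def test_null_p_super_uniform_under_shuffled_dx(self):
        reps, nperm = 200, 99
        rejections = 0
        master = np.random.default_rng(999)
        for rep in range(reps):
            dx = _cond(master.random(45))   # n = 10, independent of dy
            dy = _cond(master.random(45))
            res = es.mantel(dx, dy,
                            plan=es.ChunkPlan(master_seed=rep, nperm=nperm))
            rejections += res.perm.p_value <= 0.05
        assert rejections / reps <= 0.08


class TestPartialMantel:
    def test_reduces_to_plain_when_controls_uncorrelated(self):
        # construct dz orthogonal to both dx and dy
        rng = np.random.default_rng(10)
        dx = _cond(rng.random(10))
        dy = _cond(rng.random(10))
        zx = (dx.values - dx.values.mean())
        zy = (dy.values - dy.values.mean())
        raw = rng.random(10)
        basis = np.vstack([np.ones(10), zx, zy])
        proj = basis.T @ np.linalg.lstsq(basis.T, raw, rcond=None)[0]
        dz = _cond(raw - proj + 1.0)
        res = es.partial_mantel(dx, dy, dz)
        assert res.r == pytest.approx(es.mantel(dx, dy).r, abs=1e-10)

    def test_self_control_zero(self):
        rng = np.random.default_rng(12)
        dx = _cond(rng.random(10))
        dy = _cond(rng.random(10))
        res = es.partial_mantel(dx, dy, dy)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(13)
        m = 15  # n = 6 samples
        dx, dy, dz = (_cond(rng.random(m)) for _ in range(3))
        res = es.partial_mantel(dx, dy, dz)

        def resid(a, b):
            b1 = np.vstack([np.ones(m), b]).T
            return a - b1 @ np.linalg.lstsq(b1, a, rcond=None)[0]

        rx = resid(dx.values, dz.values)
        ry = resid(dy.values, dz.values)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_perfect_control_degenerates_to_zero(self):
        # a control that is an affine copy of dx forces both numerator
        # and denominator to zero; the degenerate partial r is 0
        dx = _cond([1.0, 2.0, 4.0])
        dy = _cond([1.0, 3.0, 4.0])
        res = es.partial_mantel(dx, dy, dx)
        assert res.r == 0.0


class TestBioEnv:
    def _fixture(self, seed=3, n_vars=6, coupling=0.95):
        spec, _, comm, _ = make_fixture(seed=seed, S=40, n_samples=10,
                                        group_effect=1.0)
        env = es.gen_env(spec, coupled_to=comm, n_vars=n_vars,
                         coupling=coupling)
        d = es.bray_curtis(comm)
        env = es.EnvMatrix(d.labels, env.var_names, env.values)
        return d, env

    def test_perfect_singleton_match(self):
        # an env variable whose scaled distances share the ranks of the
        # community dissimilarities gives rho = 1
        y = np.array([0.0, 1.0, 3.0, 7.0])
        labels = [f"s{i}" for i in range(4)]
        sq = np.abs(y[:, None] - y[None, :])
        d = CondensedDissimilarity.from_square(labels, sq)
        env = es.EnvMatrix(labels, ["match", "noise"],
                           np.c_[y, [0.3, -1.2, 0.8, 0.1]])
        res = es.bioenv(d, env, max_size=1)
        assert res.best_subset == ("match",)
        assert res.best_rho == pytest.approx(1.0, abs=1e-12)

    def test_subset_count_is_power_set_minus_empty(self):
        d, env = self._fixture(n_vars=3)
        res = es.bioenv(d, env, max_size=3)
        assert res.n_evaluated == 7

    def test_chunked_equals_single_chunk_oracle(self):
        d, env = self._fixture(n_vars=6)
        base = es.bioenv(d, env, chunk_size=10 ** 9, workers=1)
        for chunk_size, workers in [(1, 1), (5, 2), (13, 4)]:
            got = es.bioenv(d, env, chunk_size=chunk_size, workers=workers)
            assert got.best_subset == base.best_subset
            assert got.best_rho == base.best_rho  # bitwise
            assert got.best_by_size == base.best_by_size
            assert got.n_evaluated == base.n_evaluated

    def test_worker_cap_warning(self):
        d, env = self._fixture(n_vars=3)
        with pytest.warns(UserWarning, match="not useful"):
            es.bioenv(d, env, workers=5, chunk_size=2)

    def test_constant_column_error(self):
        labels = ["a", "b", "c"]
        d = _cond([0.1, 0.5, 0.4], labels=labels)
        env = es.EnvMatrix(labels, ["flat"], [[1.0], [1.0], [1.0]])
        with pytest.raises(es.ValidationError, match="flat"):
            es.bioenv(d, env)

    def test_max_size_bounds(self):
        d, env = self._fixture(n_vars=3)
        with pytest.raises(es.ValidationError):
            es.bioenv(d, env, max_size=4)

    def test_variable_cap_requires_force(self):
        rng = np.random.default_rng(0)
        n = 6
        labels = [f"s{i}" for i in range(n)]
        d = _cond(rng.random(n * (n - 1) // 2), labels=labels)
        env = es.EnvMatrix(labels, [f"v{i}" for i in range(16)],
                           rng.normal(size=(n, 16)))
        with pytest.raises(es.ValidationError, match="force"):
            es.bioenv(d, env)
        res = es.bioenv(d, env, max_size=1, force=True)
        assert res.n_evaluated == 16
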