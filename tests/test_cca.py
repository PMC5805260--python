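"""Canonical correlation: classical solution against a numerical optimizer,
and the sparse supervised variant against its SVD limit and planted truth."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirlink import (
    SparseCCA,
    classical_cca,
    soft_threshold,
    sparse_cca,
    standardize_columns,
    supervision_sets,
)


class TestStandardize:
    def test_constant_column_raises(self):
        with pytest.raises(ValueError):
            standardize_columns(np.ones((5, 2)))

    def test_idempotent(self, rng):
        a = standardize_columns(rng.normal(size=(30, 3)))
        np.testing.assert_allclose(standardize_columns(a), a, atol=1e-12)

    def test_hand_computed(self):
        out = standardize_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])


class TestClassicalCca:
    def test_univariate_equals_abs_pearson(self, rng):
        x = rng.normal(size=(40, 1))
        y = 0.6 * x + rng.normal(size=(40, 1))
        res = classical_cca(x, y)
        r = np.corrcoef(x[:, 0], y[:, 0])[0, 1]
        assert res.d[0] == pytest.approx(abs(r), abs=1e-10)

    def test_linear_map_gives_perfect_correlations(self, rng):
        X = rng.normal(size=(50, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        res = classical_cca(X, X @ A)
        np.testing.assert_allclose(res.d, 1.0, atol=1e-8)

    def test_reconstruction_and_orderding(self, rng):
        X = rng.normal(size=(50, 3))
        Y = rng.normal(size=(50, 4))
        res = classical_cca(X, Y)
        np.testing.assert_allclose(
            res.e @ np.diag(res.d) @ res.f.T[: res.d.size], res.k, atol=1e-8
        )
        assert np.all(np.diff(res.d) <= 1e-12)
        assert np.all((res.d >= -1e-10) & (res.d <= 1 + 1e-10))

    def test_first_correlation_matches_optimizer_oracle(self, rng):
        from scipy.optimize import minimize

        X = rng.normal(size=(50, 3))
        Y = rng.normal(size=(50, 4))
        res = classical_cca(X, Y)

        def neg_corr(w):
            u, v = w[:3], w[3:]
            a, b = X @ u, Y @ v
            if a.std() == 0 or b.std() == 0:
                return 0.0
            return -abs(np.corrcoef(a, b)[0, 1])

        best = 0.0
        for s in range(8):
            w0 = np.random.default_rng(s).normal(size=7)
            opt = minimize(neg_corr, w0, method="Nelder-Mead",
                           options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12})
            best = max(best, -opt.fun)
        assert res.d[0] == pytest.approx(best, abs=1e-4)

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(ValueError):
            classical_cca(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)))


class TestSupervision:
    def test_q_frac_one_keeps_all(self, rng):
        X = rng.normal(size=(20, 5))
        Y = rng.normal(size=(20, 3))
        z = np.array([1] * 8 + [0] * 12)
        qu, qv = supervision_sets(X, Y, z, 1.0)
        assert list(qu) == list(range(5)) and list(qv) == list(range(3))

    def test_q_frac_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            supervision_sets(rng.normal(size=(10, 2)), rng.normal(size=(10, 2)),
                             np.array([1] * 5 + [0] * 5), 0.0)

    def test_matches_brute_force_ranking(self, rng):
        from scipy import stats

        X = rng.normal(size=(30, 5))
        X[:, 2] += np.array([2.0] * 12 + [0.0] * 18)
        z = np.array([1] * 12 + [0] * 18)
        qu, _ = supervision_sets(X, X, z, 0.4)  # top 2 of 5
        t = [abs(stats.ttest_ind(X[z == 1, j], X[z == 0, j]).statistic) for j in range(5)]
        expected = sorted(np.argsort(t)[-2:])
        assert list(qu) == expected


class TestSoftThreshold:
    @pytest.mark.parametrize("a,c,out", [(0.5, 1, 0.0), (2, 0.5, 1.5), (-2, 0.5, -1.5)])
    def test_examples(self, a, c, out):
        assert soft_threshold(a, c) == pytest.approx(out)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(-100, 100), st.floats(0, 100))
    def test_shrinks_toward_zero(self, a, c):
        s = soft_threshold(a, c)
        assert abs(s) <= max(abs(a) - c, 0.0) + 1e-12
        assert s * a >= 0


class TestSparseCCA:
    def test_unpenalized_limit_matches_svd(self, rng):
        # penalties = 1 with supervision off: loadings equal the leading
        # singular vectors of X'Y up to sign
        X = standardize_columns(rng.normal(size=(40, 6)))
        Y = standardize_columns(rng.normal(size=(40, 5)))
        est = SparseCCA(penalty_u=1.0, penalty_v=1.0).fit(X, Y)
        U, D, Vt = np.linalg.svd(X.T @ Y)
        u1, v1 = U[:, 0], Vt[0]
        if np.sign(u1[np.argmax(np.abs(est.u_))]) != np.sign(est.u_[np.argmax(np.abs(est.u_))]):
            u1, v1 = -u1, -v1
        np.testing.assert_allclose(est.u_, u1, atol=1e-6)
        np.testing.assert_allclose(est.v_, v1, atol=1e-6)
        assert est.u_ @ (X.T @ Y) @ est.v_ == pytest.approx(D[0], abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_monotone_ascent(self, seed):
        rng = np.random.default_rng(seed)
        X = standardize_columns(rng.normal(size=(30, 8)))
        Y = standardize_columns(rng.normal(size=(30, 7)))
        est = SparseCCA(penalty_u=0.3, penalty_v=0.5).fit(X, Y)
        path = np.array(est.objective_path_)
        scale = max(1.0, np.abs(path).max())
        assert np.all(np.diff(path) >= -1e-8 * scale)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_pair_support_recovery(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        shared = rng.normal(size=n)
        X = rng.normal(size=(n, 6))
        Y = rng.normal(size=(n, 6))
        X[:, 1] = shared + 0.1 * rng.normal(size=n)
        Y[:, 4] = shared + 0.1 * rng.normal(size=n)
        X, Y = standardize_columns(X), standardize_columns(Y)
        pair = sparse_cca(X, Y, penalty_u=0.3, penalty_v=0.3)
        assert list(pair.selected_x) == [1]
        assert list(pair.selected_y) == [4]

    def test_penalty_monotonicity_of_l1_norm(self, rng):
        X = standardize_columns(rng.normal(size=(40, 10)))
        Y = standardize_columns(rng.normal(size=(40, 9)))
        l1 = []
        for pen in (1.0, 0.7, 0.5, 0.3):
            est = SparseCCA(penalty_u=pen, penalty_v=1.0).fit(X, Y)
            l1.append(np.abs(est.u_).sum())
        assert np.all(np.diff(l1) <= 1e-8)

    def test_constraints_satisfied_and_sign_convention(self, rng):
        X = standardize_columns(rng.normal(size=(30, 12)))
        Y = standardize_columns(rng.normal(size=(30, 8)))
        z = np.array([1] * 12 + [0] * 18)
        est = SparseCCA(penalty_u=0.4, penalty_v=0.6, q_frac=0.5).fit(X, Y, z)
        eps = 1e-6
        assert np.linalg.norm(est.u_) <= 1 + eps
        assert np.linalg.norm(est.v_) <= 1 + eps
        assert np.abs(est.u_).sum() <= est.c_u_ + 1e-6
        assert np.abs(est.v_).sum() <= est.c_v_ + 1e-6
        # supervision: loadings vanish outside the admitted sets
        outside_u = np.setdiff1d(np.arange(12), est.q_u_)
        assert np.all(est.u_[outside_u] == 0)
        assert est.u_[np.argmax(np.abs(est.u_))] > 0
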