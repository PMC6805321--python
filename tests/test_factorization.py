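import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypernmf.factorization import (
    FitConfig,
    VARIANTS,
    fit,
    init_factors,
    l21_norm,
    objective,
    residual_weights,
    update_U,
    update_V,
    variant_config,
)
from hypernmf.hypergraph import build_knn_hypergraph
from hypernmf.synthetic import generate


def classical_nmf_trajectory(X, k, seed, n_iter):
    """Independent multiplicative squared-loss NMF (oracle)."""
    U, V = init_factors(X, k, seed)
    traj = [float(np.sum((X - U @ V) ** 2))]
    for _ in range(n_iter):
        U = U * (X @ V.T) / (U @ V @ V.T)
        V = V * (U.T @ X) / (U.T @ U @ V)
        traj.append(float(np.sum((X - U @ V) ** 2)))
    return np.asarray(traj), U, V


class TestL21Norm:
    def test_identity(self):
        assert l21_norm(np.eye(2)) == pytest.approx(2.0)

    def test_three_four_five(self):
        assert l21_norm(np.array([[3.0, 4.0], [0.0, 0.0]])) == pytest.approx(5.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(5, 3))
        expected = sum(
            np.sqrt(sum(M[i, j] ** 2 for j in range(3))) for i in range(5)
        )
        assert l21_norm(M) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_nonnegative_and_bounded_by_frobenius_sqrt_m(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(4, 6))
        val = l21_norm(M)
        fro = np.linalg.norm(M)
        assert 0.0 <= val <= np.sqrt(4) * fro + 1e-12
        assert val >= fro - 1e-12

    def test_rejects_1d(self):
        with pytest.raises(ValueError):
            l21_norm(np.ones(3))


class TestResidualWeights:
    def test_exact_factorization(self):
        rng = np.random.default_rng(1)
        U = rng.uniform(size=(6, 2))
        V = rng.uniform(size=(2, 4))
        d = residual_weights(U @ V, U, V, gamma=1e-8)
        np.testing.assert_allclose(d, np.full(4, 1e4), rtol=1e-6)

    def test_unit_residual_limit(self):
        X = np.zeros((3, 2))
        X[0, :] = 1.0  # each column has residual norm 1 against U V = 0
        U = np.zeros((3, 1))
        V = np.zeros((1, 2))
        d = residual_weights(X, U, V, gamma=1e-14)
        np.testing.assert_allclose(d, np.ones(2), rtol=1e-6)

    def test_column_loop_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(5, 7))
        U = rng.uniform(size=(5, 3))
        V = rng.uniform(size=(3, 7))
        gamma = 1e-6
        d = residual_weights(X, U, V, gamma)
        for j in range(7):
            rj = X[:, j] - U @ V[:, j]
            expected = 1.0 / np.sqrt(np.dot(rj, rj) + gamma)
            assert d[j] == pytest.approx(expected, rel=1e-12)

    def test_positive_and_finite(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(4, 5)) * 100
        d = residual_weights(X, np.zeros((4, 2)), np.zeros((2, 5)), 1e-8)
        assert np.all(d > 0) and np.all(np.isfinite(d))

    def test_bad_gamma(self):
        with pytest.raises(ValueError):
            residual_weights(np.ones((2, 2)), np.ones((2, 1)), np.ones((1, 2)), 0.0)


class TestObjective:
    def test_zero_factors(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(5, 4))
        val = objective(X, np.zeros((5, 2)), np.zeros((2, 4)), norm="l21")
        # with zero factors the loss is the sum of column norms of X
        assert val == pytest.approx(l21_norm(X.T), rel=1e-12)

    def test_exact_fit_is_zero(self):
        rng = np.random.default_rng(5)
        U = rng.uniform(size=(5, 2))
        V = rng.uniform(size=(2, 4))
        assert objective(U @ V, U, V, norm="l21") == pytest.approx(0.0, abs=1e-10)

    def test_composition_of_oracles(self):
        from hypernmf.hypergraph import hypergraph_regularizer

        rng = np.random.default_rng(6)
        X = rng.uniform(size=(8, 10))
        U = rng.uniform(size=(8, 3))
        V = rng.uniform(size=(3, 10))
        hg = build_knn_hypergraph(X.T, g=3)
        L = hg.laplacian
        alpha = 0.7
        val = objective(X, U, V, L, alpha, "l21")
        expected = l21_norm((X - U @ V).T) + alpha * hypergraph_regularizer(V, L)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_frobenius_norm_variant(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(6, 5))
        U = rng.uniform(size=(6, 2))
        V = rng.uniform(size=(2, 5))
        val = objective(X, U, V, norm="frobenius")
        assert val == pytest.approx(np.linalg.norm(X - U @ V) ** 2, rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            objective(np.ones((3, 3)), np.ones((3, 2)), np.ones((2, 4)))


class TestUpdates:
    def test_update_U_stationary(self):
        # at an exact factorization the multiplicative ratio is 1
        rng = np.random.default_rng(8)
        U = rng.uniform(0.1, 1.0, size=(6, 2))
        V = rng.uniform(0.1, 1.0, size=(2, 5))
        X = U @ V
        d = np.ones(5)
        np.testing.assert_allclose(update_U(X, U, V, d), U, rtol=1e-12)

    def test_update_U_classical_with_identity_weights(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(size=(6, 5))
        U = rng.uniform(0.1, 1.0, size=(6, 2))
        V = rng.uniform(0.1, 1.0, size=(2, 5))
        got = update_U(X, U, V, np.ones(5))
        classical = U * (X @ V.T) / (U @ V @ V.T)
        np.testing.assert_allclose(got, classical, rtol=1e-12)

    def test_update_U_weighted_descent(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(size=(4, 5))
        U = rng.uniform(0.1, 1.0, size=(4, 3))
        V = rng.uniform(0.1, 1.0, size=(3, 5))
        d = rng.uniform(0.5, 2.0, size=5)

        def weighted(Umat):
            R = X - Umat @ V
            return float(np.einsum("ij,ij,j->", R, R, d))

        U2 = update_U(X, U, V, d)
        assert weighted(U2) <= weighted(U) + 1e-12
        assert np.min(U2) >= 0

    def test_update_V_classical(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(size=(6, 5))
        U = rng.uniform(0.1, 1.0, size=(6, 2))
        V = rng.uniform(0.1, 1.0, size=(2, 5))
        got = update_V(X, U, V, np.ones(5), None, 0.0)
        classical = V * (U.T @ X) / (U.T @ U @ V)
        np.testing.assert_allclose(got, classical, rtol=1e-12)

    def test_update_V_stationary(self):
        rng = np.random.default_rng(12)
        U = rng.uniform(0.1, 1.0, size=(6, 2))
        V = rng.uniform(0.1, 1.0, size=(2, 5))
        X = U @ V
        np.testing.assert_allclose(
            update_V(X, U, V, np.ones(5), None, 0.0), V, rtol=1e-12
        )

    def test_zero_entries_stay_zero(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(size=(5, 4))
        U = rng.uniform(0.1, 1.0, size=(5, 2))
        U[2, 0] = 0.0
        V = rng.uniform(0.1, 1.0, size=(2, 4))
        V[1, 3] = 0.0
        d = np.ones(4)
        assert update_U(X, U, V, d)[2, 0] == 0.0
        assert update_V(X, U, V, d, None, 0.0)[1, 3] == 0.0

    def test_full_sweep_monotone_with_hypergraph(self):
        rng = np.random.default_rng(14)
        X = rng.uniform(size=(12, 15))
        hg = build_knn_hypergraph(X.T, g=3)
        E = hg.adjacency_like
        dv = hg.vertex_degrees
        L = np.diag(dv) - E
        alpha, gamma = 0.5, 1e-8
        U = rng.uniform(0.1, 1.0, size=(12, 3))
        V = rng.uniform(0.1, 1.0, size=(3, 15))
        prev = objective(X, U, V, L, alpha, "l21")
        for _ in range(50):
            d = residual_weights(X, U, V, gamma)
            U = update_U(X, U, V, d)
            V = update_V(X, U, V, d, (E, dv), alpha)
            cur = objective(X, U, V, L, alpha, "l21")
            assert cur <= prev + 1e-9 * abs(prev)
            prev = cur


class TestFitConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": 0},
            {"k": 2, "alpha": -1.0},
            {"k": 2, "norm": "l2"},
            {"k": 2, "manifold": "torus"},
            {"k": 2, "gamma": 0.0},
            {"k": 2, "max_iter": 0},
            {"k": 2, "g": 0},
            {"k": 2, "tol": -1e-3},
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            FitConfig(**kwargs)

    def test_variant_table(self):
        assert set(VARIANTS) == {
            "nmf",
            "nmf-l21",
            "gnmf",
            "hnmf",
            "rgnmf",
            "rhnmf",
        }
        cfg = variant_config("gnmf", k=3, alpha=2.0)
        assert cfg.norm == "frobenius" and cfg.manifold == "simple_graph"
        assert cfg.alpha == 2.0
        with pytest.raises(ValueError):
            variant_config("pca", k=3)


class TestFit:
    def test_noiseless_low_rank_recovery(self):
        ds = generate(
            m=30, n=20, c=2, noise_sd=0.0, outlier_fraction=0.0,
            planted_gene_count=10, seed=4,
        )
        cfg = FitConfig(
            k=2, alpha=0.0, norm="frobenius", manifold="none",
            max_iter=500, tol=0.0, seed=4,
        )
        r = fit(ds.X, cfg)
        rel = np.linalg.norm(ds.X - r.U @ r.V) / np.linalg.norm(ds.X)
        assert rel < 1e-3

    def test_matches_classical_nmf_trajectory(self):
        rng = np.random.default_rng(42)
        X = rng.uniform(0.5, 2.0, size=(20, 15))
        cfg = FitConfig(
            k=3, alpha=0.0, norm="frobenius", manifold="none",
            max_iter=10, tol=0.0, seed=7,
        )
        r = fit(X, cfg)
        traj, U, V = classical_nmf_trajectory(X, 3, 7, 10)
        np.testing.assert_allclose(r.objective_trajectory, traj, rtol=1e-10)
        np.testing.assert_allclose(r.U, U, rtol=1e-10)
        np.testing.assert_allclose(r.V, V, rtol=1e-10)

    def test_outlier_column_gets_smallest_weight(self):
        # one sample replaced by heavy-tailed noise that no non-negative
        # rank-3 model can absorb; the robust loss must down-weight it
        rng = np.random.default_rng(0)
        ds = generate(m=300, n=150, c=3, noise_sd=0.1, seed=0)
        X = ds.X.copy()
        X[:, 17] = np.minimum(np.abs(rng.standard_cauchy(300)), 50.0)
        cfg = FitConfig(
            k=3, alpha=0.0, norm="l21", manifold="none",
            max_iter=300, tol=1e-9, seed=0,
        )
        r = fit(X, cfg)
        assert int(np.argmin(r.final_residual_weights)) == 17
        # the same data under the squared loss keeps uniform weights
        rf = fit(
            X,
            FitConfig(k=3, alpha=0.0, norm="frobenius", manifold="none",
                      max_iter=50, tol=1e-9, seed=21),
        )
        np.testing.assert_array_equal(rf.final_residual_weights, np.ones(150))

    def test_nonnegativity_and_trajectory_finite(self):
        rng = np.random.default_rng(22)
        X = rng.uniform(size=(25, 18))
        r = fit(X, FitConfig(k=3, alpha=1.0, max_iter=60, tol=0.0, seed=2))
        assert np.min(r.U) >= 0 and np.min(r.V) >= 0
        assert np.all(np.isfinite(r.objective_trajectory))
        assert np.all(r.final_residual_weights > 0)

    def test_convergence_flag(self):
        ds = generate(m=30, n=20, c=2, noise_sd=0.05, planted_gene_count=10, seed=5)
        r = fit(
            ds.X,
            FitConfig(k=2, alpha=0.0, norm="frobenius", manifold="none",
                      max_iter=1000, tol=1e-8, seed=5),
        )
        assert r.converged
        assert r.iterations_run < 1000

    def test_accepts_expression_matrix_object(self):
        from hypernmf.io import ExpressionMatrix

        ds = generate(m=10, n=8, c=2, planted_gene_count=5, seed=0)
        em = ExpressionMatrix(
            ds.X, [f"g{i}" for i in range(10)], [f"s{j}" for j in range(8)]
        )
        r = fit(em, FitConfig(k=2, alpha=0.0, manifold="none", max_iter=5, seed=0))
        assert r.U.shape == (10, 2)

    def test_negative_input_rejected(self):
        X = np.ones((5, 5))
        X[0, 0] = -1.0
        with pytest.raises(ValueError):
            fit(X, FitConfig(k=2))

    def test_nan_input_rejected(self):
        X = np.ones((5, 5))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit(X, FitConfig(k=2))

    def test_rank_too_large_rejected(self):
        with pytest.raises(ValueError):
            fit(np.ones((4, 6)), FitConfig(k=5))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(30)
        X = rng.uniform(size=(15, 12))
        cfg = FitConfig(k=2, alpha=0.5, max_iter=40, tol=0.0, seed=9)
        r1, r2 = fit(X, cfg), fit(X, cfg)
        np.testing.assert_array_equal(r1.U, r2.U)
        np.testing.assert_array_equal(r1.V, r2.V)


class TestReductions:
    def hnmf_oracle(self, X, k, seed, alpha, g, n_iter):
        """Independent squared-loss + hypergraph-penalty update (oracle)."""
        hg = build_knn_hypergraph(X.T, g=g)
        E = hg.adjacency_like
        dv = hg.vertex_degrees
        U, V = init_factors(X, k, seed)
        for _ in range(n_iter):
            U = U * (X @ V.T) / (U @ V @ V.T)
            V = V * (U.T @ X + alpha * V @ E) / (U.T @ U @ V + alpha * V * dv)
        return U, V

    def test_frobenius_hypergraph_matches_independent_update(self):
        rng = np.random.default_rng(50)
        X = rng.uniform(0.5, 2.0, size=(18, 14))
        cfg = FitConfig(
            k=3, alpha=0.8, norm="frobenius", manifold="hypergraph",
            g=4, max_iter=10, tol=0.0, seed=11,
        )
        r = fit(X, cfg)
        U, V = self.hnmf_oracle(X, 3, 11, 0.8, 4, 10)
        np.testing.assert_allclose(r.U, U, rtol=1e-10)
        np.testing.assert_allclose(r.V, V, rtol=1e-10)

    def test_scale_consistency(self):
        # scaling X by c (with gamma scaled by c^2) scales the robust-loss
        # dynamics exactly, so relative reconstruction error is unchanged
        ds = generate(m=40, n=30, c=2, noise_sd=0.1, seed=13)
        c = 7.0
        cfg1 = FitConfig(k=2, alpha=1.0, norm="l21", manifold="hypergraph",
                         max_iter=80, tol=0.0, gamma=1e-8, seed=3)
        cfg2 = FitConfig(k=2, alpha=1.0, norm="l21", manifold="hypergraph",
                         max_iter=80, tol=0.0, gamma=1e-8 * c * c, seed=3)
        r1 = fit(ds.X, cfg1)
        r2 = fit(c * ds.X, cfg2)
        e1 = np.linalg.norm(ds.X - r1.U @ r1.V) / np.linalg.norm(ds.X)
        e2 = np.linalg.norm(c * ds.X - r2.U @ r2.V) / np.linalg.norm(c * ds.X)
        assert e1 == pytest.approx(e2, abs=1e-6)


def test_per_iteration_cost_scales_linearly_in_n():
    # doubling n at fixed m, k should at most ~double per-sweep time
    # (O(mnk) updates); allow a 3x slack on the factor-of-2 prediction
    import time

    rng = np.random.default_rng(60)
    m, k = 200, 5

    def sweep_time(n, repeats=3, sweeps=30):
        X = rng.uniform(size=(m, n))
        U = rng.uniform(size=(m, k))
        V = rng.uniform(size=(k, n))
        d = np.ones(n)
        best = np.inf
        for _ in range(repeats):
            t0 = time.perf_counter()
            Uc, Vc = U.copy(), V.copy()
            for _ in range(sweeps):
                Uc = update_U(X, Uc, Vc, d)
                Vc = update_V(X, Uc, Vc, d, None, 0.0)
            best = min(best, time.perf_counter() - t0)
        return best

    t1 = sweep_time(150)
    t2 = sweep_time(300)
    assert t2 <= 6.0 * max(t1, 1e-9)
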