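"""Core solver: initialization, the two convex subproblems, and fit()."""

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from sparsesig import (
    fit,
    initialize_signatures,
    lambda_max,
    load_preset,
    update_exposures,
    update_signatures,
)
from sparsesig.factorization import ExposureSet, _solve_beta

from conftest import (
    assert_trace_non_increasing,
    projected_gradient_lasso,
    random_signatures,
)


class TestInitializeSignatures:
    def test_deterministic_given_seed(self, rng):
        M = rng.poisson(50, size=(8, 96)).astype(float)
        a = initialize_signatures(M, 3, restarts=3, seed=7)
        b = initialize_signatures(M, 3, restarts=3, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_rows_sum_to_one(self, rng):
        M = rng.poisson(50, size=(8, 96)).astype(float)
        beta = initialize_signatures(M, 4, restarts=2, seed=0)
        np.testing.assert_allclose(beta.sum(axis=1), 1.0, atol=1e-9)

    def test_rank_one_recovery(self, rng):
        profile = rng.dirichlet(np.ones(96))
        M = np.outer(rng.uniform(500, 2000, size=6), profile)
        beta = initialize_signatures(M, 1, restarts=3, seed=0)
        cos = float(beta[0] @ profile / (np.linalg.norm(beta[0]) * np.linalg.norm(profile)))
        assert cos >= 0.999

    def test_k_larger_than_n_errors(self, rng):
        M = rng.poisson(5, size=(3, 96)).astype(float)
        with pytest.raises(ValueError, match="exceeds"):
            initialize_signatures(M, 4)


class TestUpdateExposures:
    def test_exact_background_inverse(self, germline):
        M = 1000.0 * germline.probs[None, :]
        exp = update_exposures(M, germline, np.zeros((0, 96)))
        assert exp.alpha0[0] == pytest.approx(1000.0, rel=1e-8)
        assert exp.alpha.shape == (1, 0)

    def test_recovers_interior_least_squares(self, rng):
        """With strictly positive truth the NNLS solution is the LS solution."""
        beta = random_signatures(rng, 3)
        alpha_true = rng.uniform(100, 500, size=(5, 3))
        M = alpha_true @ beta
        exp = update_exposures(M, None, beta)
        np.testing.assert_allclose(exp.alpha, alpha_true, rtol=1e-6, atol=1e-4)

    def test_zero_matrix_gives_zero_exposures(self, germline, rng):
        beta = random_signatures(rng, 2)
        exp = update_exposures(np.zeros((3, 96)), germline, beta)
        np.testing.assert_allclose(exp.alpha0, 0.0, atol=1e-12)
        np.testing.assert_allclose(exp.alpha, 0.0, atol=1e-12)

    def test_cd_matches_active_set(self, rng, germline):
        """The vectorized CD path and the per-sample active-set path agree."""
        beta = random_signatures(rng, 3)
        M = rng.poisson(40, size=(6, 96)).astype(float)
        cd = update_exposures(M, germline, beta, solver="cd")
        ast = update_exposures(M, germline, beta, solver="active-set")
        np.testing.assert_allclose(cd.alpha, ast.alpha, rtol=1e-5, atol=1e-4)
        np.testing.assert_allclose(cd.alpha0, ast.alpha0, rtol=1e-5, atol=1e-4)

    def test_dimension_mismatch_errors(self, germline):
        with pytest.raises(ValueError, match="match"):
            update_exposures(np.ones((2, 50)), germline, np.ones((1, 96)) / 96)


class TestLambdaMax:
    def test_perfect_background_fit_gives_zero(self, germline):
        M = 500.0 * germline.probs[None, :]
        exp = ExposureSet(alpha0=np.array([500.0]), alpha=np.array([[0.0]]))
        # residual R = 0, but alpha must be nonzero for a meaningful bound
        exp = ExposureSet(alpha0=np.array([500.0]), alpha=np.array([[1.0]]))
        assert lambda_max(M, germline, exp) == pytest.approx(0.0, abs=1e-8)

    def test_homogeneous_of_degree_one(self, rng, germline):
        beta = random_signatures(rng, 2)
        M = rng.poisson(30, size=(4, 96)).astype(float)
        exp = update_exposures(M, germline, beta)
        lam1 = lambda_max(M, germline, exp)
        exp2 = ExposureSet(alpha0=exp.alpha0 * 2, alpha=exp.alpha)
        lam2 = lambda_max(2 * M, germline, exp2)
        assert lam2 == pytest.approx(2 * lam1, rel=1e-9)

    def test_zero_exposures_flagged_as_zero(self, rng):
        M = rng.poisson(10, size=(3, 96)).astype(float)
        exp = ExposureSet(alpha0=None, alpha=np.zeros((3, 2)))
        assert lambda_max(M, None, exp) == 0.0

    def test_agrees_with_grid_search_oracle(self, rng):
        """lambda_max is where an independent solver first returns beta = 0."""
        alpha = rng.uniform(0.5, 2.0, size=(2, 2))
        R = rng.uniform(0, 5.0, size=(2, 3))
        exp = ExposureSet(alpha0=None, alpha=alpha)
        lam = lambda_max(R, None, exp)
        grid = np.linspace(0.5 * lam, 1.5 * lam, 41)
        zero_at = []
        for penalty in grid:
            beta = projected_gradient_lasso(R, alpha, np.ones((2, 3)), penalty)
            zero_at.append(np.abs(beta).max() < 1e-9)
        first_zero = grid[int(np.argmax(zero_at))]
        assert first_zero == pytest.approx(lam, rel=0.05)
        assert all(zero_at[i] for i in range(len(grid)) if grid[i] >= lam * 1.001)


class TestUpdateSignatures:
    def test_zero_penalty_equals_nnls(self, rng):
        """lambda = 0 reduces to column-wise non-negative least squares."""
        alpha = rng.uniform(0, 3, size=(5, 2))
        R = rng.uniform(0, 10, size=(5, 96))
        exp = ExposureSet(alpha0=None, alpha=alpha)
        beta = update_signatures(R, None, exp, np.zeros((2, 96)), 0.0)
        oracle = np.column_stack([scipy_nnls(alpha, R[:, j])[0] for j in range(96)])
        np.testing.assert_allclose(beta, oracle, atol=1e-5)

    def test_penalty_at_lambda_max_zeroes_beta(self, rng):
        """KKT: at the maximal penalty the minimizer is the zero matrix."""
        for trial in range(5):
            alpha = rng.uniform(0.1, 2, size=(4, 2))
            R = rng.uniform(0, 8, size=(4, 6))
            exp = ExposureSet(alpha0=None, alpha=alpha)
            beta = _solve_beta(R, alpha, rng.uniform(0, 1, size=(2, 6)),
                               lambda_max(R, None, exp))
            np.testing.assert_allclose(beta, 0.0, atol=1e-6)

    def test_matches_projected_gradient_oracle(self, rng):
        for trial in range(10):
            n, k, m = 4, 2, 6
            alpha = rng.uniform(0, 2, size=(n, k))
            R = rng.uniform(0, 5, size=(n, m))
            exp = ExposureSet(alpha0=None, alpha=alpha)
            penalty = 0.05 * lambda_max(R, None, exp)
            ours = _solve_beta(R, alpha, np.full((k, m), 0.5), penalty)
            oracle = projected_gradient_lasso(R, alpha, np.full((k, m), 0.5), penalty)
            np.testing.assert_allclose(ours, oracle, atol=1e-5)


class TestFit:
    def test_noiseless_parameter_recovery(self, rng, germline):
        beta_true = random_signatures(rng, 3)
        # presence pattern: exposure variation across samples is what makes
        # signatures identifiable next to the dense always-on background
        alpha_true = rng.uniform(200, 2000, size=(20, 3)) * (rng.random((20, 3)) < 0.6)
        alpha0_true = rng.uniform(500, 3000, size=20)
        M = alpha_true @ beta_true + np.outer(alpha0_true, germline.probs)
        res = fit(M, germline, 3, 0.0, seed=0, iterations=200, tol=1e-10)
        assert res.mse < 1e-6 * M.mean() ** 2
        cos = np.array([
            max(
                beta_true[i] @ res.signatures[j]
                / (np.linalg.norm(beta_true[i]) * np.linalg.norm(res.signatures[j]))
                for j in range(3)
            )
            for i in range(3)
        ])
        assert np.all(cos > 0.99)

    def test_objective_trace_non_increasing(self, rng, germline):
        for seed in range(5):
            M = rng.poisson(30, size=(8, 96)).astype(float)
            res = fit(M, germline, 2, 0.1, iterations=10, restarts=2, seed=seed)
            assert_trace_non_increasing(res.objective_trace)

    def test_k_zero_is_background_only_nnls(self, germline, rng):
        M = rng.poisson(20, size=(4, 96)).astype(float)
        res = fit(M, germline, 0, 0.0)
        direct = update_exposures(M, germline, np.zeros((0, 96)), solver="active-set")
        np.testing.assert_allclose(res.exposures.alpha0, direct.alpha0, rtol=1e-6, atol=1e-6)
        assert res.signatures.shape == (0, 96)

    def test_k_zero_without_background_errors(self, rng):
        with pytest.raises(ValueError, match="background"):
            fit(np.ones((2, 96)), None, 0, 0.0)

    def test_output_rows_normalized_and_product_invariant(self, rng, germline):
        M = rng.poisson(60, size=(10, 96)).astype(float)
        res = fit(M, germline, 2, 0.05, iterations=8, restarts=2, seed=3)
        nz = res.signatures.sum(axis=1) > 0
        np.testing.assert_allclose(res.signatures[nz].sum(axis=1), 1.0, atol=1e-9)
        # renormalization must not change the reconstruction alpha @ beta
        rec = res.reconstruction()
        assert res.mse == pytest.approx(((M - rec) ** 2).mean(), rel=1e-9)

    def test_no_background_zero_lambda_reaches_nmf_stationary_point(self, rng):
        """Plain NMF limit: multiplicative updates from the same start agree."""
        beta_true = rng.dirichlet(np.ones(8), size=2)
        W = rng.uniform(0.5, 2.0, size=(6, 2))
        M = W @ beta_true
        beta_init = rng.dirichlet(np.ones(8), size=2)
        res = fit(M, None, 2, 0.0, iterations=400, beta_init=beta_init)
        # reference: multiplicative-update NMF from the same H init
        H = beta_init.copy()
        Wm = np.maximum(update_exposures(M, None, H).alpha, 1e-12)
        for _ in range(20000):
            H *= (Wm.T @ M) / np.maximum(Wm.T @ Wm @ H, 1e-300)
            Wm *= (M @ H.T) / np.maximum(Wm @ H @ H.T, 1e-300)
        obj_mu = ((M - Wm @ H) ** 2).sum()
        obj_fit = res.objective_trace[-1]
        assert obj_fit <= obj_mu + 1e-6
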