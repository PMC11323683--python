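"""Θ-IPOD: hat matrix, γ-iteration, BIC*, and λ selection."""

import numpy as np
import pytest

from spatialipod import (
    RegressionProblem,
    bic_star,
    hat_matrix,
    ipod_fit,
    ipod_select,
    lambda_max,
)
from spatialipod.ipod import DEGENERATE_BIC, refit_gamma


class TestHatMatrix:
    def test_projection_onto_constant(self):
        dec = hat_matrix(np.ones((4, 1)))
        np.testing.assert_allclose(dec.H, np.full((4, 4), 0.25), atol=1e-12)
        np.testing.assert_allclose(dec.h, 0.25)

    def test_square_design_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            hat_matrix(np.eye(5))

    def test_projector_properties(self, rng):
        X = rng.normal(size=(20, 3))
        dec = hat_matrix(X)
        H = dec.H
        assert np.trace(H) == pytest.approx(3.0, abs=1e-10)
        assert np.max(np.abs(H @ H - H)) < 1e-8  # idempotent
        np.testing.assert_allclose(H, H.T, atol=1e-12)
        assert np.all((dec.h >= 0) & (dec.h <= 1))
        assert dec.m == 17

    def test_rank_deficient_names_columns(self, rng):
        X = rng.normal(size=(15, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(ValueError, match="rank deficient"):
            hat_matrix(X)


class TestIpodFit:
    def test_exact_fit_gives_zero_gamma(self, rng):
        X = rng.normal(size=(25, 2))
        beta = np.array([2.0, -1.0])
        prob = RegressionProblem(X, X @ beta)
        for rule in ("soft", "hard"):
            fit = ipod_fit(prob, lam=0.5, rule=rule)
            np.testing.assert_allclose(fit.gamma_hat, 0.0, atol=1e-12)
            np.testing.assert_allclose(fit.beta_hat, beta, atol=1e-8)

    def test_large_lambda_reduces_to_ols(self, small_problem):
        prob, _ = small_problem
        dec = hat_matrix(prob.X)
        lam = lambda_max(dec, prob.y) * 1.0001
        fit = ipod_fit(prob, lam=lam, rule="soft", dec=dec)
        assert fit.n_outliers == 0
        ols = np.linalg.lstsq(prob.X, prob.y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta_hat, ols, atol=1e-10)

    def test_single_shift_flagged(self, rng):
        """One gross shift: the flagged index matches the exhaustive
        single-shift search for mid-range λ."""
        X = rng.uniform(-5, 5, size=(10, 1))
        y = (2.0 * X[:, 0]) + 0.1 * rng.normal(size=10)
        shifted = 6
        y[shifted] += 8.0
        prob = RegressionProblem(X, y)
        # exhaustive single-shift oracle: best index by deleted-row RSS
        rss = [refit_gamma(prob, np.array([i]))[2] for i in range(10)]
        assert int(np.argmin(rss)) == shifted
        dec = hat_matrix(X)
        lmax = lambda_max(dec, y)
        for frac in (0.3, 0.5, 0.7):
            fit = ipod_fit(prob, lam=frac * lmax, rule="hard", dec=dec)
            assert fit.outlier_idx.tolist() == [shifted]

    def test_fixed_point_reevaluates(self, rng):
        from spatialipod.thresholding import apply_threshold

        X = rng.normal(size=(40, 2))
        y = X @ np.array([1.0, 1.0]) + rng.normal(size=40)
        y[3] += 10
        prob = RegressionProblem(X, y)
        dec = hat_matrix(X)
        for rule in ("soft", "hard"):
            fit = ipod_fit(prob, lam=2.0, rule=rule, dec=dec)
            assert fit.converged
            g = fit.gamma_iterate
            working = y + dec.project(g - y)
            lam_vec = 2.0 * np.sqrt(1 - dec.h)
            again = apply_threshold(working, lam_vec, rule)
            np.testing.assert_allclose(again, g, atol=1e-6)

    def test_soft_objective_monotone(self, rng):
        X = rng.normal(size=(50, 3))
        y = X @ np.ones(3) + rng.normal(size=50)
        y[:5] += 8
        fit = ipod_fit(
            RegressionProblem(X, y), lam=1.5, rule="soft", track_objective=True
        )
        diffs = np.diff(fit.objective_path)
        assert np.all(diffs <= 1e-10)

    def test_lambda_zero_interpolates(self, rng):
        """At λ = 0 the fixed point satisfies (I − H)(y − γ) = 0."""
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        prob = RegressionProblem(X, y)
        dec = hat_matrix(X)
        fit = ipod_fit(prob, lam=0.0, rule="soft", dec=dec)
        resid = dec.resid_project(y - fit.gamma_iterate)
        np.testing.assert_allclose(resid, 0.0, atol=1e-8)

    def test_nonconvergence_flagged(self, rng):
        X = rng.normal(size=(30, 2))
        y = X @ np.ones(2) + rng.normal(size=30)
        y[:4] += 8
        fit = ipod_fit(RegressionProblem(X, y), lam=1.0, rule="soft", max_iter=1)
        assert not fit.converged


class TestBicStar:
    @pytest.fixture
    def intercept_fixture(self):
        X = np.ones((6, 1))
        y = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 6.0])
        return hat_matrix(X), y

    def test_hand_computed_value(self, intercept_fixture):
        dec, y = intercept_fixture
        # γ̂ = 0: RSS = Σ(y − ȳ)² = 30, m = 5, k = 1
        val = bic_star(dec, y, np.zeros(6))
        assert val == pytest.approx(5 * np.log(6.0) + (np.log(5.0) + 1.0))

    def test_degenerate_sentinel(self, intercept_fixture):
        dec, y = intercept_fixture
        gamma = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 6.0])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert bic_star(dec, y, gamma) == DEGENERATE_BIC

    def test_zero_gamma_uses_ols_rss(self, small_problem):
        prob, _ = small_problem
        dec = hat_matrix(prob.X)
        resid = dec.resid_project(prob.y)
        rss = float(resid @ resid)
        m = dec.m
        expected = m * np.log(rss / m) + 1 * (np.log(m) + 1)
        assert bic_star(dec, prob.y, np.zeros(prob.n)) == pytest.approx(expected)


class TestIpodSelect:
    def test_clean_data_rarely_swamps(self):
        """On clean data the BIC* optimum flags nothing in ≥95% of replicates."""
        master = np.random.default_rng(11)
        clean = 0
        reps = 200
        for _ in range(reps):
            rng = np.random.default_rng(master.integers(2**31))
            X = rng.uniform(-5, 5, size=(100, 2))
            y = X @ np.ones(2) + 0.3 * rng.normal(size=100)
            fit = ipod_select(RegressionProblem(X, y), rule="soft", n_lambda=50)
            clean += fit.n_outliers == 0
        assert clean / reps >= 0.95

    def test_single_outlier_matches_single_shift_search(self, rng):
        """One gross shift: selection flags exactly the index the exhaustive
        single-shift search (deleted-row RSS argmin) identifies."""
        X = rng.uniform(-5, 5, size=(10, 1))
        y = 2.0 * X[:, 0] + 0.1 * rng.normal(size=10)
        y[4] += 8.0
        prob = RegressionProblem(X, y)
        rss = [refit_gamma(prob, np.array([i]))[2] for i in range(10)]
        assert int(np.argmin(rss)) == 4
        for rule in ("hard", "soft"):
            fit = ipod_select(prob, rule=rule)
            assert fit.outlier_idx.tolist() == [4]

    def test_two_point_grid_clean(self, small_problem):
        prob, beta = small_problem
        fit = ipod_select(prob, rule="soft", n_lambda=2)
        assert fit.n_outliers == 0
        np.testing.assert_allclose(fit.beta_hat, beta, atol=0.1)

    def test_selection_metadata(self, small_problem):
        prob, _ = small_problem
        fit = ipod_select(prob, rule="soft", n_lambda=25)
        assert fit.lambda_grid.shape == (25,)
        assert fit.bic_path.shape == (25,)
        assert fit.lambda_grid[0] == pytest.approx(
            lambda_max(hat_matrix(prob.X), prob.y)
        )
        assert fit.lambda_grid[-1] == 0.0

    def test_n_lambda_validation(self, small_problem):
        prob, _ = small_problem
        with pytest.raises(ValueError, match="at least 2"):
            ipod_select(prob, n_lambda=1)
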