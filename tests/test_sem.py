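"""SEM machinery: weights, GLS transform, MLE, ψ functions, RoMLE scoring."""

import numpy as np
import pytest

from spatialipod import (
    PSI_FUNCTIONS,
    Scenario,
    SpatialWeights,
    admissible_interval,
    gls_transform,
    make_dataset,
    make_weights,
    omega_inv_sqrt,
    psi,
    romle_fit,
    row_standardize,
    sem_mle,
    transform_matrix,
)
from spatialipod.sem import psi_deriv_moment, psi_squared_moment


class TestRowStandardize:
    def test_already_standard(self):
        w = row_standardize(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(w.W, [[0, 1], [1, 0]])
        assert w.row_standardized

    def test_normalization_and_isolated(self):
        W = np.array([[0.0, 2.0, 2.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="isolated"):
            w = row_standardize(W)
        np.testing.assert_allclose(
            w.W, [[0, 0.5, 0.5], [1, 0, 0], [0, 0, 0]]
        )
        assert w.isolated.tolist() == [2]

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            row_standardize(np.array([[0.0, -1.0], [1.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="zero diagonal"):
            SpatialWeights(W=np.array([[0.5, 0.5], [0.5, 0.0]]))


class TestGlsTransform:
    def test_mu_zero_is_identity(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        w = make_weights(5, 0.5)
        Xt, yt = gls_transform(X, y, w, mu=0.0)
        np.testing.assert_allclose(Xt, X)
        np.testing.assert_allclose(yt, y)

    def test_two_by_two_hand_arithmetic(self):
        w = row_standardize(np.array([[0.0, 1.0], [1.0, 0.0]]))
        Xt, yt = gls_transform(np.ones((2, 1)), np.array([2.0, 4.0]), w, mu=0.5)
        np.testing.assert_allclose(yt, [0.0, 3.0])
        np.testing.assert_allclose(Xt, [[0.5], [0.5]])

    def test_mu_one_singular(self):
        w = row_standardize(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="singular"):
            gls_transform(np.ones((2, 1)), np.zeros(2), w, mu=1.0)


def test_admissible_interval_row_standardized():
    w = make_weights(20, 0.5)
    lo, hi = admissible_interval(w)
    assert -1.0 <= lo < 0 < hi <= 1.0
    ev = w.eigenvalues()
    assert hi == pytest.approx(min(1.0, 1.0 / ev[-1]))


def test_omega_inverse_sqrt_reconstruction():
    """S·Ω·S = I for the symmetric inverse square root, Ω = (BᵀB)⁻¹."""
    w = make_weights(25, 0.5)
    for mu in (0.3, 0.7, -0.4):
        B = transform_matrix(w, mu)
        omega = np.linalg.inv(B.T @ B)
        S = omega_inv_sqrt(w, mu)
        np.testing.assert_allclose(S, S.T, atol=1e-10)
        assert np.linalg.norm(S @ omega @ S - np.eye(25)) < 1e-8


class TestPsi:
    @pytest.mark.parametrize("kind", ["cauchy", "welsch", "insha", "logistic"])
    def test_odd_and_zero_at_origin(self, kind, rng):
        assert psi(0.0, kind) == 0.0
        r = rng.normal(size=50) * 5
        np.testing.assert_allclose(psi(-r, kind), -psi(r, kind), atol=1e-12)

    @pytest.mark.parametrize("kind", ["cauchy", "welsch", "insha", "logistic"])
    def test_bounded(self, kind):
        grid = np.linspace(-100, 100, 20001)
        vals = psi(grid, kind)
        assert np.all(np.isfinite(vals))
        # bounded: sup on |r| ≤ 100 is attained well inside, not at the edge
        assert np.abs(vals[0]) < np.max(np.abs(vals)) + 1e-12
        assert np.max(np.abs(vals)) < 10

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown psi"):
            psi(1.0, "tukey-made-up")

    @pytest.mark.parametrize("kind", ["cauchy", "welsch", "insha", "logistic"])
    def test_reference_moments(self, kind):
        K = psi_squared_moment(kind)
        D1 = psi_deriv_moment(kind)
        assert 0 < K <= 1.0  # ψ(r) shrinks r, so E[ψ²] ≤ E[Z²] = 1
        assert 0 < D1 <= 1.0

    def test_identity_moments(self):
        assert psi_squared_moment("none") == pytest.approx(1.0)
        assert psi_deriv_moment("none") == pytest.approx(1.0)


class TestSemMle:
    def test_zero_weights_reduces_to_ols(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.ones(3) + rng.normal(size=40)
        w = SpatialWeights(W=np.zeros((40, 40)))
        est = sem_mle(X, y, w)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(est.beta_hat, ols, atol=1e-10)

    def test_recovers_null_mu(self):
        mus = []
        for seed in range(15):
            sc = Scenario(n=200, p=3, n_outliers=0, mu=0.0, seed=seed)
            d = make_dataset(sc)
            mus.append(sem_mle(d.X, d.y, d.w).mu_hat)
        assert abs(float(np.mean(mus))) < 0.05

    def test_profile_prefers_truth_over_zero(self):
        from spatialipod.sem import _profile_negloglik

        sc = Scenario(n=200, p=3, n_outliers=0, mu=0.7, seed=5)
        d = make_dataset(sc)
        est = sem_mle(d.X, d.y, d.w)
        ev = d.w.eigenvalues()
        nll_hat = _profile_negloglik(est.mu_hat, d.w, d.X, d.y, ev)
        nll_zero = _profile_negloglik(0.0, d.w, d.X, d.y, ev)
        assert nll_hat <= nll_zero


class TestRomle:
    def test_identity_psi_matches_mle(self):
        sc = Scenario(n=150, p=3, n_outliers=0, seed=2)
        d = make_dataset(sc)
        mle = sem_mle(d.X, d.y, d.w)
        rom = romle_fit(d.X, d.y, d.w, psi_kind="none", tol=1e-10)
        assert rom.converged
        np.testing.assert_allclose(rom.beta_hat, mle.beta_hat, atol=1e-4)
        assert rom.mu_hat == pytest.approx(mle.mu_hat, abs=1e-3)

    @pytest.mark.parametrize("kind", ["cauchy", "welsch"])
    def test_clean_recovery_small(self, kind):
        """Robust scoring recovers μ on clean SEM data (small-n check)."""
        mus = []
        for seed in range(10):
            sc = Scenario(n=200, p=3, n_outliers=0, seed=seed)
            d = make_dataset(sc)
            est = romle_fit(d.X, d.y, d.w, psi_kind=kind)
            mus.append(est.mu_hat)
        assert float(np.mean(mus)) == pytest.approx(0.7, abs=0.08)

    def test_invalid_init(self, rng):
        w = make_weights(20, 0.5)
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="init"):
            romle_fit(X, rng.normal(size=20), w, init="bad")


def test_gls_shrinks_beta_variance():
    """GLS on the true μ beats naive OLS in β variance on clean SEM data."""
    betas_ols, betas_gls = [], []
    w = make_weights(100, 0.5)
    for seed in range(100):
        sc = Scenario(n=100, p=2, n_outliers=0, seed=seed)
        d = make_dataset(sc, w=w)
        betas_ols.append(np.linalg.lstsq(d.X, d.y, rcond=None)[0])
        Xt, yt = gls_transform(d.X, d.y, w, 0.7)
        betas_gls.append(np.linalg.lstsq(Xt, yt, rcond=None)[0])
    var_ols = np.var(np.array(betas_ols), axis=0).sum()
    var_gls = np.var(np.array(betas_gls), axis=0).sum()
    assert var_gls < var_ols
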