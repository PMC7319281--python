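"""Synthetic-data generators: moment structure and reproducibility."""

import numpy as np
import pytest

from flute.basis import BasisSpec
from flute.functional import residual_coeffs
from flute.simulate import (
    SimulationDesign,
    beta_surface_coeffs,
    beta_vector_coeffs,
    error_scales,
    gen_functional_data,
    gen_scalar_data,
    ma_covariance,
    ma_loadings,
)

F5 = BasisSpec("fourier", 5)
F11 = BasisSpec("fourier", 11)


class TestMALoadings:
    def test_degenerate_ma_is_iid_standard_normal(self, rng):
        xi = ma_loadings(5000, 4, 1, np.array([1.0]), rng)
        cov = np.cov(xi.T)
        se = 3.0 / np.sqrt(5000)
        assert np.abs(cov - np.eye(4)).max() < 3 * se

    def test_lag_one_covariance_closed_form(self, rng):
        a, b = 0.6, 0.3
        n = 20000
        xi = ma_loadings(n, 6, 2, np.array([a, b]), rng)
        cov = np.cov(xi.T)
        # var = a^2 + b^2, lag-1 = a*b; 3 SE Monte-Carlo tolerance
        se = 3.0 * (a * a + b * b) / np.sqrt(n)
        assert np.abs(np.diag(cov) - (a * a + b * b)).max() < 3 * se
        assert np.abs(np.diag(cov, 1) - a * b).max() < 3 * se

    def test_lags_beyond_range_uncorrelated(self, rng):
        T = 3
        rho = rng.uniform(0, 1, T)
        xi = ma_loadings(20000, 8, T, rho, rng)
        cov = np.cov(xi.T)
        for lag in range(T, 8):
            assert np.abs(np.diag(cov, lag)).max() < 0.05

    def test_empirical_covariance_matches_banded_closed_form(self, rng):
        rho = rng.uniform(0, 1, 4)
        xi = ma_loadings(20000, 7, 4, rho, rng)
        target = ma_covariance(7, rho)
        assert np.abs(np.cov(xi.T) - target).max() < 3 * 3.0 * target[0, 0] / np.sqrt(20000)

    def test_implied_covariance_is_psd_and_banded(self, rng):
        rho = rng.uniform(0, 1, 3)
        cov = ma_covariance(9, rho)
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-10
        assert np.all(cov[np.abs(np.subtract.outer(range(9), range(9))) >= 3] == 0)


class TestBetaSurface:
    def test_zero_amplitude_gives_zero_surface(self):
        assert np.array_equal(beta_surface_coeffs(0.0, F5, F5).coeffs, np.zeros((5, 5)))

    def test_separable_surface_is_rank_one(self):
        coeffs = beta_surface_coeffs(0.3, F11, F5).coeffs
        s = np.linalg.svd(coeffs, compute_uv=False)
        assert s[1] < 1e-8 * s[0]

    def test_amplitude_is_linear(self):
        one = beta_surface_coeffs(0.2, F5, F5).coeffs
        two = beta_surface_coeffs(0.4, F5, F5).coeffs
        assert np.allclose(two, 2.0 * one)

    def test_normalized_surface_has_requested_norm(self):
        # squared L2 norm of the surface == betasq under normalize=True;
        # the K=L=25 truncation carries essentially all of the smooth shape
        big = BasisSpec("fourier", 25)
        coeffs = beta_surface_coeffs(0.37, big, big, normalize=True).coeffs
        # truncation can only lose norm, and the smooth shape loses < 1%
        assert np.sum(coeffs**2) <= 0.37 + 1e-12
        assert np.sum(coeffs**2) == pytest.approx(0.37, rel=1e-2)

    def test_quadrature_against_direct_2d_integration(self):
        # oracle: 2-D trapezoid of beta(t,s) eta_l(t) phi_k(s) on a 401^2 grid
        from flute.basis import evaluate_basis

        g = np.linspace(0, 1, 401)
        surf = 0.25 * np.exp((g[:, None] ** 2 + g[None, :] ** 2) / 2.0)
        design = evaluate_basis(F5, g)
        oracle = np.empty((5, 5))
        for l in range(5):
            for k in range(5):
                inner = np.trapezoid(surf * design[None, :, k].squeeze(), g, axis=1)
                oracle[l, k] = np.trapezoid(inner * design[:, l], g)
        assert np.abs(beta_surface_coeffs(0.25, F5, F5).coeffs - oracle).max() < 1e-5


class TestGenerators:
    def test_reproducible_bitwise(self):
        d = SimulationDesign(n=20, K=5, L=5, betasq=0.1, reps=1)
        X1, Y1, _ = gen_functional_data(d, np.random.default_rng(42))
        X2, Y2, _ = gen_functional_data(d, np.random.default_rng(42))
        assert np.array_equal(X1.coeffs, X2.coeffs)
        assert np.array_equal(Y1.coeffs, Y2.coeffs)

    def test_true_surface_residuals_are_pure_noise(self, rng):
        d = SimulationDesign(n=50, K=5, L=5, betasq=0.3)
        X, Y, beta = gen_functional_data(d, rng)
        R = residual_coeffs(Y, X, beta)
        # removing the true signal leaves iid N(0, I) loadings
        assert np.var(R.coeffs) == pytest.approx(1.0, rel=0.2)
        assert abs(np.corrcoef(X.coeffs[:, 0], R.coeffs[:, 0])[0, 1]) < 0.35

    def test_heteroscedastic_error_variances(self, rng):
        d = SimulationDesign(n=20000, K=5, L=5, betasq=0.0,
                             error_cov="heteroscedastic_1_over_l")
        _, Y, _ = gen_functional_data(d, rng)
        target = 1.0 / np.arange(1, 6)
        se = 3.0 * target * np.sqrt(2.0 / 20000)
        # X contributes nothing at betasq=0, so Y loadings are the errors
        assert np.abs(Y.coeffs.var(axis=0) - target).max() < 3 * se.max()
        assert np.allclose(error_scales(d) ** 2, target)

    def test_scalar_coefficients_norm_exact(self):
        beta = beta_vector_coeffs(0.37, F11)
        assert np.sum(beta**2) == pytest.approx(0.37, abs=1e-15)

    def test_scalar_null_response_is_standard_normal_noise(self, rng):
        d = SimulationDesign(n=20000, K=5, L=1, betasq=0.0, response="scalar")
        X, y, _ = gen_scalar_data(d, rng)
        assert y.mean() == pytest.approx(0.0, abs=3.0 / np.sqrt(20000))
        assert y.var() == pytest.approx(1.0, rel=0.05)
        assert abs(np.corrcoef(X.coeffs[:, 0], y)[0, 1]) < 0.03

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(T=0)
        with pytest.raises(ValueError):
            SimulationDesign(error_cov="bogus")
        with pytest.raises(ValueError):
            SimulationDesign(betasq=-0.1)
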