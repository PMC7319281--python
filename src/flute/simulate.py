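"""Synthetic data generators for the Monte-Carlo size and power study.

The designs mirror a standard functional-regression simulation: predictor
curves built on Fourier bases with moving-average factor loadings,

    xi_ik = rho_1 N_ik + rho_2 N_i(k+1) + ... + rho_T N_i(k+T-1),

with N_i ~ N(0, I_{K+T-1}) and rho_t drawn from U(0, 1), so that var(xi) is
banded with bandwidth T-1 and lag-(>=T) loadings are uncorrelated.  The
regression surface is beta(t, s) = |beta|^2 exp{(t^2+s^2)/2} -- the printed
amplitude convention of the study being emulated; note its L2 norm is NOT
|beta|^2, and the ``normalize_beta`` switch rescales the surface so that its
squared L2 norm equals |beta|^2 for sensitivity analysis.  Response loadings
are the transformed predictor loadings plus Gaussian error loadings with
covariance I_L or diag(1/l).

Everything is generated directly in coefficient space (exact under
orthonormal bases); grid rendering is available through
:func:`flute.basis.render_curves` to exercise projection round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .basis import BasisSpec, CoefficientSet, evaluate_basis
from .functional import RegressionSurface

__all__ = [
    "SimulationDesign",
    "ma_covariance",
    "ma_loadings",
    "beta_surface_coeffs",
    "beta_vector_coeffs",
    "gen_functional_data",
    "gen_scalar_data",
    "error_scales",
]


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the Monte-Carlo grid.

    ``rho_policy`` controls whether the MA weights rho are redrawn for every
    replicate dataset (treating them as part of the random design, the
    default) or drawn once per cell and shared by all replicates.
    """

    n: int = 40
    K: int = 5
    L: int = 5
    T: int = 5
    betasq: float = 0.0
    error_cov: str = "identity"  # or "heteroscedastic_1_over_l"
    response: str = "functional"  # or "scalar"
    alpha_levels: tuple = (0.05, 0.1)
    reps: int = 1000
    seed: int = 0
    rho_policy: str = "per_replicate"  # or "fixed_per_cell"
    normalize_beta: bool = False

    def __post_init__(self) -> None:
        if self.T < 1 or self.reps < 1 or self.betasq < 0 or self.n < 4:
            raise ValueError("invalid design: need T>=1, reps>=1, betasq>=0, n>=4")
        if self.error_cov not in ("identity", "heteroscedastic_1_over_l"):
            raise ValueError(f"unknown error covariance {self.error_cov!r}")
        if self.response not in ("functional", "scalar"):
            raise ValueError(f"unknown response kind {self.response!r}")
        if self.rho_policy not in ("per_replicate", "fixed_per_cell"):
            raise ValueError(f"unknown rho policy {self.rho_policy!r}")

    def with_betasq(self, betasq: float) -> "SimulationDesign":
        return replace(self, betasq=betasq)


def ma_covariance(K: int, rho: np.ndarray) -> np.ndarray:
    """Closed-form banded covariance implied by the MA loading model.

    Entry (k, l) is sum_t rho_t rho_{t+|k-l|} for |k-l| < T, zero beyond.
    """
    rho = np.asarray(rho, dtype=float)
    T = rho.size
    cov = np.zeros((K, K))
    for d in range(min(T, K)):
        val = float(np.dot(rho[: T - d], rho[d:]))
        idx = np.arange(K - d)
        cov[idx, idx + d] = val
        cov[idx + d, idx] = val
    return cov


def ma_loadings(n: int, K: int, T: int, rho: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Draw n iid loading rows from the moving-average factor model."""
    rho = np.asarray(rho, dtype=float)
    if rho.size != T or T < 1:
        raise ValueError("rho must have length T >= 1")
    N = rng.standard_normal((n, K + T - 1))
    out = np.zeros((n, K))
    for t in range(T):
        out += rho[t] * N[:, t : t + K]
    return out


def _exp_shape_loadings(size: int, n_quad: int = 2001) -> np.ndarray:
    """Basis loadings a_m = int_0^1 exp(u^2/2) phi_m(u) du (Fourier)."""
    grid = np.linspace(0.0, 1.0, n_quad)
    weight = np.exp(grid**2 / 2.0)
    design = evaluate_basis(BasisSpec("fourier", size), grid)
    return np.trapezoid(weight[:, None] * design, grid, axis=0)


# squared L2 norm of exp{(t^2+s^2)/2} on the unit square
_EXP_SHAPE_NORM_SQ = float(np.trapezoid(
    np.exp(np.linspace(0, 1, 4001) ** 2), np.linspace(0, 1, 4001)
)) ** 2


def beta_surface_coeffs(betasq: float, response_basis: BasisSpec,
                        predictor_basis: BasisSpec,
                        normalize: bool = False) -> RegressionSurface:
    """Coefficients of beta(t, s) = |beta|^2 exp{(t^2+s^2)/2}.

    The surface is separable, so the coefficient matrix is rank one:
    amplitude * outer(a_L, a_K) with a_m the exp-shape loadings.  With
    ``normalize`` the amplitude is rescaled so the surface's squared L2 norm
    equals ``betasq`` instead of using it as a bare amplitude.
    """
    if betasq < 0:
        raise ValueError("betasq must be nonnegative")
    amplitude = betasq
    if normalize and betasq > 0:
        amplitude = np.sqrt(betasq / _EXP_SHAPE_NORM_SQ)
    size = max(response_basis.size, predictor_basis.size)
    a = _exp_shape_loadings(size)
    coeffs = amplitude * np.outer(a[: response_basis.size], a[: predictor_basis.size])
    return RegressionSurface(coeffs, response_basis, predictor_basis)


def beta_vector_coeffs(betasq: float, predictor_basis: BasisSpec) -> np.ndarray:
    """Scalar-response coefficient loadings beta_k = sqrt(|beta|^2 / K).

    Chosen so that sum_k beta_k^2 = |beta|^2 exactly, making |beta|^2 the
    squared L2 norm of beta(t).
    """
    K = predictor_basis.size
    return np.full(K, np.sqrt(betasq / K))


def error_scales(design: SimulationDesign) -> np.ndarray:
    """Per-component error-loading standard deviations for the design."""
    if design.error_cov == "identity":
        return np.ones(design.L)
    return 1.0 / np.sqrt(np.arange(1, design.L + 1))


def _draw_rho(design: SimulationDesign, rng: np.random.Generator,
              cell_rng: np.random.Generator | None) -> np.ndarray:
    if design.rho_policy == "fixed_per_cell":
        if cell_rng is None:
            raise ValueError("fixed_per_cell policy needs a cell-level generator")
        return cell_rng.uniform(0.0, 1.0, design.T)
    return rng.uniform(0.0, 1.0, design.T)


def gen_functional_data(design: SimulationDesign, rng: np.random.Generator,
                        cell_rng: np.random.Generator | None = None):
    """One functional-response dataset: (X, Y, beta) in coefficient space.

    Response loadings are y_i = B xi_i + eps_i with B the surface coefficient
    matrix and eps_i ~ N(0, Sigma_eps).
    """
    if design.response != "functional":
        raise ValueError("design.response must be 'functional'")
    pred = BasisSpec("fourier", design.K)
    resp = BasisSpec("fourier", design.L)
    rho = _draw_rho(design, rng, cell_rng)
    xi = ma_loadings(design.n, design.K, design.T, rho, rng)
    beta = beta_surface_coeffs(design.betasq, resp, pred, design.normalize_beta)
    eps = rng.standard_normal((design.n, design.L)) * error_scales(design)
    y = xi @ beta.coeffs.T + eps
    return CoefficientSet(xi, pred), CoefficientSet(y, resp), beta


def gen_scalar_data(design: SimulationDesign, rng: np.random.Generator,
                    cell_rng: np.random.Generator | None = None):
    """One scalar-response dataset: (X, y, beta) with eps_i ~ N(0, 1)."""
    if design.response != "scalar":
        raise ValueError("design.response must be 'scalar'")
    pred = BasisSpec("fourier", design.K)
    rho = _draw_rho(design, rng, cell_rng)
    xi = ma_loadings(design.n, design.K, design.T, rho, rng)
    beta = beta_vector_coeffs(design.betasq, pred)
    y = xi @ beta + rng.standard_normal(design.n)
    return CoefficientSet(xi, pred), y, beta
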