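"""FLUTE test for scalar-response functional linear models.

Model: Y_i = alpha + int_0^1 X_i(t) beta(t) dt + eps_i with real Y_i.  The
statistic is the functional one with the residual Gram replaced by the outer
product of the scalar residuals r_i = Y_i - <X_i, beta0>; under the null

    n T_n / (sigma^2 sqrt(2 tr(Sigma^2)))  ->  N(0, 1),

with sigma^2 = var[eps], estimated here by the sample variance of the
centered residuals (a pluggable strategy).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import stats

from .basis import CoefficientSet
from .functional import (
    CalibrationError,
    TestResult,
    flute_statistic,
    tr_sq_estimate,
)

__all__ = ["scalar_residuals", "scalar_statistic", "scalar_test"]


def scalar_residuals(y: np.ndarray, X: CoefficientSet,
                     beta0: np.ndarray | None = None) -> np.ndarray:
    """Null residuals r_i = y_i - xi_i . beta0 (beta0 in predictor loadings)."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.n:
        raise ValueError("y and X must have the same number of subjects")
    if beta0 is None:
        return y.copy()
    beta0 = np.asarray(beta0, dtype=float).ravel()
    if beta0.size != X.basis.size:
        raise ValueError(
            f"beta0 has length {beta0.size}, predictor basis size is {X.basis.size}"
        )
    return y - X.coeffs @ beta0


def scalar_statistic(A: np.ndarray, r: np.ndarray) -> float:
    """The scalar-response U-statistic: T_n with residual Gram outer(r, r)."""
    r = np.asarray(r, dtype=float).ravel()
    return flute_statistic(A, np.outer(r, r))


def sample_variance(r: np.ndarray) -> float:
    """Default sigma^2 estimator: variance of the centered residuals."""
    r = np.asarray(r, dtype=float)
    return float(np.var(r - r.mean(), ddof=1))


def scalar_test(X: CoefficientSet, y: np.ndarray,
                beta0: np.ndarray | None = None, alpha: float = 0.05,
                center: bool = True,
                sigma2_estimator: Callable[[np.ndarray], float] = sample_variance,
                ) -> TestResult:
    """Run the FLUTE test for a scalar response."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = X.n
    if n < 4:
        raise ValueError("the FLUTE test needs at least 4 subjects")
    r = scalar_residuals(y, X, beta0)
    Tn = scalar_statistic(X.coeffs @ X.coeffs.T, r)
    Xc = X.coeffs - X.coeffs.mean(axis=0, keepdims=True) if center else X.coeffs
    tr_sigma2 = tr_sq_estimate(Xc @ Xc.T)
    clipped = tr_sigma2 < 0.0
    tr_sigma2 = max(tr_sigma2, 0.0)
    sigma2 = sigma2_estimator(r)
    if sigma2 <= 0.0:
        raise CalibrationError("zero-variance residuals; sigma^2-hat is degenerate")
    if tr_sigma2 <= 0.0:
        raise CalibrationError(
            f"nonpositive tr(Sigma^2)^ = {tr_sigma2:.3g} after clipping"
        )
    z = n * Tn / (sigma2 * np.sqrt(2.0 * tr_sigma2))
    p = float(stats.norm.sf(z))
    return TestResult(
        statistic=float(Tn),
        tr_sigma2_hat=float(tr_sigma2),
        noise_sq_hat=float(sigma2),
        z=float(z),
        p_value=p,
        alpha=float(alpha),
        reject=bool(p <= alpha),
        n=n,
        K=X.basis.size,
        L=1,
        clipped=bool(clipped),
        details={"n_times_statistic": float(n * Tn), "centered_plugins": bool(center)},
    )
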