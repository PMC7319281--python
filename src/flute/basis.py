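"""Orthonormal bases on [0, 1] and curve <-> coefficient conversion.

Curves are represented either on a common observation grid (:class:`CurveSet`)
or by their loadings on an orthonormal basis (:class:`CoefficientSet`).  All
inner products of curves reduce to Euclidean dot products of coefficient rows,
which is what makes the U-statistic computations cheap: for an orthonormal
basis ``{phi_k}`` and curves ``X_i = sum_k c_ik phi_k``,

    <X_i, X_j>_{L2[0,1]} = c_i . c_j .

Raw supports ``[a, b]`` should be affinely rescaled to ``[0, 1]`` before use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BasisSpec",
    "CurveSet",
    "CoefficientSet",
    "evaluate_basis",
    "project_curves",
    "render_curves",
    "gram_matrix",
]


@dataclass(frozen=True)
class BasisSpec:
    """An orthonormal basis family on [0, 1] with a truncation size.

    Parameters
    ----------
    family:
        ``"fourier"`` (orthonormal: 1, sqrt(2) sin(2*pi*s), sqrt(2) cos(2*pi*s),
        sqrt(2) sin(4*pi*s), ...) or ``"bspline"`` (cubic B-splines on a uniform
        knot sequence; not orthonormal, provided for least-squares smoothing
        only).
    size:
        Number of basis functions (the truncation level K or L).
    """

    family: str = "fourier"
    size: int = 5

    def __post_init__(self) -> None:
        if self.family not in ("fourier", "bspline"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.size < 1:
            raise ValueError("basis size must be >= 1")
        if self.family == "bspline" and self.size < 4:
            raise ValueError("cubic bspline basis needs size >= 4")


@dataclass(frozen=True)
class CurveSet:
    """Densely observed curves on a common grid in [0, 1]."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if grid.ndim != 1:
            raise ValueError("grid must be one-dimensional")
        if np.any(grid < 0.0) or np.any(grid > 1.0):
            raise ValueError("grid points must lie in [0, 1]")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if values.shape[1] != grid.size:
            raise ValueError(
                f"values have {values.shape[1]} columns but grid has {grid.size} points"
            )
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CoefficientSet:
    """Sample of curves represented by basis loadings (one row per subject)."""

    coeffs: np.ndarray
    basis: BasisSpec = field(default_factory=BasisSpec)

    def __post_init__(self) -> None:
        coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        if coeffs.shape[1] != self.basis.size:
            raise ValueError(
                f"coefficient matrix has {coeffs.shape[1]} columns, "
                f"basis size is {self.basis.size}"
            )
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def n(self) -> int:
        return self.coeffs.shape[0]


def evaluate_basis(basis: BasisSpec, grid: np.ndarray) -> np.ndarray:
    """Evaluate the basis functions on a grid.

    Returns a ``G x size`` matrix whose column ``k`` holds basis function ``k``
    on the grid.  Fourier ordering is constant, sin, cos, sin, cos, ... with
    frequencies 2*pi, 2*pi, 4*pi, 4*pi, ...
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0.0) or np.any(grid > 1.0):
        raise ValueError("grid points must lie in [0, 1]")
    K = basis.size
    if basis.family == "fourier":
        out = np.empty((grid.size, K))
        out[:, 0] = 1.0
        for k in range(1, K):
            freq = 2.0 * np.pi * ((k + 1) // 2)
            if k % 2 == 1:
                out[:, k] = np.sqrt(2.0) * np.sin(freq * grid)
            else:
                out[:, k] = np.sqrt(2.0) * np.cos(freq * grid)
        return out
    # cubic B-splines on uniform interior knots
    from scipy.interpolate import BSpline

    degree = 3
    n_interior = K - degree - 1
    interior = np.linspace(0, 1, n_interior + 2)[1:-1] if n_interior > 0 else []
    knots = np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])
    out = np.empty((grid.size, K))
    for k in range(K):
        c = np.zeros(K)
        c[k] = 1.0
        out[:, k] = BSpline(knots, c, degree, extrapolate=False)(grid)
    return np.nan_to_num(out)


def project_curves(curves: CurveSet, basis: BasisSpec) -> CoefficientSet:
    """Least-squares projection of observed curves onto the basis.

    Each coefficient row minimizes the discrete squared reconstruction error
    over the grid.  Requires at least as many grid points as basis functions.
    """
    G = curves.grid.size
    if G < basis.size:
        raise ValueError(
            f"grid has {G} points but basis has {basis.size} functions; "
            "the least-squares fit is rank deficient"
        )
    if G < 2:
        raise ValueError("grid needs at least 2 points")
    design = evaluate_basis(basis, curves.grid)
    coeffs, _, rank, _ = np.linalg.lstsq(design, curves.values.T, rcond=None)
    if rank < basis.size:
        raise ValueError("rank-deficient design: degenerate grid for this basis")
    return CoefficientSet(coeffs.T, basis)


def render_curves(coeffs: CoefficientSet, grid: np.ndarray) -> CurveSet:
    """Evaluate coefficient-represented curves on a grid."""
    design = evaluate_basis(coeffs.basis, np.asarray(grid, dtype=float))
    return CurveSet(grid, coeffs.coeffs @ design.T)


def gram_matrix(A: CoefficientSet, B: CoefficientSet | None = None) -> np.ndarray:
    """Pairwise L2 inner products of curves, computed in coefficient space.

    With ``B`` omitted, returns the symmetric PSD matrix ``<X_i, X_j>``.  Both
    sets must share the same basis, as the Euclidean shortcut is only valid
    under a common orthonormal system.
    """
    if B is None:
        return A.coeffs @ A.coeffs.T
    if B.basis != A.basis:
        raise ValueError("coefficient sets use different bases")
    return A.coeffs @ B.coeffs.T
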