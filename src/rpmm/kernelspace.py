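"""Gaussian-kernel RKHS machinery for displacement-field fitting.

A displacement field ``f`` lives in the vector-valued reproducing kernel
Hilbert space induced by a scalar Gaussian kernel applied identically to each
output dimension (a "diagonal" kernel).  By the representer theorem the
regularized weighted least-squares minimizer is a finite kernel expansion
over the data points, so fitting reduces to one linear solve with D
right-hand sides.  A subset-of-regressors variant restricts the expansion to
a small random basis for large point sets.

Transforms follow the displacement convention: ``T(x) = x + f(x)``, so a
transform with all-zero coefficients is the identity map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist

__all__ = [
    "KernelConfig",
    "RbfTransform",
    "NumericalError",
    "kernel_matrix",
    "solve_full",
    "solve_sparse",
    "apply_transform",
    "rkhs_norm_sq",
]

#: jitter escalation cap; solves failing beyond this raise NumericalError
_MAX_JITTER = 1e-6


class NumericalError(RuntimeError):
    """Raised when a kernel linear system stays singular after jitter escalation."""


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian kernel hyper-parameters.

    Parameters
    ----------
    beta
        Inverse-square length scale of the kernel ``k(a, b) =
        exp(-beta * ||a - b||^2)``.  Controls how wide the range of
        interaction between correspondences is; larger beta means more
        local fields.  Default 0.1 is calibrated for unit-variance
        (normalized) coordinates.
    jitter
        Non-negative value added to the diagonal of the kernel matrix before
        solving, purely for conditioning.
    """

    beta: float = 0.1
    jitter: float = 1e-10

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.jitter < 0:
            raise ValueError(f"jitter must be non-negative, got {self.jitter}")


@dataclass
class RbfTransform:
    """One mixture component's displacement field.

    Evaluates as ``T(q) = q + K(q, basis) @ coeffs`` where ``K`` is the
    Gaussian kernel matrix.  ``mode`` records whether the coefficients came
    from the full representer solve or the sparse (subset-of-regressors)
    approximation; evaluation is identical either way.
    """

    basis: np.ndarray
    coeffs: np.ndarray
    beta: float
    mode: str = "full"

    def __post_init__(self) -> None:
        self.basis = np.atleast_2d(np.asarray(self.basis, dtype=float))
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        if self.basis.shape != self.coeffs.shape:
            raise ValueError(
                f"basis {self.basis.shape} and coeffs {self.coeffs.shape} "
                "must have identical shapes"
            )
        if self.basis.shape[1] not in (2, 3) and self.basis.shape[1] != 1:
            raise ValueError(f"unsupported dimensionality D={self.basis.shape[1]}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")

    @property
    def dim(self) -> int:
        return self.basis.shape[1]

    def __call__(self, Q: np.ndarray) -> np.ndarray:
        return apply_transform(self, Q)

    def displacement(self, Q: np.ndarray) -> np.ndarray:
        """Evaluate only the displacement part ``f(Q)``."""
        Q = _check_points(Q, self.dim)
        return kernel_matrix(Q, self.basis, self.beta) @ self.coeffs

    @classmethod
    def identity(cls, basis: np.ndarray, beta: float, mode: str = "full") -> "RbfTransform":
        basis = np.atleast_2d(np.asarray(basis, dtype=float))
        return cls(basis=basis, coeffs=np.zeros_like(basis), beta=beta, mode=mode)


def _check_points(A: np.ndarray, dim: int | None = None) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.ndim != 2:
        raise ValueError(f"expected a 2-D point array, got ndim={A.ndim}")
    if dim is not None and A.shape[1] != dim:
        raise ValueError(f"dimensionality mismatch: expected D={dim}, got {A.shape[1]}")
    return A


def kernel_matrix(A: np.ndarray, B: np.ndarray, beta: float) -> np.ndarray:
    """Gaussian kernel matrix with entries ``exp(-beta * ||A_i - B_j||^2)``.

    The same scalar kernel acts on every output dimension, so a single
    N x M matrix serves all D coordinates of a displacement field.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    A = _check_points(A)
    B = _check_points(B, A.shape[1])
    return np.exp(-beta * cdist(A, B, metric="sqeuclidean"))


def _solve_with_jitter(
    assemble, rhs: np.ndarray, jitter0: float, symmetric: bool
) -> np.ndarray:
    """Solve assemble(jitter) @ C = rhs, escalating jitter x10 on failure."""
    jitter = max(jitter0, 1e-16)
    while True:
        A = assemble(jitter)
        try:
            if symmetric:
                C = linalg.solve(A, rhs, assume_a="pos")
            else:
                C = linalg.solve(A, rhs)
            if np.all(np.isfinite(C)):
                return C
        except linalg.LinAlgError:
            pass
        except ValueError:
            pass
        if jitter >= _MAX_JITTER:
            raise NumericalError(
                f"kernel system remained singular with diagonal jitter up to {jitter:g}"
            )
        jitter *= 10.0


def solve_full(
    X: np.ndarray,
    Ydisp: np.ndarray,
    p: np.ndarray,
    sigma2: float,
    lam: float,
    cfg: KernelConfig,
    K: np.ndarray | None = None,
) -> np.ndarray:
    """Representer-theorem solve for the full kernel expansion.

    Returns the N x D coefficient matrix ``C`` solving

        (diag(p) K + lam * sigma2 * I) C = diag(p) Ydisp,

    where ``K = kernel_matrix(X, X, beta)``.  The induced field minimizes the
    responsibility-weighted regularized risk

        sum_i p_i ||Ydisp_i - f(X_i)||^2 / (2 sigma2) + (lam / 2) ||f||^2_H

    over the whole RKHS.  All-zero weights return all-zero coefficients
    (identity transform).
    """
    X = _check_points(X)
    Ydisp = np.atleast_2d(np.asarray(Ydisp, dtype=float))
    p = np.asarray(p, dtype=float).ravel()
    n = X.shape[0]
    if Ydisp.shape != X.shape:
        raise ValueError("Ydisp must match X in shape")
    if p.shape[0] != n:
        raise ValueError("p must have one weight per point")
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValueError("responsibilities must lie in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not np.any(p > 0):
        return np.zeros_like(X)

    if K is None:
        K = kernel_matrix(X, X, cfg.beta)
    rhs = p[:, None] * Ydisp
    ridge = lam * sigma2

    def assemble(jitter: float) -> np.ndarray:
        Kj = K + jitter * np.eye(n)
        return p[:, None] * Kj + ridge * np.eye(n)

    # diag(p) K is not symmetric for non-uniform p -> general LU solve
    return _solve_with_jitter(assemble, rhs, cfg.jitter, symmetric=False)


def solve_sparse(
    X: np.ndarray,
    Ydisp: np.ndarray,
    p: np.ndarray,
    sigma2: float,
    lam: float,
    basis_idx: np.ndarray,
    cfg: KernelConfig,
    UV: tuple[np.ndarray, np.ndarray] | None = None,
) -> RbfTransform:
    """Subset-of-regressors solve restricted to ``X[basis_idx]``.

    Minimizes the same weighted regularized risk as :func:`solve_full`, but
    over fields spanned by kernels centered on an arbitrary M-subset of the
    inputs, giving the M x M system

        (U' diag(p) U + lam * sigma2 * V) C_s = U' diag(p) Ydisp

    with ``U = K(X, X_basis)`` and ``V = K(X_basis, X_basis)``.  With the
    full basis and an invertible kernel matrix this reproduces the full
    solution's field values.
    """
    X = _check_points(X)
    Ydisp = np.atleast_2d(np.asarray(Ydisp, dtype=float))
    p = np.asarray(p, dtype=float).ravel()
    basis_idx = np.asarray(basis_idx, dtype=int).ravel()
    if basis_idx.size == 0:
        raise ValueError("basis_idx must be non-empty")
    if basis_idx.size > X.shape[0]:
        raise ValueError("basis size cannot exceed the number of points")
    if len(np.unique(basis_idx)) != basis_idx.size:
        raise ValueError("basis_idx must be distinct")
    if np.any(basis_idx < 0) or np.any(basis_idx >= X.shape[0]):
        raise ValueError("basis_idx out of range")
    if sigma2 <= 0 or lam <= 0:
        raise ValueError("sigma2 and lam must be positive")

    Xb = X[basis_idx]
    if not np.any(p > 0):
        return RbfTransform.identity(Xb, cfg.beta, mode="sparse")

    if UV is None:
        U = kernel_matrix(X, Xb, cfg.beta)
        V = kernel_matrix(Xb, Xb, cfg.beta)
    else:
        U, V = UV
    UtP = U.T * p[None, :]
    rhs = UtP @ Ydisp
    ridge = lam * sigma2
    m = Xb.shape[0]
    UtPU = UtP @ U

    def assemble(jitter: float) -> np.ndarray:
        return UtPU + ridge * (V + jitter * np.eye(m))

    coeffs = _solve_with_jitter(assemble, rhs, cfg.jitter, symmetric=True)
    return RbfTransform(basis=Xb, coeffs=coeffs, beta=cfg.beta, mode="sparse")


def apply_transform(t: RbfTransform, Q: np.ndarray) -> np.ndarray:
    """Evaluate ``T(Q) = Q + K(Q, basis) @ coeffs`` at arbitrary points."""
    Q = _check_points(Q, t.dim)
    return Q + kernel_matrix(Q, t.basis, t.beta) @ t.coeffs


def rkhs_norm_sq(t: RbfTransform) -> float:
    """Squared RKHS norm of the displacement field: ``tr(C' V C)``.

    ``V`` is the basis-basis kernel matrix; the result is non-negative up to
    round-off because V is positive semi-definite.
    """
    V = kernel_matrix(t.basis, t.basis, t.beta)
    return float(np.sum(t.coeffs * (V @ t.coeffs)))
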