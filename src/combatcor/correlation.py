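"""Sample correlation induced by two-step batch adjustment, and its repair.

Subtracting estimated batch means makes the adjusted samples correlated:
writing ``P1`` for the projector onto the group design X1, the adjusted data
have covariance ``sigma^2 * M`` with

    H12 = X2 (X2' P1perp X2)^{-1} X2' P1perp,      P1perp = I - P1
    M   = (I - H12)(I - H12)'

``M`` depends only on the design, not on the genes.  Because B-1 directions
are annihilated, M is rank deficient; to use it in generalized least squares
its zero eigenvalues are replaced by a small positive value

    theta = zeta * (sum of the retained eigenvalues),

where the user-chosen noise fraction ``zeta`` is recommended in
[0.1/n, 1/n].  The repaired matrix ``M_tilde`` shares M's eigenvectors, is
positive definite, and carries a Cholesky factor used for whitening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky

from .design import ConfoundedDesignError, GroupBatchDesign

__all__ = [
    "CorrelationModel",
    "compute_H12",
    "compute_M",
    "approximate_M",
    "recommended_zeta_range",
    "default_zeta",
    "build_correlation_model",
]

#: eigenvalues below this multiple of the largest one count as structural zeros
RANK_TOL = 1e-10


@dataclass
class CorrelationModel:
    """Spectral description of the induced correlation and its repair."""

    H12: np.ndarray | None
    M: np.ndarray
    eigenvectors: np.ndarray   # columns, ordered by nonincreasing eigenvalue
    eigenvalues: np.ndarray    # nonincreasing
    rank: int
    zeta: float
    theta: float
    n_replaced: int
    M_tilde: np.ndarray
    whitener: np.ndarray       # lower-triangular L with L @ L.T = M_tilde


def compute_H12(d: GroupBatchDesign) -> np.ndarray:
    """Oblique projector onto the batch design after removing the group design.

    Satisfies H12 @ X2 = X2 and H12 @ H12 = H12; it is symmetric only for
    balanced designs.  With a single batch (empty X2) it is the zero matrix.
    """
    n = d.n
    if d.X2.shape[1] == 0:
        return np.zeros((n, n))
    X1, X2 = d.X1, d.X2
    P1 = X1 @ np.linalg.solve(X1.T @ X1, X1.T)
    P1perp = np.eye(n) - P1
    A = X2.T @ P1perp @ X2
    if np.linalg.cond(A) > 1e12:
        raise ConfoundedDesignError(
            "X2' P1perp X2 is singular: batch design is confounded with the group design"
        )
    return X2 @ np.linalg.solve(A, X2.T @ P1perp)


def compute_M(H12: np.ndarray) -> np.ndarray:
    """Correlation matrix M = (I - H12)(I - H12)' of two-step adjusted samples."""
    R = np.eye(H12.shape[0]) - H12
    M = R @ R.T
    return (M + M.T) / 2.0


def approximate_M(
    M: np.ndarray, zeta: float, H12: np.ndarray | None = None, design: GroupBatchDesign | None = None
) -> CorrelationModel:
    """Full-rank spectral repair of M with noise fraction ``zeta``.

    Eigenvalues below ``RANK_TOL`` times the largest are treated as the zero
    set and replaced by ``theta = zeta * sum(retained eigenvalues)``; the
    repaired matrix keeps M's eigenvectors.  If ``design`` is given, a warning
    is emitted when the count of zero eigenvalues differs from the structural
    expectation B - 1, or when zeta falls outside the recommended range.
    """
    if not 0.0 < zeta < 1.0:
        raise ValueError(f"zeta must be a fraction in (0, 1), got {zeta}")
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("M must be a symmetric square matrix")
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lmax = vals[0]
    if lmax <= 0:
        raise ValueError("M has no positive eigenvalues")
    if vals[-1] < -1e-8 * lmax:
        raise ValueError(f"M is not positive semidefinite (min eigenvalue {vals[-1]:.3e})")

    zero = vals < RANK_TOL * lmax
    rank = int((~zero).sum())
    theta = float(zeta * vals[~zero].sum())
    vals_rep = vals.copy()
    vals_rep[zero] = theta

    if design is not None:
        expected = design.n - (design.n_batches - 1)
        if rank != expected:
            warnings.warn(
                f"rank of M is {rank} but the design implies {expected} "
                f"(n - (B-1)); check the design for extra collinearity",
                stacklevel=2,
            )
        low, high = recommended_zeta_range(design.n)
        if not low <= zeta <= high:
            warnings.warn(
                f"zeta={zeta:.4g} is outside the recommended range "
                f"[{low:.4g}, {high:.4g}] for n={design.n}; statistical power may suffer",
                stacklevel=2,
            )

    if zero.any():
        M_tilde = (vecs * vals_rep) @ vecs.T
        M_tilde = (M_tilde + M_tilde.T) / 2.0
    else:
        M_tilde = M
    L = cholesky(M_tilde, lower=True)
    return CorrelationModel(
        H12=H12,
        M=M,
        eigenvectors=vecs,
        eigenvalues=vals,
        rank=rank,
        zeta=float(zeta),
        theta=theta,
        n_replaced=int(zero.sum()),
        M_tilde=M_tilde,
        whitener=L,
    )


def recommended_zeta_range(n: int) -> tuple[float, float]:
    """Recommended noise-fraction interval (0.1/n, 1/n) for n samples."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    return 0.1 / n, 1.0 / n


def default_zeta(n: int) -> float:
    """Midpoint of the recommended range — the package default."""
    low, high = recommended_zeta_range(n)
    return (low + high) / 2.0


def build_correlation_model(d: GroupBatchDesign, zeta: float) -> CorrelationModel:
    """Design -> H12 -> M -> repaired correlation model, in one call."""
    H12 = compute_H12(d)
    M = compute_M(H12)
    return approximate_M(M, zeta, H12=H12, design=d)
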