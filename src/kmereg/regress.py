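"""Predictors: KMER (kernel on MMD distances), KRR and linear ridge.

All three minimise a squared loss with an L2 penalty.  The kernel methods
share one dual solution: given a similarity matrix K over training
subjects, the dual weights solve

    (K + alpha I) beta = y - mean(y)

and a new subject with cross-similarities kappa is predicted as
``kappa @ beta + mean(y)``.  KMER builds K from MMD distances between
spectra via the outer radial basis function kernel K_ij = exp(-gamma
D_ij^2); KRR builds it from Euclidean distances between bin-power feature
vectors; with Euclidean feature distances fed through the KMER path the
two coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .embedding import DistanceMatrix

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_GAMMA_GRID",
    "OuterKernelSpec",
    "KernelMatrix",
    "RidgeSolution",
    "LinearRidgeSolution",
    "outer_kernel",
    "rbf_from_squared_distance",
    "fit_dual_ridge",
    "predict_dual",
    "fit_rr",
    "predict_rr",
    "krr_kernel",
    "squared_euclidean",
]

# Decade grids for nested cross-validation (configurable at the call site).
DEFAULT_ALPHA_GRID = tuple(np.logspace(-3, 3, 7))
DEFAULT_GAMMA_GRID = tuple(np.logspace(-3, 2, 6))


@dataclass(frozen=True)
class OuterKernelSpec:
    """Bandwidth of the distance-to-similarity kernel exp(-gamma d^2)."""

    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass
class KernelMatrix:
    """Similarity matrix with provenance (outer bandwidth + distance origin)."""

    values: np.ndarray
    subject_ids: list[str]
    gamma: float

    def __post_init__(self) -> None:
        V = np.asarray(self.values, float)
        if V.shape != (len(self.subject_ids),) * 2:
            raise ValueError("kernel matrix shape must match subject list")
        if np.max(np.abs(V - V.T)) > 1e-9:
            raise ValueError("kernel matrix must be symmetric")
        self.values = (V + V.T) / 2.0


def rbf_from_squared_distance(sq: np.ndarray, gamma: float) -> np.ndarray:
    if np.any(sq < -1e-12):
        raise ValueError("squared distances must be non-negative")
    return np.exp(-gamma * np.clip(sq, 0.0, None))


def outer_kernel(
    D: DistanceMatrix | np.ndarray, spec: OuterKernelSpec | float
) -> KernelMatrix | np.ndarray:
    """Similarity K_ij = exp(-gamma D_ij^2) from a (cross-)distance block.

    Returns a :class:`KernelMatrix` when given a :class:`DistanceMatrix`,
    else a plain array (for rectangular test-by-train blocks).
    """
    gamma = spec.gamma if isinstance(spec, OuterKernelSpec) else float(spec)
    if isinstance(D, DistanceMatrix):
        K = rbf_from_squared_distance(D.values**2, gamma)
        return KernelMatrix(K, list(D.subject_ids), gamma)
    D = np.asarray(D, float)
    if np.any(D < 0):
        raise ValueError("distances must be non-negative (clamp upstream)")
    return rbf_from_squared_distance(D**2, gamma)


@dataclass
class RidgeSolution:
    """Dual ridge weights beta, one per training subject, plus the target mean."""

    beta: np.ndarray
    alpha: float
    intercept: float
    subject_ids: list[str] | None = None
    kind: str = "kmer"


@dataclass
class LinearRidgeSolution:
    """Primal ridge: one coefficient per frequency bin, unpenalised intercept."""

    coefficients: np.ndarray
    intercept: float
    alpha: float
    feature_means: np.ndarray | None = None


def _solve_spd(A: np.ndarray, b: np.ndarray, alpha: float) -> np.ndarray:
    # Cholesky first; one shot of jitter for marginal matrices; least-squares
    # as the last resort.  alpha == 0 with a rank-deficient system is an error.
    try:
        c, low = scipy.linalg.cho_factor(A, check_finite=False)
        return scipy.linalg.cho_solve((c, low), b, check_finite=False)
    except np.linalg.LinAlgError:
        pass
    if alpha == 0:
        raise np.linalg.LinAlgError(
            "singular system at alpha=0; use a regularization alpha > 0"
        )
    try:
        jittered = A + 1e-10 * np.eye(A.shape[0])
        c, low = scipy.linalg.cho_factor(jittered, check_finite=False)
        return scipy.linalg.cho_solve((c, low), b, check_finite=False)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def fit_dual_ridge(
    K: KernelMatrix | np.ndarray,
    y: np.ndarray,
    alpha: float,
    kind: str = "kmer",
) -> RidgeSolution:
    """Solve (K + alpha I) beta = y - mean(y) by symmetric factorization."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    ids = None
    if isinstance(K, KernelMatrix):
        ids = list(K.subject_ids)
        K = K.values
    K = np.asarray(K, float)
    y = np.asarray(y, float)
    if K.shape[0] != K.shape[1] or K.shape[0] != y.size:
        raise ValueError("K must be square and aligned with y")
    intercept = float(y.mean())
    A = K + alpha * np.eye(K.shape[0])
    beta = _solve_spd(A, y - intercept, alpha)
    return RidgeSolution(beta=beta, alpha=float(alpha), intercept=intercept,
                         subject_ids=ids, kind=kind)


def predict_dual(
    model: RidgeSolution,
    K_cross: np.ndarray,
    train_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Predict from a test-by-train similarity block: K_cross @ beta + intercept."""
    K_cross = np.atleast_2d(np.asarray(K_cross, float))
    if K_cross.shape[1] != model.beta.size:
        raise ValueError("K_cross columns must align with training subjects")
    if train_ids is not None and model.subject_ids is not None:
        if list(train_ids) != list(model.subject_ids):
            raise ValueError("K_cross column order does not match training order")
    return K_cross @ model.beta + model.intercept


def fit_rr(X: np.ndarray, y: np.ndarray, alpha: float) -> LinearRidgeSolution:
    """Linear ridge on bin-power features, intercept unpenalised.

    Normal-equations solve on centred X and y; equivalent to minimising
    ||y - X w - b||^2 + alpha ||w||^2 over (w, b).
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("features and targets must be finite")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    A = Xc.T @ Xc + alpha * np.eye(X.shape[1])
    try:
        w = _solve_spd(A, Xc.T @ (y - y_mean), alpha)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "collinear features at alpha=0; use a regularization alpha > 0"
        ) from exc
    return LinearRidgeSolution(coefficients=w, intercept=y_mean,
                               alpha=float(alpha), feature_means=x_mean)


def predict_rr(model: LinearRidgeSolution, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.coefficients.size:
        raise ValueError("feature dimension mismatch")
    mu = model.feature_means if model.feature_means is not None else 0.0
    return (X - mu) @ model.coefficients + model.intercept


def squared_euclidean(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between feature rows."""
    Xa = np.atleast_2d(np.asarray(Xa, float))
    Xb = np.atleast_2d(np.asarray(Xb, float))
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("feature dimension mismatch")
    sq = (
        (Xa**2).sum(axis=1)[:, None]
        + (Xb**2).sum(axis=1)[None, :]
        - 2.0 * Xa @ Xb.T
    )
    return np.clip(sq, 0.0, None)


def krr_kernel(Xa: np.ndarray, Xb: np.ndarray, gamma: float) -> np.ndarray:
    """RBF kernel exp(-gamma ||x_a - x_b||^2) on bin-power feature vectors."""
    return rbf_from_squared_distance(squared_euclidean(Xa, Xb), gamma)
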