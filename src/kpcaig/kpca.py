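"""Kernel PCA: centering, eigendecomposition, projection, sigma selection.

Kernel PCA diagonalizes the double-centered Gram matrix K-tilde
``HKH`` (``H = I - (1/n) 1 1^T``). If ``e_k`` is a unit eigenvector with
eigenvalue ``lam_k`` (the eigenvalue of K-tilde; the feature-space
covariance eigenvalue is ``lam_k / n``), the dual coefficients are
``a_k = e_k / sqrt(lam_k)``, which makes the principal axis
``v_k = sum_i a_ik phi~(x_i)`` unit-norm in feature space. That
normalization fixes the absolute scale of the gradient-based importance
scores computed from a fitted model, so it is applied unconditionally.

A new point x projects onto the retained axes as

    rho = (Z^T - (1/n) 1^T K) (I - (1/n) 1 1^T) A,

with ``Z_i = k(x, x_i)`` and ``A`` the n x q dual-coefficient matrix.
For a training point this reduces to the corresponding row of
``K-tilde @ A``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .kernels import KernelSpec, kernel_cross_matrix, kernel_matrix

__all__ = [
    "CenteredKernelMatrix",
    "EigenBasis",
    "KPCAModel",
    "center_kernel_matrix",
    "fit_kpca",
    "fit",
    "project",
    "explained_variance",
    "select_sigma",
    "standardize",
]

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_GRID: np.ndarray = np.logspace(-8, -2, 13)


@dataclass(frozen=True)
class CenteredKernelMatrix:
    """Double-centered Gram matrix together with the centering statistics
    of the raw K (column means and grand mean), cached for out-of-sample
    projection."""

    values: np.ndarray
    col_means: np.ndarray
    grand_mean: float

    @property
    def n(self) -> int:
        return self.values.shape[0]


class EigenBasis(NamedTuple):
    """Retained spectrum of K-tilde and the normalized dual coefficients."""

    eigenvalues: np.ndarray  # length q, descending
    dual_coefs: np.ndarray  # n x q, column k scaled so a^T K~ a = 1
    spectrum: np.ndarray  # all eigenvalues of K~ clipped at 0, descending


def center_kernel_matrix(K: np.ndarray, sym_tol: float = 1e-8) -> CenteredKernelMatrix:
    """Double-center a Gram matrix in feature space.

    Computes ``K~ = K - (1/n) K 1 1^T - (1/n) 1 1^T K + (1/n^2)(1^T K 1) 1 1^T``
    and caches the column means and grand mean of K.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"K must be square, got shape {K.shape}")
    asym = np.max(np.abs(K - K.T)) if K.size else 0.0
    if asym > sym_tol:
        raise ValueError(f"kernel matrix is not symmetric (max |K - K^T| = {asym:.3g})")
    col_means = K.mean(axis=0)
    grand = float(col_means.mean())
    Kc = K - col_means[None, :] - col_means[:, None] + grand
    return CenteredKernelMatrix(values=Kc, col_means=col_means, grand_mean=grand)


def fit_kpca(
    centered: CenteredKernelMatrix | np.ndarray,
    q: int,
    eig_tol: float = 1e-12,
) -> EigenBasis:
    """Eigendecompose K-tilde and return the leading q normalized axes.

    Eigenvalues below ``eig_tol * max(eigenvalue)`` are treated as rank
    deficiency and dropped; if fewer than q directions survive, q is
    reduced with a warning. Each dual-coefficient column is divided by
    sqrt(eigenvalue) (unit-norm axes) and sign-fixed so its
    largest-magnitude entry is positive.
    """
    Kc = centered.values if isinstance(centered, CenteredKernelMatrix) else np.asarray(centered, float)
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    w, V = np.linalg.eigh(Kc)
    w = w[::-1]
    V = V[:, ::-1]
    spectrum = np.clip(w, 0.0, None)
    if spectrum[0] <= 0 or not np.isfinite(spectrum[0]):
        raise ValueError("degenerate kernel matrix: no positive eigenvalue")
    keep = w > eig_tol * w[0]
    rank = int(np.count_nonzero(keep))
    if q > rank:
        warnings.warn(
            f"requested q={q} exceeds numerical rank {rank}; reducing q to {rank}",
            stacklevel=2,
        )
        q = rank
    lam = w[:q]
    A = V[:, :q] / np.sqrt(lam)[None, :]
    # deterministic sign: largest-magnitude entry of each column positive
    flip = A[np.abs(A).argmax(axis=0), np.arange(q)] < 0
    A[:, flip] *= -1.0
    return EigenBasis(eigenvalues=lam, dual_coefs=A, spectrum=spectrum)


def standardize(
    X: np.ndarray, with_scaling: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature z-scoring; returns (X_scaled, means, scales).

    Zero-variance features get scale 1 (they end up identically 0 after
    centering) and trigger a warning rather than a division by zero.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    # round-off in the mean leaves constant columns with sd ~ eps*|mean|
    zero = sds <= 1e-12 * np.maximum(1.0, np.abs(means))
    if with_scaling:
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance feature(s) left at 0 after centering",
                stacklevel=2,
            )
        scales = np.where(zero, 1.0, sds)
    else:
        scales = np.ones(X.shape[1])
    Xs = (X - means) / scales
    Xs[:, zero] = 0.0
    return Xs, means, scales


@dataclass
class KPCAModel:
    """A fitted kernel PCA model.

    ``eigenvalues`` are eigenvalues of K-tilde (descending); the
    feature-space covariance eigenvalues of the classical formulation
    are ``eigenvalues / n`` (see :attr:`lambdas`). ``dual_coefs`` is the
    n x q matrix A with unit-feature-space-norm axes. ``X`` holds the
    preprocessed (z-scored unless scaling was disabled) training data.
    """

    kernel: KernelSpec
    q: int
    eigenvalues: np.ndarray
    dual_coefs: np.ndarray
    spectrum: np.ndarray
    X: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    K: np.ndarray
    K_col_means: np.ndarray
    K_grand_mean: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    scaled: bool
    _training_scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def lambdas(self) -> np.ndarray:
        """Eigenvalues on the paper-of-record KPCA scale (lam' / n)."""
        return self.eigenvalues / self.n

    @property
    def centered_K(self) -> np.ndarray:
        return (
            self.K
            - self.K_col_means[None, :]
            - self.K_col_means[:, None]
            + self.K_grand_mean
        )

    def training_scores(self) -> np.ndarray:
        """Sample coordinates on the retained axes (n x q)."""
        if self._training_scores is None:
            self._training_scores = self.centered_K @ self.dual_coefs
        return self._training_scores


def _extract_frame(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        return (
            X.to_numpy(dtype=float),
            [str(c) for c in X.columns],
            [str(i) for i in X.index],
        )
    X = np.asarray(X, dtype=float)
    return (
        X,
        [f"f{j}" for j in range(X.shape[1])],
        [f"s{i}" for i in range(X.shape[0])],
    )


def fit(
    X,
    kernel: KernelSpec,
    q: int,
    scale: bool = True,
    eig_tol: float = 1e-12,
) -> KPCAModel:
    """Fit kernel PCA on a samples-by-features matrix.

    Features are z-scored by default before the kernel is evaluated
    (``scale=False`` disables the variance scaling; the per-feature mean
    is always removed so that duplicated pipelines stay comparable).
    """
    values, feature_ids, sample_ids = _extract_frame(X)
    Xs, means, scales = standardize(values, with_scaling=scale)
    K = kernel_matrix(Xs, kernel)
    centered = center_kernel_matrix(K)
    basis = fit_kpca(centered, q=q, eig_tol=eig_tol)
    q_eff = basis.dual_coefs.shape[1]
    logger.info(
        "fitted KPCA: n=%d p=%d kernel=%s q=%d top eigenvalues=%s",
        Xs.shape[0],
        Xs.shape[1],
        kernel,
        q_eff,
        np.array2string(basis.eigenvalues[: min(q_eff, 5)], precision=4),
    )
    return KPCAModel(
        kernel=kernel,
        q=q_eff,
        eigenvalues=basis.eigenvalues,
        dual_coefs=basis.dual_coefs,
        spectrum=basis.spectrum,
        X=Xs,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        K=K,
        K_col_means=centered.col_means,
        K_grand_mean=centered.grand_mean,
        feature_means=means,
        feature_scales=scales,
        scaled=scale,
    )


def project(model: KPCAModel, X_new) -> np.ndarray:
    """Project new samples onto the retained kernel principal axes.

    Applies the training preprocessing to ``X_new``, evaluates the
    kernel against the training set, and applies the out-of-sample
    projection formula. Projecting the training data reproduces
    :meth:`KPCAModel.training_scores`.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [f for f in model.feature_ids if f not in X_new.columns]
        if missing:
            raise ValueError(f"X_new is missing training features: {missing[:10]}")
        X_new = X_new.loc[:, model.feature_ids].to_numpy(dtype=float)
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.p:
        raise ValueError(
            f"feature mismatch: model has p={model.p}, X_new has {X_new.shape[1]}"
        )
    Xs = (X_new - model.feature_means) / model.feature_scales
    Z = kernel_cross_matrix(Xs, model.X, model.kernel)
    A = model.dual_coefs
    HA = A - A.mean(axis=0, keepdims=True)
    return (Z - model.K_col_means[None, :]) @ HA


def explained_variance(model: KPCAModel) -> np.ndarray:
    """Fraction of feature-space variance per retained component.

    Each retained eigenvalue is divided by the sum of *all* nonnegative
    eigenvalues of K-tilde, so the q fractions need not sum to 1.
    """
    total = model.spectrum.sum()
    if total <= 0:
        raise ValueError("degenerate kernel matrix: zero total variance")
    return model.eigenvalues / total


def select_sigma(
    X,
    grid: Sequence[float] | None = None,
    q: int = 2,
    scale: bool = True,
    return_table: bool = False,
):
    """Pick the RBF width maximizing cumulative explained variance.

    Evaluates every sigma on the grid, fits KPCA with q components and
    scores it by the cumulative explained-variance fraction of those q
    components. Ties go to the smaller sigma. With
    ``return_table=True`` also returns the full (sigma, variance) table
    as a DataFrame; the table is always logged.
    """
    if grid is None:
        grid = DEFAULT_SIGMA_GRID
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("sigma grid must be nonempty")
    if np.any(grid <= 0):
        raise ValueError("sigma grid values must be positive")
    grid = np.sort(grid)
    objective = np.empty(grid.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, s in enumerate(grid):
            model = fit(X, KernelSpec("rbf", float(s)), q=q, scale=scale)
            objective[i] = explained_variance(model).sum()
    best = int(np.argmax(objective))  # argmax takes the first = smallest sigma on ties
    table = pd.DataFrame({"sigma": grid, "cumulative_explained_variance": objective})
    logger.info("sigma selection (q=%d):\n%s", q, table.to_string(index=False))
    sigma = float(grid[best])
    if return_table:
        return sigma, table
    return sigma
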