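"""Contrast-based partial least squares.

Both the data matrix X (scans × voxels) and the indicator design matrix Y
(scans × 4 group-by-season cells) are standardized columnwise, their
cross-product E = YᵀX is formed, and E is decomposed by SVD, E = U Δ Vᵀ.
Each latent variable (LV) pairs a design contrast (a column of U, the
design saliences) with a voxel pattern (a column of V, the voxel
saliences); the squared singular values give each LV's share of the total
design–data covariance. A scan's expression of an LV is its brain score,
the dot product of its standardized data row with the voxel salience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import CohortDesign, DataMatrix, DesignMatrix, standardize_columns


@dataclass(frozen=True)
class PLSModel:
    """Latent-variable decomposition of the design–data cross-product.

    Attributes
    ----------
    U : ndarray, (4, L)
        Design saliences, orthonormal columns.
    singvals : ndarray, (L,)
        Singular values, descending and positive.
    V : ndarray, (voxels, L)
        Voxel saliences, orthonormal columns.
    cov_fraction : ndarray, (L,)
        delta_l^2 / sum(delta^2); sums to 1.
    """

    U: np.ndarray
    singvals: np.ndarray
    V: np.ndarray
    cov_fraction: np.ndarray

    @property
    def n_latent(self) -> int:
        return self.singvals.shape[0]


@dataclass(frozen=True)
class BrainScores:
    """Scans × L expression of each LV's voxel pattern (standardized X · V)."""

    scores: np.ndarray
    row_design: CohortDesign


def _canonical_sign(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix each LV's joint (u, v) sign so the largest-|u| element is positive.

    The SVD sign is arbitrary per component; pinning it makes outputs
    deterministic across linear-algebra backends.
    """
    U = U.copy()
    V = V.copy()
    for l in range(U.shape[1]):
        pivot = np.argmax(np.abs(U[:, l]))
        if U[pivot, l] < 0:
            U[:, l] *= -1
            V[:, l] *= -1
    return U, V


def cross_product(X_std: np.ndarray, Y_std: np.ndarray) -> np.ndarray:
    """E = YᵀX on already-standardized matrices (4 × voxels)."""
    return Y_std.T @ X_std


def fit_pls(
    X: DataMatrix | np.ndarray,
    Y: DesignMatrix | np.ndarray,
    squared_cov_fraction: bool = True,
) -> PLSModel:
    """Standardize X and Y, decompose E = YᵀX by economy SVD.

    Parameters
    ----------
    squared_cov_fraction : bool
        If True (default, the common PLS convention) covariance fractions
        are delta^2 / sum(delta^2); if False, delta / sum(delta).
    """
    Xm = X.X if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    Ym = Y.Y if isinstance(Y, DesignMatrix) else np.asarray(Y, dtype=float)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError(f"row mismatch: X has {Xm.shape[0]} scans, Y has {Ym.shape[0]}")
    if Xm.shape[0] < 2:
        raise ValueError("PLS needs at least 2 scans")
    E = cross_product(standardize_columns(Xm), standardize_columns(Ym))
    U, s, Vt = np.linalg.svd(E, full_matrices=False)
    tol = max(E.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank == 0:
        raise ValueError("cross-product matrix is zero after standardization")
    L = min(4, Xm.shape[1], rank)
    U, s, V = U[:, :L], s[:L], Vt[:L].T
    U, V = _canonical_sign(U, V)
    if squared_cov_fraction:
        frac = s**2 / np.sum(s**2)
    else:
        frac = s / np.sum(s)
    return PLSModel(U=U, singvals=s, V=V, cov_fraction=frac)


def brain_scores(X: DataMatrix, model: PLSModel) -> BrainScores:
    """Brain scores: standardized data rows projected onto the voxel saliences."""
    if X.X.shape[1] != model.V.shape[0]:
        raise ValueError(
            f"X has {X.X.shape[1]} voxels but model saliences have {model.V.shape[0]}"
        )
    return BrainScores(scores=standardize_columns(X.X) @ model.V, row_design=X.row_design)


def design_scores(Y: DesignMatrix, model: PLSModel) -> np.ndarray:
    """Design scores: standardized indicators projected onto the design saliences."""
    if Y.Y.shape[1] != model.U.shape[0]:
        raise ValueError("design matrix columns do not match model design saliences")
    return standardize_columns(Y.Y) @ model.U
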