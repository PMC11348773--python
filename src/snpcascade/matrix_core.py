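"""Centering/scaling, SVD-based genotype imputation, and exact PCA.

Missing genotypes are completed by iterative low-rank (truncated SVD)
matrix completion: missing cells are initialized at the locus mean of the
observed calls, then repeatedly replaced by their rank-``r`` reconstruction
until the largest per-iteration change on the missing cells falls below a
tolerance.  Observed cells are never altered.  Imputed values are left
real-valued for downstream PCA; use :func:`round_to_genotype` for export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class ImputedMatrix:
    """Result of low-rank completion of a genotype matrix."""

    matrix: np.ndarray  # dense float samples x loci
    mask: np.ndarray  # True where a cell was imputed
    rank: int
    n_iter: int
    final_change: float
    converged: bool


@dataclass
class PCAResult:
    """Exact PCA of a centered (optionally unit-scaled) matrix.

    ``scores = ((X - mean) / scale) @ loadings``; ``eigenvalues`` are the
    per-component score variances (non-increasing).  Loadings columns are
    orthonormal with a deterministic sign convention: the largest-magnitude
    loading of each component is positive.
    """

    loadings: np.ndarray  # loci x k, orthonormal columns
    scores: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # length k
    mean: np.ndarray
    scale: np.ndarray | None

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = X - self.mean
        if self.scale is not None:
            Xc = Xc / self.scale
        return Xc @ self.loadings


def _as_nan_matrix(gm) -> np.ndarray:
    if isinstance(gm, GenotypeMatrix):
        return gm.as_float()
    X = np.array(gm, dtype=float)
    return X


def svd_impute(
    gm,
    rank: int = 10,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ImputedMatrix:
    """Complete missing cells by alternating truncated-SVD projection.

    Parameters
    ----------
    gm
        GenotypeMatrix (MISSING sentinel) or float array with NaN for
        missing cells.
    rank
        Rank of the truncated SVD reconstruction (clipped to matrix rank).
    tol
        Convergence threshold on the max absolute change of imputed cells.
    max_iter
        Iteration cap; non-convergence is reported (warning), not fatal.
    """
    X = _as_nan_matrix(gm)
    mask = np.isnan(X)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    rank = min(rank, min(X.shape))
    if mask.all(axis=1).any():
        raise ValueError("sample with all genotypes missing")
    if mask.all(axis=0).any():
        raise ValueError("locus with all genotypes missing")
    if not mask.any():
        return ImputedMatrix(X.copy(), mask, rank, 0, 0.0, True)

    filled = X.copy()
    col_means = np.nanmean(X, axis=0)
    idx = np.where(mask)
    filled[idx] = col_means[idx[1]]

    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        approx = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        new_vals = approx[idx]
        change = float(np.max(np.abs(new_vals - filled[idx])))
        filled[idx] = new_vals
        if change < tol:
            break
    converged = change < tol
    if not converged:
        warnings.warn(
            f"svd_impute did not converge in {max_iter} iterations "
            f"(final change {change:.3g})",
            RuntimeWarning,
        )
    return ImputedMatrix(filled, mask, rank, it, change, converged)


def round_to_genotype(imp: ImputedMatrix) -> np.ndarray:
    """Round an imputed matrix back to hard {0,1,2} calls for export."""
    return np.clip(np.rint(imp.matrix), 0, 2).astype(np.int8)


def pca(matrix: np.ndarray, k: int | None = None, scale: bool = False) -> PCAResult:
    """Exact PCA via SVD of the centered (optionally unit-scaled) matrix.

    ``k`` defaults to the full rank ``min(n-1, p)``.  Columns with zero
    variance are given unit scale (with a warning) when ``scale=True``;
    after centering they contribute nothing to any component.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("pca requires a complete matrix (impute first)")
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    scale_ = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance column(s) left unscaled",
                RuntimeWarning,
            )
            sd = np.where(zero, 1.0, sd)
        scale_ = sd
        Xc = Xc / sd
    full_rank = min(n - 1 if n > 1 else 1, p)
    if k is None:
        k = full_rank
    if k < 1 or k > min(n, p):
        raise ValueError(f"k={k} outside [1, {min(n, p)}]")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(k, len(s))
    loadings = Vt[:k].T
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Xc @ loadings
    eigenvalues = (s[:k] ** 2) / max(n - 1, 1)
    return PCAResult(loadings, scores, eigenvalues, mean, scale_)
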