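"""Kernel (line-by-line relationship matrix) construction.

Supported kernels:

* linear kernel ``K = X Xᵀ / p`` on standardized features;
* VanRaden genomic relationship matrix on 0/1/2 marker codes,
  ``K = Z Zᵀ / (2 Σ p_k (1 - p_k))`` with ``Z`` the allele-frequency-centered
  genotypes;
* Gaussian kernel ``K_ij = exp(-d²_ij / σ)`` with the bandwidth set to the
  median of the off-diagonal squared Euclidean distances;
* hybrid interaction kernels from a pair of base kernels: the matrix product
  ``P = K1 K2`` is split into its upper triangle (diagonal included, "CC")
  and strictly lower triangle ("PP"), each symmetrized as ``T + Tᵀ``;
* the entrywise (Hadamard) product, the conventional interaction kernel the
  hybrid construction is contrasted with.

The symmetrized triangles of a matrix product need not be positive
semi-definite, so :func:`psd_repair` (eigenvalue clipping) is applied to
hybrid kernels before they serve as covariances; :func:`scale_kernel`
normalizes every kernel to mean diagonal 1 so variance components are
comparable across kernels of different construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_io import FeatureMatrix

logger = logging.getLogger(__name__)

SYMMETRY_RTOL = 1e-8


class KernelError(ValueError):
    pass


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric n x n similarity matrix tagged with its construction recipe.

    ``recipe`` encodes layer(s) and kind, e.g. ``"g:linear"``, ``"t:gaussian"``,
    ``"gt:linear:CC"``.  ``bandwidth`` is set for Gaussian kernels only.
    """

    line_ids: tuple
    values: np.ndarray
    recipe: str
    bandwidth: Optional[float] = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "line_ids", tuple(str(i) for i in self.line_ids))
        n = len(self.line_ids)
        if values.shape != (n, n):
            raise KernelError(f"kernel shape {values.shape} != ({n}, {n})")
        if not np.isfinite(values).all():
            raise KernelError(f"non-finite entries in kernel {self.recipe!r}")
        scale = max(np.abs(values).max(), 1.0)
        if np.abs(values - values.T).max() > SYMMETRY_RTOL * scale:
            raise KernelError(f"kernel {self.recipe!r} is not symmetric")

    @property
    def n(self) -> int:
        return len(self.line_ids)


def _check_pair(K1: KernelMatrix, K2: KernelMatrix) -> None:
    if K1.line_ids != K2.line_ids:
        raise KernelError(
            f"kernels {K1.recipe!r} and {K2.recipe!r} have mismatched line IDs"
        )


def linear_kernel(X: FeatureMatrix, recipe: str = "linear") -> KernelMatrix:
    """``K = X Xᵀ / p`` on standardized features; PSD by construction."""
    if X.n_features == 0:
        raise KernelError("linear kernel needs at least one feature")
    K = X.values @ X.values.T / X.n_features
    K = (K + K.T) / 2.0
    return KernelMatrix(line_ids=X.line_ids, values=K, recipe=recipe)


def vanraden_kernel(Mgeno: FeatureMatrix, recipe: str = "g:linear") -> KernelMatrix:
    """Genomic relationship matrix from 0/1/2 marker codes.

    With per-marker allele frequency ``p_k = mean(column)/2`` and centered
    genotypes ``Z = M - 2p``, ``K = Z Zᵀ / (2 Σ p_k (1 - p_k))``.
    """
    M = Mgeno.values
    if np.isnan(M).any():
        raise KernelError("genotype matrix has missing values; impute first")
    if not np.isin(M, (0.0, 1.0, 2.0)).all():
        raise KernelError("genotype entries must be coded 0/1/2")
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise KernelError("all markers monomorphic: VanRaden denominator is zero")
    Z = M - 2.0 * p[np.newaxis, :]
    K = Z @ Z.T / denom
    K = (K + K.T) / 2.0
    return KernelMatrix(line_ids=Mgeno.line_ids, values=K, recipe=recipe)


def gaussian_kernel(X: FeatureMatrix, recipe: str = "gaussian") -> KernelMatrix:
    """``K_ij = exp(-d²_ij / σ)`` with σ = median of off-diagonal squared
    Euclidean distances between lines (diagonal zeros excluded)."""
    if X.n_lines < 2:
        raise KernelError("Gaussian kernel needs at least two lines")
    d2_condensed = pdist(X.values, metric="sqeuclidean")
    sigma = float(np.median(d2_condensed))
    if sigma <= 0:
        raise KernelError("median squared distance is zero: degenerate bandwidth")
    K = np.exp(-squareform(d2_condensed) / sigma)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(
        line_ids=X.line_ids, values=K, recipe=recipe, bandwidth=sigma
    )


def hybrid_kernels(K1: KernelMatrix, K2: KernelMatrix, recipe_stem: str = "hybrid"):
    """Split ``P = K1 K2`` into symmetrized upper/lower-triangle kernels.

    UT keeps the diagonal, LT is strictly below it, so ``UT + LT = P`` and the
    outputs satisfy ``K_CC + K_PP = P + Pᵀ`` entrywise.  The outputs are
    symmetric but not necessarily PSD; callers must :func:`psd_repair` them
    before use as covariances.

    Returns ``(K_CC, K_PP)``.
    """
    _check_pair(K1, K2)
    P = K1.values @ K2.values
    UT = np.triu(P)          # diagonal included
    LT = np.tril(P, k=-1)    # diagonal excluded
    K_cc = UT + UT.T
    K_pp = LT + LT.T
    ids = K1.line_ids
    return (
        KernelMatrix(line_ids=ids, values=K_cc, recipe=f"{recipe_stem}:CC"),
        KernelMatrix(line_ids=ids, values=K_pp, recipe=f"{recipe_stem}:PP"),
    )


def hadamard_kernel(K1: KernelMatrix, K2: KernelMatrix, recipe: str = "hadamard") -> KernelMatrix:
    """Entrywise product; PSD whenever both inputs are (Schur product theorem)."""
    _check_pair(K1, K2)
    return KernelMatrix(line_ids=K1.line_ids, values=K1.values * K2.values, recipe=recipe)


def scale_kernel(K: KernelMatrix) -> KernelMatrix:
    """Divide by the mean diagonal so that mean(diag) == 1.

    Keeps variance components on a common per-line scale across kernels.
    """
    mean_diag = float(np.mean(np.diag(K.values)))
    if mean_diag <= 0:
        raise KernelError(f"kernel {K.recipe!r} has non-positive mean diagonal")
    return replace(K, values=K.values / mean_diag)


def psd_repair(K: KernelMatrix, tol: float = SYMMETRY_RTOL) -> KernelMatrix:
    """Clip negative eigenvalues to zero and reconstruct.

    The clipped mass (|negative eigenvalue| sum relative to the total
    absolute spectrum) is logged; for genuinely PSD input the output equals
    the input to numerical precision.
    """
    A = K.values
    scale = max(np.abs(A).max(), 1.0)
    if np.abs(A - A.T).max() > tol * scale:
        raise KernelError(f"psd_repair requires a symmetric matrix ({K.recipe!r})")
    eigvals, eigvecs = np.linalg.eigh((A + A.T) / 2.0)
    neg = eigvals < 0
    if not neg.any():
        return K
    total = float(np.abs(eigvals).sum())
    clipped_mass = float(np.abs(eigvals[neg]).sum()) / total if total > 0 else 0.0
    logger.info(
        "psd_repair %s: clipped %d/%d eigenvalues (mass %.3g)",
        K.recipe, int(neg.sum()), len(eigvals), clipped_mass,
    )
    eigvals = np.clip(eigvals, 0.0, None)
    repaired = (eigvecs * eigvals) @ eigvecs.T
    repaired = (repaired + repaired.T) / 2.0
    return replace(K, values=repaired)


def min_eigenvalue_ratio(K: KernelMatrix) -> float:
    """min eigenvalue / max eigenvalue — PSD diagnostic used in tests/logs."""
    w = np.linalg.eigvalsh((K.values + K.values.T) / 2.0)
    wmax = float(np.abs(w).max())
    return float(w.min()) / wmax if wmax > 0 else 0.0
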