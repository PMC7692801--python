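"""Genomic relatedness matrix and its spectral decomposition.

The polygenic covariance structure is the marker cross-product of the
genotype matrix divided by the marker count.  Rotating the model by the
eigenvectors of that matrix diagonalises the polygenic covariance, so every
later per-marker likelihood reduces to diagonal-plus-rank-one algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hrepml.io_formats import GenotypeTable, KinshipTable

__all__ = ["SpectralBasis", "compute_kinship", "spectral_decompose", "rotate", "rotate_vector"]


@dataclass
class SpectralBasis:
    """Eigendecomposition of the kinship plus the rotated data.

    ``eigenvalues`` are sorted descending and clipped below at zero;
    ``eigenvectors`` (columns) are orthonormal.  ``rotated_phenotype`` and
    ``rotated_covariates`` are populated by :func:`rotate`.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    rotated_phenotype: np.ndarray | None = None
    rotated_covariates: np.ndarray | None = None

    @property
    def sample_count(self) -> int:
        return self.eigenvectors.shape[0]


def _as_sample_major(G) -> np.ndarray:
    if isinstance(G, GenotypeTable):
        return G.sample_major()
    Z = np.asarray(G, dtype=float)
    if Z.ndim != 2:
        raise ValueError("genotype matrix must be 2-D")
    return Z


def compute_kinship(G, centered: bool = False) -> KinshipTable:
    """Relatedness matrix Z Z^T / m from a genotype table (Z sample-major).

    By default the genotype matrix enters uncentered, matching the covariance
    definition the model stages assume.  ``centered=True`` subtracts each
    marker's mean call first (common GRM practice), offered as an option.
    """
    Z = _as_sample_major(G)
    if centered:
        Z = Z - Z.mean(axis=0, keepdims=True)
    m = Z.shape[1]
    if m < 1:
        raise ValueError("need at least one marker to build a kinship matrix")
    K = (Z @ Z.T) / m
    K = 0.5 * (K + K.T)  # exact symmetry despite BLAS rounding
    return KinshipTable(K)


def spectral_decompose(K) -> SpectralBasis:
    """Eigendecomposition of a symmetric kinship, eigenvalues descending.

    Eigenvalues below zero by more than 1e-8 trigger a warning; all negative
    eigenvalues are clipped to zero so downstream diagonal covariances stay
    valid.
    """
    M = K.matrix if isinstance(K, KinshipTable) else np.asarray(K, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"kinship must be square, got {M.shape}")
    scale = max(1.0, float(np.abs(M).max(initial=0.0)))
    if np.abs(M - M.T).max(initial=0.0) > 1e-8 * scale:
        raise ValueError("kinship matrix is not symmetric within tolerance")
    evals, evecs = np.linalg.eigh(0.5 * (M + M.T))
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals.min(initial=0.0) < -1e-8:
        warnings.warn(
            f"clipping negative kinship eigenvalue {evals.min():.3e} to zero", RuntimeWarning
        )
    evals = np.clip(evals, 0.0, None)
    return SpectralBasis(eigenvalues=evals, eigenvectors=evecs)


def rotate(y, F, basis: SpectralBasis) -> tuple[np.ndarray, np.ndarray]:
    """Rotate phenotype and covariates into the eigenbasis (y_Q, F_Q).

    The rotated vectors are also stored on ``basis`` so the scan stage can
    carry a single object.
    """
    yv = np.asarray(getattr(y, "values", y), dtype=float).reshape(-1)
    Fm = np.asarray(getattr(F, "design", F), dtype=float)
    Q = basis.eigenvectors
    if yv.size != Q.shape[0] or Fm.shape[0] != Q.shape[0]:
        raise ValueError("phenotype/covariate length does not match the kinship dimension")
    y_Q = Q.T @ yv
    F_Q = Q.T @ Fm
    basis.rotated_phenotype = y_Q
    basis.rotated_covariates = F_Q
    return y_Q, F_Q


def rotate_vector(x, basis: SpectralBasis) -> np.ndarray:
    """Rotate a single marker vector: x_Q = Q^T x."""
    xv = np.asarray(x, dtype=float).reshape(-1)
    return basis.eigenvectors.T @ xv
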