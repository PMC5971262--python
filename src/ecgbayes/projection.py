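"""Cluster-based scatter-matrix projection for low-dimensional display.

Visualization-only pipeline: whiten the data to identity total covariance,
project every sample onto the Gram-Schmidt orthonormal basis of the
(whitened) class means, then diagonalize M = Sw^-1 Sb within that subspace
and read coordinates off the leading eigenvectors.  Nothing here feeds back
into classification — it only produces 2-D/3-D display coordinates.

Scatter matrices follow the classical definitions: Sw sums squared
deviations of samples from their own class mean; Sb sums N_j-weighted
squared deviations of class means from the grand mean; Sw + Sb equals the
total scatter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .features import FeatureDataset
from .outliers import regularize_covariance

__all__ = [
    "ScatterMatrices",
    "ProjectionBasis",
    "scatter_matrices",
    "whiten",
    "gram_schmidt",
    "mean_subspace_projection",
    "display_coordinates",
]

logger = logging.getLogger(__name__)


@dataclass
class ScatterMatrices:
    Sw: np.ndarray
    Sb: np.ndarray


@dataclass
class ProjectionBasis:
    whitener: np.ndarray          # (d, d): X_white = (X - center) @ whitener
    center: np.ndarray            # grand mean used by the whitener
    mean_basis: np.ndarray        # (k, d) orthonormal rows spanning class means
    eigvecs: np.ndarray           # (k, n_dims) within the mean subspace
    eigvals: np.ndarray           # descending


def _class_split(data: FeatureDataset):
    labels = data.labels.astype(str)
    classes = sorted(set(labels.tolist()))
    return labels, classes


def scatter_matrices(data: FeatureDataset) -> ScatterMatrices:
    """Within-class (Sw) and between-class (Sb) scatter of a labeled dataset."""
    X = data.matrix
    labels, classes = _class_split(data)
    if len(classes) < 2:
        raise ValueError("scatter matrices need at least 2 classes")
    mu = X.mean(axis=0)
    d = X.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for cls in classes:
        Xc = X[labels == cls]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        mu_c = Xc.mean(axis=0)
        centered = Xc - mu_c
        Sw += centered.T @ centered
        dm = (mu_c - mu)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)
    return ScatterMatrices(Sw=Sw, Sb=Sb)


def whiten(data: FeatureDataset) -> tuple[FeatureDataset, np.ndarray, np.ndarray]:
    """Transform the dataset to identity total covariance.

    Eigendecompose the total covariance C = V diag(lam) V' and map
    ``X -> (X - mean) V diag(lam^-1/2)``.  Returns the whitened dataset, the
    whitening matrix and the center.
    """
    X = data.matrix
    if X.shape[0] < 2:
        raise ValueError("whitening needs at least 2 samples")
    center = X.mean(axis=0)
    C = regularize_covariance(np.cov(X, rowvar=False, ddof=1))
    lam, V = linalg.eigh(C)
    if lam.min() <= 0:
        raise ValueError("degenerate total covariance; cannot whiten")
    W = V @ np.diag(lam ** -0.5)
    Xw = (X - center) @ W
    return FeatureDataset(matrix=Xw, labels=data.labels.copy()), W, center


def gram_schmidt(vectors: np.ndarray, drop_tol: float = 1e-10) -> np.ndarray:
    """Orthonormalize row vectors with a re-orthogonalization pass.

    Rows whose residual norm falls below ``drop_tol`` (relative to the
    largest input norm) are dropped and logged: they are linearly dependent
    on earlier rows.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    scale = max(np.linalg.norm(vectors, axis=1).max(), 1.0)
    basis: list[np.ndarray] = []
    for i, v in enumerate(vectors):
        u = v.copy()
        for _ in range(2):  # second pass for numerical stability
            for b in basis:
                u -= (u @ b) * b
        norm = np.linalg.norm(u)
        if norm < drop_tol * scale:
            logger.info("Gram-Schmidt dropped dependent vector %d", i)
            continue
        basis.append(u / norm)
    if not basis:
        raise ValueError("all vectors vanished under orthogonalization")
    return np.array(basis)


def mean_subspace_projection(
    data: FeatureDataset,
) -> tuple[FeatureDataset, np.ndarray]:
    """Project every sample onto the span of the class means.

    The basis comes from Gram-Schmidt on the class means in input order.
    Returns the projected dataset (still in the ambient dimension) and the
    orthonormal basis rows.
    """
    X = data.matrix
    labels, classes = _class_split(data)
    means = np.array([X[labels == cls].mean(axis=0) for cls in classes])
    if np.allclose(means, 0):
        raise ValueError("all class means are zero; no subspace to project onto")
    basis = gram_schmidt(means)
    proj = (X @ basis.T) @ basis
    return FeatureDataset(matrix=proj, labels=data.labels.copy()), basis


def _fisher_axes(data_reduced: FeatureDataset, n_dims: int):
    """Leading eigenpairs of Sw^-1 Sb via the symmetric generalized problem."""
    sm = scatter_matrices(data_reduced)
    Sw = regularize_covariance(sm.Sw)
    eigvals, eigvecs = linalg.eigh(sm.Sb, Sw)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvecs = eigvecs[:, :n_dims]
    # sign convention: largest-magnitude component positive
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return eigvals[:n_dims], eigvecs


def display_coordinates(
    data: FeatureDataset, n_dims: int = 2
) -> tuple[np.ndarray, ProjectionBasis]:
    """Per-sample display coordinates on the leading Fisher eigen-axes.

    Pipeline: whiten -> project onto the class-mean subspace -> eigen-
    decompose M = Sw^-1 Sb inside that subspace -> coordinates on the
    leading ``n_dims`` eigenvectors (eigenvalues descending).
    """
    if n_dims not in (2, 3):
        raise ValueError("n_dims must be 2 or 3")
    _, classes = _class_split(data)
    if len(classes) < 2:
        raise ValueError("display projection needs at least 2 classes "
                         "(between-class scatter has rank 0 otherwise)")
    white, W, center = whiten(data)
    projected, basis = mean_subspace_projection(white)
    # work in mean-subspace coordinates so Sw is full rank there
    reduced = FeatureDataset(matrix=white.matrix @ basis.T, labels=data.labels.copy())
    n_dims_eff = min(n_dims, reduced.matrix.shape[1])
    eigvals, eigvecs = _fisher_axes(reduced, n_dims_eff)
    coords = reduced.matrix @ eigvecs
    info = ProjectionBasis(whitener=W, center=center, mean_basis=basis,
                           eigvecs=eigvecs, eigvals=eigvals)
    return coords, info
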