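"""Diffusion-map embedding with an adaptive Gaussian kernel.

Cell-cell similarities are built from a k-nearest-neighbor graph with a
per-cell bandwidth equal to the distance to the k-th neighbor (local
scaling). The kernel is symmetrized and row-normalized to a Markov
transition matrix; its leading nontrivial eigenvectors, scaled by their
eigenvalues, give denoised coordinates in which trajectory geometry is
fitted. The trivial stationary eigenvector (eigenvalue 1) is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

__all__ = ["DiffusionEmbedding", "compute_diffusion_map", "adaptive_kernel", "transition_matrix"]


@dataclass
class DiffusionEmbedding:
    """Cell x component diffusion coordinates with their eigenvalues."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray  # in (0, 1], descending
    n_neighbors: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")


def adaptive_kernel(points: np.ndarray, n_neighbors: int) -> sp.csr_matrix:
    """Symmetric adaptive Gaussian kNN kernel.

    K_ij = exp(-d_ij^2 / (sigma_i sigma_j)) over the kNN graph, with
    sigma_i the distance from cell i to its n_neighbors-th neighbor;
    symmetrized as (K + K^T)/2. Raises if the graph is disconnected,
    naming the component sizes.
    """
    points = np.asarray(points, dtype=float)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(points)
    dist, idx = nn.kneighbors(points)
    sigma = np.maximum(dist[:, -1], 1e-12)

    n = points.shape[0]
    rows = np.repeat(np.arange(n), n_neighbors + 1)
    cols = idx.ravel()
    vals = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    k = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    k = (k + k.T) / 2

    n_comp, labels = connected_components(k, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"kernel graph is disconnected: {n_comp} components with sizes {sizes.tolist()}"
        )
    return k


def transition_matrix(points: np.ndarray, n_neighbors: int) -> sp.csr_matrix:
    """Row-stochastic Markov matrix P = D^-1 K of the adaptive kernel."""
    k = adaptive_kernel(points, n_neighbors)
    inv_deg = 1.0 / np.asarray(k.sum(axis=1)).ravel()
    return sp.diags(inv_deg) @ k


def compute_diffusion_map(
    points: np.ndarray, n_components: int = 5, n_neighbors: int = 30
) -> DiffusionEmbedding:
    """Diffusion-map coordinates from the adaptive-kernel Markov matrix.

    Eigenvectors 2..(n_components + 1) of P, each scaled by its eigenvalue,
    form the coordinates. Computed through the symmetric conjugate
    S = D^-1/2 K D^-1/2, which shares eigenvalues with P; right eigenvectors
    of P are recovered as D^-1/2 v. Component signs are fixed so the
    largest-magnitude entry is positive.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < n_components + 1:
        raise ValueError("need at least n_components + 1 cells")
    nn = min(n_neighbors, points.shape[0] - 1)

    k = adaptive_kernel(points, nn)
    d = np.asarray(k.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(d))
    s = d_inv_sqrt @ k @ d_inv_sqrt

    n_eig = n_components + 1
    evals, evecs = eigsh(s, k=n_eig, which="LA")
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]

    psi = d_inv_sqrt @ evecs  # right eigenvectors of P; psi[:, 0] is constant
    coords = psi[:, 1:n_eig] * evals[1:n_eig]
    for c in range(coords.shape[1]):
        imax = np.argmax(np.abs(coords[:, c]))
        if coords[imax, c] < 0:
            coords[:, c] = -coords[:, c]
    return DiffusionEmbedding(coordinates=coords, eigenvalues=evals[1:n_eig], n_neighbors=nn)
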