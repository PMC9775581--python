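"""Similarity network fusion baseline.

Builds a Gaussian-kernel sample affinity network per domain with a locally
adaptive bandwidth, then fuses the networks by cross-diffusion: each
domain's full-kernel transition matrix is repeatedly pushed through the
other domains' sparse K-nearest-neighbour kernels.  The fused network is
clustered with normalized-Laplacian spectral clustering.  Defaults follow
the published SNF conventions (K=20 neighbours, mu=0.5, 20 iterations); the
melanoma profile clusters the fused network into 3 groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from omnifuse.io_formats import OmicsMatrix
from omnifuse.clustering import PartitionLabels, kmeans_cluster

__all__ = ["AffinityNetwork", "SnfOptions", "affinity_matrix", "snf_fuse", "spectral_cluster"]


@dataclass
class AffinityNetwork:
    """Symmetric non-negative sample x sample similarity matrix."""

    sample_ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.sample_ids)
        if self.W.shape != (n, n):
            raise ValueError(f"W shape {self.W.shape} does not match {n} samples")
        if np.max(np.abs(self.W - self.W.T)) > 1e-10:
            raise ValueError("W must be symmetric")
        if np.any(self.W < 0):
            raise ValueError("W must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class SnfOptions:
    K_neighbors: int = 20
    mu: float = 0.5
    iterations: int = 20
    n_clusters: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.mu <= 1:
            raise ValueError("mu must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _knn_indices(D: np.ndarray, K: int) -> np.ndarray:
    """Indices of the K nearest neighbours per row, excluding self.

    Distance ties are broken by sample index (argsort is stable on the
    secondary key), keeping the kernel deterministic.
    """
    n = D.shape[0]
    order = np.argsort(D + np.eye(n) * (D.max() + 1.0), axis=1, kind="stable")
    return order[:, :K]


def affinity_matrix(X: OmicsMatrix, K_neighbors: int = 20, mu: float = 0.5) -> AffinityNetwork:
    """Locally scaled Gaussian affinity from Euclidean sample distances.

    W(i,j) = exp(-d(i,j)^2 / (mu * eps_ij)) with
    eps_ij = (mean d(i, KNN_i) + mean d(j, KNN_j) + d(i,j)) / 3, so the
    bandwidth adapts to each pair's local density.
    """
    n = X.n_samples
    if K_neighbors >= n:
        raise ValueError(f"K_neighbors={K_neighbors} must be < n_samples={n}")
    D = squareform(pdist(X.values, metric="euclidean"))
    knn = _knn_indices(D, K_neighbors)
    mean_knn = np.take_along_axis(D, knn, axis=1).mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + D) / 3.0
    eps = np.maximum(eps, np.finfo(float).tiny)
    W = np.exp(-(D ** 2) / (mu * eps))
    W = 0.5 * (W + W.T)
    return AffinityNetwork(list(X.sample_ids), W)


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Row-normalized transition matrix with off-diagonal mass 1/2, diag 1/2."""
    n = W.shape[0]
    off = W - np.diag(np.diag(W))
    rs = off.sum(axis=1)
    rs[rs == 0] = 1.0
    P = off / (2.0 * rs[:, None])
    P[np.diag_indices(n)] = 0.5
    return P


def _sparse_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized K-NN kernel (zero outside each row's neighbourhood)."""
    n = W.shape[0]
    D = -W  # larger affinity = nearer
    np.fill_diagonal(D, np.inf)
    knn = np.argsort(D, axis=1, kind="stable")[:, :K]
    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), K)
    S[rows, knn.ravel()] = W[rows, knn.ravel()]
    rs = S.sum(axis=1)
    rs[rs == 0] = 1.0
    return S / rs[:, None]


def snf_fuse(networks: list[AffinityNetwork], options: SnfOptions | None = None) -> AffinityNetwork:
    """Fuse per-domain affinity networks by cross-diffusion.

    Iterates P_v <- S_v @ mean(P_other) @ S_v^T for each domain v, where P_v
    is the full-kernel normalization of W_v and S_v its sparse K-NN kernel,
    re-symmetrizing and re-normalizing after every step; the result is the
    symmetrized average of the final P's.
    """
    if options is None:
        options = SnfOptions()
    if len(networks) < 2:
        raise ValueError("need at least two networks to fuse")
    ids = networks[0].sample_ids
    for net in networks[1:]:
        if net.sample_ids != ids:
            raise ValueError("networks are not on identical aligned samples")
    n = len(ids)
    if options.K_neighbors >= n:
        raise ValueError("K_neighbors must be < number of samples")
    P = [_full_kernel(net.W) for net in networks]
    S = [_sparse_kernel(net.W, options.K_neighbors) for net in networks]
    m = len(networks)
    for _ in range(options.iterations):
        P_new = []
        for v in range(m):
            others = np.mean([P[w] for w in range(m) if w != v], axis=0)
            Pv = S[v] @ others @ S[v].T
            Pv = 0.5 * (Pv + Pv.T)
            P_new.append(_full_kernel(Pv))
        P = P_new
    fused = np.mean(P, axis=0)
    fused = 0.5 * (fused + fused.T)
    return AffinityNetwork(list(ids), fused)


def spectral_embedding(W: AffinityNetwork, n_components: int) -> np.ndarray:
    """Row-normalized bottom eigenvectors of the normalized Laplacian."""
    A = W.W.copy()
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(A.shape[0]) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    L = 0.5 * (L + L.T)
    vals, vecs = np.linalg.eigh(L)
    E = vecs[:, :n_components]
    norms = np.linalg.norm(E, axis=1)
    norms[norms == 0] = 1.0
    return E / norms[:, None]


def spectral_cluster(W: AffinityNetwork, n_clusters: int, seed: int = 0) -> PartitionLabels:
    """Normalized-Laplacian spectral clustering of an affinity network.

    Ng-Jordan-Weiss style: embed samples with the bottom ``n_clusters``
    eigenvectors of the normalized Laplacian (rows renormalized), then
    k-means in the embedding.  Deterministic given ``seed``.
    """
    n = W.n_samples
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} samples")
    if n_clusters == n:
        return PartitionLabels(list(W.sample_ids), np.arange(1, n + 1), n)
    E = spectral_embedding(W, n_clusters)
    return kmeans_cluster(E, n_clusters, seed=seed, sample_ids=W.sample_ids)
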