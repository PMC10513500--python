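"""Similarity network fusion (SNF), spectral clustering, and label transfer.

Fuses per-view sample-similarity networks (here: methylation and gene
expression) by cross-diffusion, clusters the fused network spectrally into
k groups, scores partition agreement with normalized mutual information,
and maps cluster numbers back onto subgroup names by maximum-agreement
assignment.

The SNF kernel and update rule follow Wang et al. (2014): the scaled
exponential similarity kernel

    W(i, j) = exp(-d2(i, j) / (mu * eps(i, j))),
    eps(i, j) = (mean d2 to the K nearest neighbours of i
                 + same for j + d2(i, j)) / 3,

operating on the squared-distance matrix throughout, and the
cross-diffusion update P_v <- S_v @ mean(P_other) @ S_v.T, where P is the
full kernel with off-diagonal row mass 1/2 and S the row-normalized
K-nearest-neighbour mask of W.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

__all__ = [
    "SNFParams",
    "pairwise_sq_distance",
    "affinity_kernel",
    "snf_fuse",
    "spectral_cluster",
    "nmi",
    "relabel_clusters",
    "fuse_views",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SNFParams:
    """Fusion hyperparameters: K neighbours, kernel scale mu, iterations t."""

    K: int = 51
    mu: float = 0.85
    t: int = 120
    k_clusters: int = 4

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")

    def effective_k(self, n_samples: int) -> int:
        """K clamped to n-1 for small cohorts (with a logged warning)."""
        if self.K >= n_samples:
            logger.warning(
                "K=%d >= n=%d; clamping neighbour count to %d",
                self.K, n_samples, n_samples - 1,
            )
            return n_samples - 1
        return self.K


def pairwise_sq_distance(x: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between rows (samples x features)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed")
    d = squareform(pdist(x, metric="sqeuclidean"))
    np.fill_diagonal(d, 0.0)
    return d


def affinity_kernel(d2: np.ndarray, params: SNFParams) -> np.ndarray:
    """Scaled exponential similarity kernel on a squared-distance matrix."""
    d2 = np.asarray(d2, dtype=float)
    n = d2.shape[0]
    if d2.shape != (n, n):
        raise ValueError("distance matrix must be square")
    k = params.effective_k(n)
    if k >= n:
        raise ValueError("K must be < number of samples")
    # mean squared distance to the K nearest neighbours (self excluded)
    sorted_d = np.sort(d2, axis=1)
    knn_mean = sorted_d[:, 1 : k + 1].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + d2) / 3.0
    eps = np.maximum(eps, np.finfo(float).tiny)
    w = np.exp(-d2 / (params.mu * eps))
    w = (w + w.T) / 2.0
    return w


def _full_kernel(w: np.ndarray) -> np.ndarray:
    """Row-stochastic P with diagonal 1/2 and off-diagonal mass 1/2."""
    p = w.copy().astype(float)
    np.fill_diagonal(p, 0.0)
    row = p.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    p = p / (2.0 * row)
    np.fill_diagonal(p, 0.5)
    return p


def _local_kernel(w: np.ndarray, k: int) -> np.ndarray:
    """Row-normalized K-nearest-neighbour mask of W (self excluded)."""
    n = w.shape[0]
    s = np.zeros_like(w)
    for i in range(n):
        order = np.argsort(w[i])[::-1]
        order = order[order != i][:k]
        s[i, order] = w[i, order]
    row = s.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    return s / row


def snf_fuse(affinities: list[np.ndarray], params: SNFParams) -> np.ndarray:
    """Cross-diffusion fusion of >= 2 same-ordered affinity matrices."""
    if len(affinities) < 2:
        raise ValueError("fusion needs >= 2 views")
    n = affinities[0].shape[0]
    for w in affinities:
        if w.shape != (n, n):
            raise ValueError("all views must share the same samples in the same order")
    k = params.effective_k(n)

    ps = [_full_kernel(w) for w in affinities]
    ss = [_local_kernel(w, k) for w in affinities]
    for _ in range(params.t):
        new_ps = []
        for v, s in enumerate(ss):
            others = [ps[u] for u in range(len(ps)) if u != v]
            mean_other = np.mean(others, axis=0)
            p = s @ mean_other @ s.T
            p = _full_kernel((p + p.T) / 2.0)
            new_ps.append(p)
        ps = new_ps
    fused = np.mean(ps, axis=0)
    fused = (fused + fused.T) / 2.0
    return fused


def spectral_cluster(affinity: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering (NJW) into labels 1..k.

    Symmetric-normalized Laplacian, bottom-k eigenvectors, row
    normalization, then k-means with 50 restarts at a fixed seed.
    """
    a = np.asarray(affinity, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n):
        raise ValueError("affinity must be square")
    if k >= n:
        raise ValueError("k must be < number of samples")
    if k == 1:
        return np.ones(n, dtype=int)
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("affinity must be symmetric")
    deg = a.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :]
    # bottom-k eigenvectors; eigh returns ascending eigenvalues
    _, vecs = eigh(lap, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    embedding = vecs / norms
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    return km.fit_predict(embedding) + 1


def nmi(a, b) -> float:
    """Normalized mutual information, I(a;b) / sqrt(H(a) H(b)).

    1 iff the partitions are identical up to renaming; by convention 1 when
    both labelings are constant (both entropies zero).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.size == 0:
        raise ValueError("labels must be non-empty")
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        return 1.0
    return float(normalized_mutual_info_score(a, b, average_method="geometric"))


def relabel_clusters(cluster_ids, reference) -> np.ndarray:
    """Map cluster numbers to subgroup names by maximum total agreement.

    Solves the one-to-one assignment exactly (Hungarian algorithm) on the
    cluster x class contingency table, so each cluster gets the reference
    class with which the global overlap is maximal.
    """
    cluster_ids = np.asarray(cluster_ids)
    reference = np.asarray(reference)
    if cluster_ids.shape != reference.shape:
        raise ValueError("label vectors must have equal length")
    clusters = np.unique(cluster_ids)
    classes = np.unique(reference)
    if len(clusters) > len(classes):
        raise ValueError(
            f"{len(clusters)} clusters cannot be injectively mapped onto "
            f"{len(classes)} reference classes"
        )
    contingency = np.zeros((len(clusters), len(classes)))
    for i, c in enumerate(clusters):
        for j, r in enumerate(classes):
            contingency[i, j] = np.sum((cluster_ids == c) & (reference == r))
    if contingency.sum() == 0:
        raise ValueError("degenerate overlap: contingency table is all zeros")
    rows, cols = linear_sum_assignment(-contingency)
    mapping = {clusters[i]: classes[j] for i, j in zip(rows, cols)}
    return np.array([mapping[c] for c in cluster_ids])


def fuse_views(
    meth_features: np.ndarray,
    expr_features: np.ndarray,
    params: SNFParams | None = None,
) -> np.ndarray:
    """Convenience: distances -> kernels -> fused affinity for two views.

    Both inputs are samples x features matrices over the same samples; each
    view is z-scored per feature before the distance computation so the
    views contribute on comparable scales.
    """
    params = params or SNFParams()
    affinities = []
    for x in (meth_features, expr_features):
        x = np.asarray(x, dtype=float)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
        affinities.append(affinity_kernel(pairwise_sq_distance(x), params))
    return snf_fuse(affinities, params)
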