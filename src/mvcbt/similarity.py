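"""Subject-similarity graphs and Laplacians for multi-view clustering.

For every view, subjects are embedded as vectorized networks, pairwise
Euclidean distances are turned into a KNN-sparsified scaled-exponential
affinity (local sigma rule), and the unnormalized graph Laplacian
``L = W - S`` is formed.  The M per-view Laplacians are then coupled into a
single block matrix whose off-diagonal blocks ``-beta * I`` reward cluster
assignments that agree across views.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pairwise_distance_matrix",
    "knn_mask",
    "similarity_from_distance",
    "view_laplacian",
    "joint_laplacian",
]


def pairwise_distance_matrix(features) -> np.ndarray:
    """Euclidean distance matrix between subjects' feature vectors.

    Parameters
    ----------
    features : array-like of shape (n_subjects, n_features)
    """
    f = np.atleast_2d(np.asarray(features, dtype=float))
    sq = np.sum(f * f, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (f @ f.T)
    np.clip(d2, 0.0, None, out=d2)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def knn_mask(distances: np.ndarray, k_neighbors: int) -> np.ndarray:
    """Boolean mutual-OR K-nearest-neighbor mask (self excluded).

    ``mask[i, j]`` is True when j is among i's ``k_neighbors`` nearest
    neighbors or vice versa.  Ties at the k-th neighbor are all included;
    within equal distances the lower subject index ranks first.
    """
    n = distances.shape[0]
    if not 0 < k_neighbors < n:
        raise ValueError(f"k_neighbors must be in 1..{n - 1}, got {k_neighbors}")
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        d = distances[i].copy()
        d[i] = np.inf
        order = np.argsort(d, kind="stable")
        kth = d[order[k_neighbors - 1]]
        mask[i] = d <= kth  # includes ties at the k-th distance
    return mask | mask.T


def similarity_from_distance(distances, k_neighbors: int):
    """Scaled-exponential affinity graph from a distance matrix.

    The kernel is ``S(i,j) = exp(-D(i,j)^2 / (2 sigma_ij^2))`` with the local
    scale ``sigma_ij = (mu_i + mu_j + D(i,j)) / 3`` where ``mu_i`` is the mean
    distance from i to its ``k_neighbors`` nearest neighbors.  The affinity is
    kept only on the mutual-OR KNN mask, symmetrized as ``(S + S.T) / 2`` and
    zeroed on the diagonal.  Degenerate all-identical inputs (sigma = 0) fall
    back to affinity 1 on the mask.

    Returns
    -------
    S, W, L : ndarray
        Affinity matrix, diagonal degree matrix and Laplacian ``L = W - S``.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distances must be square")
    mask = knn_mask(d, k_neighbors)

    d_off = d.copy()
    np.fill_diagonal(d_off, np.inf)
    order = np.argsort(d_off, axis=1, kind="stable")
    nn = order[:, :k_neighbors]
    mu = np.take_along_axis(d_off, nn, axis=1).mean(axis=1)

    sigma = (mu[:, None] + mu[None, :] + d) / 3.0
    s = np.zeros_like(d)
    pos = sigma > 0
    s[pos] = np.exp(-(d[pos] ** 2) / (2.0 * sigma[pos] ** 2))
    s[~pos] = 1.0  # identical subjects: zero scale, treat as maximally similar
    s *= mask
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 0.0)

    w = np.diag(s.sum(axis=1))
    return s, w, view_laplacian(s)


def view_laplacian(similarity) -> np.ndarray:
    """Unnormalized graph Laplacian ``L = diag(rowsum(S)) - S`` (PSD)."""
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be a square matrix")
    return np.diag(s.sum(axis=1)) - s


def joint_laplacian(laplacians, beta: float = 1.0) -> np.ndarray:
    """Cross-view block Laplacian.

    Block-diagonal of the per-view Laplacians with ``-beta * I_N`` on every
    off-diagonal block; ``beta`` balances within-view clustering against
    cross-view cluster alignment (default 1: all views weighted equally).
    """
    ls = [np.asarray(l, dtype=float) for l in laplacians]
    if not ls:
        raise ValueError("need at least one Laplacian")
    n = ls[0].shape[0]
    for l in ls:
        if l.shape != (n, n):
            raise ValueError("all per-view Laplacians must share the same size")
    m = len(ls)
    out = np.zeros((m * n, m * n))
    eye = np.eye(n)
    for a in range(m):
        out[a * n:(a + 1) * n, a * n:(a + 1) * n] = ls[a]
        for b in range(m):
            if a != b:
                out[a * n:(a + 1) * n, b * n:(b + 1) * n] = -beta * eye
    return out
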