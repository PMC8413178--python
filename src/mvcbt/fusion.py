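"""Similarity-network-fusion (SNF) primitives over ROI x ROI networks.

Within an aligned cluster, the per-view average networks ("local CBTs") are
fused by cross-network diffusion: each view's full kernel ``P`` is repeatedly
diffused along its own sparse KNN kernel ``S`` using the average of the other
views' kernels, then the diffused kernels are averaged into one cluster-level
template.  The full kernel rows carry half their mass off-diagonal and half
on the diagonal, so every row sums to 1; the sparse kernel restricts each row
to its strongest ``k_neighbors`` affinities.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "local_cbt",
    "full_kernel",
    "sparse_kernel",
    "snf_fuse",
    "final_cbt",
]


def local_cbt(networks) -> np.ndarray:
    """Elementwise mean of the networks in one cluster/view."""
    nets = [np.asarray(a, dtype=float) for a in networks]
    if not nets:
        raise ValueError("cannot average an empty cluster")
    shape = nets[0].shape
    for a in nets:
        if a.shape != shape:
            raise ValueError("all networks must share the same shape")
    return np.mean(nets, axis=0)


def full_kernel(a) -> np.ndarray:
    """Row-stochastic full kernel of a non-negative symmetric network.

    ``P(i,j) = A(i,j) / (2 * sum_{l != i} A(i,l))`` off the diagonal and
    ``P(i,i) = 1/2``, so each row sums to exactly 1.  Rows with zero
    off-diagonal mass fall back to a uniform off-diagonal distribution.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    off = a - np.diag(np.diag(a))
    row = off.sum(axis=1)
    p = np.zeros_like(off)
    nz = row > 0
    p[nz] = off[nz] / (2.0 * row[nz, None])
    if (~nz).any() and n > 1:
        p[~nz] = 1.0 / (2.0 * (n - 1))
        p[np.ix_(~nz, ~nz)] = 1.0 / (2.0 * (n - 1))
    np.fill_diagonal(p, 0.5)
    return p


def sparse_kernel(a, k_neighbors: int, *, row_norm: str = "reference") -> np.ndarray:
    """KNN-restricted kernel: each row keeps its ``k_neighbors`` strongest edges.

    Neighbor sets are the ``k_neighbors`` largest affinities per row (ties
    broken by lowest index); retained entries are normalized so the row sums
    to 1 (``row_norm="reference"``, the SNF convention) or to 1/2
    (``row_norm="printed"``).  Diagonal is zero.
    """
    if row_norm not in ("reference", "printed"):
        raise ValueError("row_norm must be 'reference' or 'printed'")
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    if not 0 < k_neighbors < n:
        raise ValueError(f"k_neighbors must be in 1..{n - 1}, got {k_neighbors}")
    denom_factor = 2.0 if row_norm == "printed" else 1.0
    s = np.zeros_like(a)
    for i in range(n):
        row = a[i].copy()
        row[i] = -np.inf
        # argsort ascending on (-value, index) -> descending value, index tie-break
        order = np.lexsort((np.arange(n), -row))
        nbrs = order[:k_neighbors]
        mass = a[i, nbrs].sum()
        if mass > 0:
            s[i, nbrs] = a[i, nbrs] / (denom_factor * mass)
        else:
            s[i, nbrs] = 1.0 / (denom_factor * k_neighbors)
    np.fill_diagonal(s, 0.0)
    return s


def _renormalize(p: np.ndarray) -> np.ndarray:
    """Symmetrize then reapply the full-kernel row rule after a diffusion sweep."""
    return full_kernel((p + p.T) / 2.0)


def snf_fuse(
    local_cbts,
    k_neighbors: int = 5,
    n_iter: int = 20,
    *,
    row_norm: str = "reference",
    return_iterates: bool = False,
):
    """Fuse per-view networks over the same ROIs by cross-network diffusion.

    Initializes ``P^m`` (full kernel) and ``S^m`` (sparse kernel) per view,
    then runs ``n_iter`` simultaneous sweeps of

        P^m <- S^m @ (mean of the other views' P) @ S^m.T

    re-normalizing every kernel after each sweep (symmetrize + full-kernel
    row rule).  Returns the symmetrized average of the diffused kernels.
    A single view degenerates to its full kernel (with a warning).

    With ``return_iterates=True`` also returns the list of per-sweep kernel
    lists (one ``[P^1, ..., P^M]`` per sweep, after re-normalization).
    """
    mats = [np.asarray(a, dtype=float) for a in local_cbts]
    m = len(mats)
    if m == 0:
        raise ValueError("need at least one network to fuse")
    shape = mats[0].shape
    for a in mats:
        if a.shape != shape:
            raise ValueError("all networks must share the same shape")
    if m == 1:
        warnings.warn("SNF with a single view degenerates to its full kernel", RuntimeWarning)
        p = full_kernel(mats[0])
        return (p, [[p]]) if return_iterates else p

    ps = [full_kernel(a) for a in mats]
    ss = [sparse_kernel(a, k_neighbors, row_norm=row_norm) for a in mats]
    iterates = []
    for _ in range(n_iter):
        total = np.sum(ps, axis=0)
        new_ps = []
        for v in range(m):
            others = (total - ps[v]) / (m - 1)
            new_ps.append(ss[v] @ others @ ss[v].T)
        ps = [_renormalize(p) for p in new_ps]
        if return_iterates:
            iterates.append([p.copy() for p in ps])
    fused = np.mean(ps, axis=0)
    fused = (fused + fused.T) / 2.0
    return (fused, iterates) if return_iterates else fused


def final_cbt(cluster_cbts) -> np.ndarray:
    """Elementwise mean of the cluster-level templates."""
    mats = [np.asarray(a, dtype=float) for a in cluster_cbts]
    if not mats:
        raise ValueError("need at least one cluster template")
    return np.mean(mats, axis=0)
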