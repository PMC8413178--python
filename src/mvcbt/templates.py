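"""Connectional brain template (CBT) estimators.

:class:`MVCFNet` is the joint multi-view clustering-and-fusion pipeline:
subjects are clustered jointly across views on the Stiefel manifold, each
cluster's networks are averaged per view into local templates, the local
templates are fused across views by SNF diffusion into cluster templates,
and the cluster templates are averaged into one population template.

:class:`SCABaseline` is a cluster-after-fusion baseline: each subject's
views are SNF-fused first, the fused networks are k-means clustered, and the
cluster centers are averaged.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .clustering import MultiViewSpectralClustering
from .fusion import final_cbt, full_kernel, local_cbt, snf_fuse
from .networks import MultiViewPopulation, vectorize

__all__ = ["MVCFNet", "SCABaseline", "estimate_cbt", "estimate_cbt_sca_baseline"]


def _as_tensor(X) -> np.ndarray:
    if isinstance(X, MultiViewPopulation):
        return X.networks
    nets = np.asarray(X, dtype=float)
    if nets.ndim != 4:
        raise ValueError("expected a (n_subjects, n_views, n_rois, n_rois) tensor")
    return nets


class MVCFNet(BaseEstimator):
    """Population template via joint multi-view clustering and SNF fusion.

    Parameters
    ----------
    n_clusters : int, default=3
        Number of aligned clusters.
    k_neighbors : int, default=5
        KNN size, used both for the subject-affinity graphs and for the
        sparse SNF kernels.
    snf_iterations : int, default=20
        Diffusion sweeps in the cross-view fusion.
    beta : float, default=1.0
        Cross-view cluster-alignment weight.
    snf_row_norm : {"reference", "printed"}
        Row normalization convention of the sparse SNF kernel.
    max_iter, tol, init : Stiefel optimizer controls.
    random_state : int or None
        Seed controlling k-means label extraction (and random init).

    Attributes
    ----------
    cbt_ : ndarray of shape (n_rois, n_rois)
        Final population template.
    labels_ : ndarray of shape (n_views, n_subjects)
        Aligned per-view cluster labels.
    local_cbts_ : dict[(cluster, view), ndarray]
        Per-cluster per-view average networks (only non-empty combinations).
    cluster_cbts_ : dict[cluster, ndarray]
        Cross-view fused templates per cluster.
    objective_ : float
        Final Stiefel trace objective.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        *,
        k_neighbors: int = 5,
        snf_iterations: int = 20,
        beta: float = 1.0,
        snf_row_norm: str = "reference",
        max_iter: int = 500,
        tol: float = 1e-8,
        init: str = "eigen",
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.k_neighbors = k_neighbors
        self.snf_iterations = snf_iterations
        self.beta = beta
        self.snf_row_norm = snf_row_norm
        self.max_iter = max_iter
        self.tol = tol
        self.init = init
        self.random_state = random_state

    def fit(self, X, y=None):
        nets = _as_tensor(X)
        n, m = nets.shape[0], nets.shape[1]
        if n < self.n_clusters:
            raise ValueError("need at least n_clusters subjects")
        clusterer = MultiViewSpectralClustering(
            n_clusters=self.n_clusters,
            k_neighbors=min(self.k_neighbors, n - 1),
            beta=self.beta,
            max_iter=self.max_iter,
            tol=self.tol,
            init=self.init,
            random_state=self.random_state,
        ).fit(nets)
        labels = clusterer.labels_

        local: dict[tuple[int, int], np.ndarray] = {}
        cluster_cbts: dict[int, np.ndarray] = {}
        for c in range(self.n_clusters):
            per_view = []
            for view in range(m):
                members = np.flatnonzero(labels[view] == c)
                if members.size == 0:
                    continue
                a = local_cbt(nets[members, view])
                local[(c, view)] = a
                per_view.append(a)
            if not per_view:
                warnings.warn(f"cluster {c} is empty in every view; dropped", RuntimeWarning)
                continue
            if len(per_view) == 1:
                cluster_cbts[c] = full_kernel(per_view[0])
            else:
                cluster_cbts[c] = snf_fuse(
                    per_view,
                    k_neighbors=min(self.k_neighbors, nets.shape[2] - 1),
                    n_iter=self.snf_iterations,
                    row_norm=self.snf_row_norm,
                )

        self.clusterer_ = clusterer
        self.labels_ = labels
        self.objective_ = clusterer.objective_
        self.local_cbts_ = local
        self.cluster_cbts_ = cluster_cbts
        self.cbt_ = final_cbt(list(cluster_cbts.values()))
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the final template matrix."""
        return self.fit(X).cbt_


class SCABaseline(BaseEstimator):
    """Cluster-after-fusion template baseline.

    Each subject's views are SNF-fused into one network, the fused networks
    are clustered by seeded k-means on their vectorized upper triangles, and
    the final template is the mean of the cluster-wise mean networks.

    Attributes
    ----------
    cbt_ : ndarray of shape (n_rois, n_rois)
    labels_ : ndarray of shape (n_subjects,)
    fused_ : ndarray of shape (n_subjects, n_rois, n_rois)
        Per-subject fused networks.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        *,
        k_neighbors: int = 5,
        snf_iterations: int = 20,
        snf_row_norm: str = "reference",
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.k_neighbors = k_neighbors
        self.snf_iterations = snf_iterations
        self.snf_row_norm = snf_row_norm
        self.random_state = random_state

    def fit(self, X, y=None):
        nets = _as_tensor(X)
        n, m, r = nets.shape[0], nets.shape[1], nets.shape[2]
        if n < self.n_clusters:
            raise ValueError("need at least n_clusters subjects")
        k = min(self.k_neighbors, r - 1)
        if m == 1:
            fused = np.stack([full_kernel(nets[i, 0]) for i in range(n)])
        else:
            fused = np.stack(
                [
                    snf_fuse(
                        nets[i],
                        k_neighbors=k,
                        n_iter=self.snf_iterations,
                        row_norm=self.snf_row_norm,
                    )
                    for i in range(n)
                ]
            )
        feats = np.stack([vectorize(f) for f in fused])
        km = KMeans(n_clusters=self.n_clusters, n_init=20, random_state=self.random_state)
        labels = km.fit_predict(feats)
        centers = [
            fused[labels == c].mean(axis=0)
            for c in range(self.n_clusters)
            if np.any(labels == c)
        ]
        self.fused_ = fused
        self.labels_ = labels
        self.cbt_ = final_cbt(centers)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).cbt_


def estimate_cbt(population, **params) -> MVCFNet:
    """Fit :class:`MVCFNet` on a population; returns the fitted estimator."""
    return MVCFNet(**params).fit(population)


def estimate_cbt_sca_baseline(population, **params) -> SCABaseline:
    """Fit :class:`SCABaseline` on a population; returns the fitted estimator."""
    return SCABaseline(**params).fit(population)
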