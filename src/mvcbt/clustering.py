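"""Joint multi-view spectral clustering on the Stiefel manifold.

The relaxed assignment problem is

    min_U  trace(U^T L U)   s.t.  U^T U = I_{N_c}

where ``L`` is the cross-view block Laplacian and ``U`` stacks one N x N_c
block per view.  It is solved by projected gradient descent with Armijo
backtracking and a polar (SVD) retraction onto the manifold; the analytic
minimum is the sum of the ``N_c`` smallest eigenvalues of ``L``, attained by
the corresponding eigenvectors.  Aligned per-view labels are read off by a
single k-means on the rows of the optimized stacked embedding, so the row
blocks of the M views share centroids and no post-hoc matching is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .networks import MultiViewPopulation, vectorize
from .similarity import joint_laplacian, pairwise_distance_matrix, similarity_from_distance

__all__ = [
    "StiefelResult",
    "clustering_objective",
    "negative_gradient",
    "tangent_projection",
    "retract",
    "optimize_joint_clustering",
    "assign_clusters",
    "MultiViewSpectralClustering",
]

_ORTHO_TOL = 1e-8


def clustering_objective(u: np.ndarray, laplacian: np.ndarray) -> float:
    """trace(U^T L U)."""
    return float(np.trace(u.T @ laplacian @ u))


def negative_gradient(u: np.ndarray, laplacian: np.ndarray) -> np.ndarray:
    """Negative Euclidean gradient of the trace objective: ``Z = -L U``.

    The gradient of trace(U^T L U) is 2LU; the constant factor is absorbed
    by the line search.
    """
    return -(laplacian @ u)


def tangent_projection(u: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Project an ambient direction onto the Stiefel tangent space at ``u``.

    ``eta = Z - U sym(U^T Z)`` with ``sym(A) = (A + A.T)/2``; the result
    satisfies the tangency condition ``U^T eta + eta^T U = 0``.
    """
    utu = u.T @ u
    if np.abs(utu - np.eye(u.shape[1])).max() > 1e-6:
        raise ValueError("u must have orthonormal columns")
    utz = u.T @ z
    return z - u @ ((utz + utz.T) / 2.0)


def retract(candidate: np.ndarray) -> np.ndarray:
    """Polar retraction: nearest orthonormal-column matrix via thin SVD."""
    w, s, vt = np.linalg.svd(candidate, full_matrices=False)
    if s[-1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("cannot retract a rank-deficient matrix")
    return w @ vt


@dataclass
class StiefelResult:
    """Optimizer output: the stacked embedding and its trace objective."""

    u: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray
    n_views: int
    n_subjects: int


def _initial_point(laplacian, n_clusters, init, rng):
    if init == "eigen":
        _, vecs = eigh(laplacian, subset_by_index=[0, n_clusters - 1])
        return vecs
    if init == "random":
        return retract(rng.standard_normal((laplacian.shape[0], n_clusters)))
    raise ValueError(f"unknown init {init!r}")


def optimize_joint_clustering(
    laplacian,
    n_clusters: int,
    *,
    n_views: int = 1,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = None,
    init: str = "eigen",
    armijo_c: float = 1e-4,
    shrink: float = 0.5,
) -> StiefelResult:
    """Minimize trace(U^T L U) over the Stiefel manifold.

    Each iteration projects the negative gradient onto the tangent space,
    backtracks an Armijo step (initial step 1.0, shrink 0.5, sufficient
    decrease 1e-4) and retracts the candidate by polar decomposition, so the
    objective is non-increasing over accepted steps and every iterate has
    orthonormal columns.  Stops when the relative objective change falls
    below ``tol``; hitting ``max_iter`` records a warning, not an error.
    """
    l = np.asarray(laplacian, dtype=float)
    total = l.shape[0]
    if l.shape != (total, total):
        raise ValueError("laplacian must be square")
    if total % n_views:
        raise ValueError("laplacian size must be a multiple of n_views")
    n_subjects = total // n_views
    if n_clusters >= n_subjects:
        raise ValueError("n_clusters must be smaller than the number of subjects")

    rng = np.random.default_rng(seed)
    u = _initial_point(l, n_clusters, init, rng)
    obj = clustering_objective(u, l)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = tangent_projection(u, negative_gradient(u, l))
        grad_sq = float(np.sum(eta * eta))
        if grad_sq <= 1e-30:
            converged = True
            break
        step = 1.0
        new_u, new_obj = u, obj
        while step > 1e-16:
            cand = retract(u + step * eta)
            cand_obj = clustering_objective(cand, l)
            if cand_obj <= obj - armijo_c * step * grad_sq:
                new_u, new_obj = cand, cand_obj
                break
            step *= shrink
        if new_obj >= obj - tol * max(1.0, abs(obj)):
            u, obj = new_u, new_obj
            trace.append(obj)
            converged = True
            break
        u, obj = new_u, new_obj
        trace.append(obj)
    if not converged:
        warnings.warn("Stiefel optimizer hit max_iter without converging", RuntimeWarning)
    return StiefelResult(
        u=u,
        objective=obj,
        n_iter=it,
        converged=converged,
        objective_trace=np.asarray(trace),
        n_views=n_views,
        n_subjects=n_subjects,
    )


def assign_clusters(result: StiefelResult, n_clusters: int, seed: int | None = None) -> np.ndarray:
    """Aligned per-view labels via k-means on the rows of the stacked embedding.

    Returns an (n_views, n_subjects) integer label matrix; because all view
    blocks are clustered against shared centroids, label ``c`` refers to the
    same cluster in every view.
    """
    if n_clusters >= result.n_subjects:
        raise ValueError("n_clusters must be smaller than the number of subjects")
    km = KMeans(n_clusters=n_clusters, n_init=20, random_state=seed)
    labels = km.fit_predict(result.u)
    return labels.reshape(result.n_views, result.n_subjects)


class MultiViewSpectralClustering(ClusterMixin, BaseEstimator):
    """Joint spectral clustering of subjects across several network views.

    Builds one KNN affinity graph per view, couples the per-view Laplacians
    into a cross-view block Laplacian, minimizes the trace objective on the
    Stiefel manifold and extracts aligned per-view labels by k-means on the
    shared embedding.

    Parameters
    ----------
    n_clusters : int, default=3
        Number of clusters per view.
    k_neighbors : int, default=5
        KNN graph size for the affinity kernel.
    beta : float, default=1.0
        Cross-view alignment weight (1 treats all views equally).
    max_iter, tol : optimizer controls.
    init : {"eigen", "random"}
        Warm start at the smallest Laplacian eigenvectors, or a seeded
        random orthonormal matrix.
    random_state : int or None
        Seed for k-means (and random init).

    Attributes
    ----------
    labels_ : ndarray of shape (n_views, n_subjects)
        Aligned per-view cluster labels.
    embedding_ : ndarray of shape (n_views * n_subjects, n_clusters)
        Optimized stacked Stiefel point.
    objective_ : float
        Final value of trace(U^T L U).
    n_iter_ : int
    """

    def __init__(
        self,
        n_clusters: int = 3,
        *,
        k_neighbors: int = 5,
        beta: float = 1.0,
        max_iter: int = 500,
        tol: float = 1e-8,
        init: str = "eigen",
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.k_neighbors = k_neighbors
        self.beta = beta
        self.max_iter = max_iter
        self.tol = tol
        self.init = init
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a population tensor.

        Parameters
        ----------
        X : MultiViewPopulation or ndarray of shape (n_subjects, n_views, n_rois, n_rois)
        """
        nets = X.networks if isinstance(X, MultiViewPopulation) else np.asarray(X, dtype=float)
        n, m = nets.shape[0], nets.shape[1]
        if self.n_clusters > n:
            raise ValueError("n_clusters cannot exceed the number of subjects")
        laplacians = []
        similarities = []
        for view in range(m):
            feats = np.stack([vectorize(nets[i, view]) for i in range(n)])
            d = pairwise_distance_matrix(feats)
            s, _, l = similarity_from_distance(d, self.k_neighbors)
            similarities.append(s)
            laplacians.append(l)
        joint = joint_laplacian(laplacians, beta=self.beta)
        result = optimize_joint_clustering(
            joint,
            self.n_clusters,
            n_views=m,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
            init=self.init,
        )
        self.similarities_ = similarities
        self.joint_laplacian_ = joint
        self.embedding_ = result.u
        self.objective_ = result.objective
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.labels_ = assign_clusters(result, self.n_clusters, seed=self.random_state)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
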