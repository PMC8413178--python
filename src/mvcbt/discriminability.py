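"""Discriminative-ROI identification between two populations.

Two independent rankings of the ``n_rois`` regions are produced:

* **Template difference** — templates are estimated per fold for each group;
  the elementwise absolute differences of all cross-group fold pairs are
  accumulated into a matrix ``T`` whose row sums score each ROI.
* **SVM weights** — for every view and every cross-group fold pair a linear
  soft-margin SVM is trained on vectorized networks; the absolute feature
  weights are summed, anti-linearized into a symmetric matrix ``B``, and row
  sums score each ROI.

Agreement between the two rankings is reported as the percentage overlap of
their top-k ROI sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .evaluation import kfold_split
from .networks import MultiViewPopulation, antivectorize, vectorize
from .templates import MVCFNet

__all__ = [
    "cumulative_difference",
    "roi_scores_from_difference",
    "rank_rois",
    "svm_feature_weights",
    "mkl_total_weights",
    "roi_scores_from_weights",
    "ranking_overlap",
    "foldwise_cbts",
    "discriminative_roi_report",
]


def cumulative_difference(cbts_a, cbts_b) -> np.ndarray:
    """Sum of elementwise absolute differences over all cross-group CBT pairs."""
    cbts_a = [np.asarray(a, dtype=float) for a in cbts_a]
    cbts_b = [np.asarray(b, dtype=float) for b in cbts_b]
    if not cbts_a or not cbts_b:
        raise ValueError("both CBT lists must be non-empty")
    shape = cbts_a[0].shape
    for x in (*cbts_a, *cbts_b):
        if x.shape != shape:
            raise ValueError("all CBTs must share the same shape")
    t = np.zeros(shape)
    for a in cbts_a:
        for b in cbts_b:
            t += np.abs(a - b)
    return t


def rank_rois(alpha: np.ndarray) -> np.ndarray:
    """Descending-score permutation with ascending-index tie-break."""
    alpha = np.asarray(alpha, dtype=float)
    return np.lexsort((np.arange(alpha.size), -alpha))


def roi_scores_from_difference(t) -> tuple[np.ndarray, np.ndarray]:
    """Row-sum ROI scores of a cumulative difference matrix.

    Returns ``(alpha, ranking)`` where ``alpha[i] = sum_j T(i, j)``.
    """
    t = np.asarray(t, dtype=float)
    alpha = t.sum(axis=1)
    return alpha, rank_rois(alpha)


def svm_feature_weights(features_a, features_b, svm_c: float = 1.0) -> np.ndarray:
    """Absolute per-feature weights of a linear soft-margin SVM.

    The SVM separates group A (label +1) from group B (label -1); the
    magnitude of each component of the separating direction ``w`` measures
    that feature's discriminative power.
    """
    fa = np.atleast_2d(np.asarray(features_a, dtype=float))
    fb = np.atleast_2d(np.asarray(features_b, dtype=float))
    if fa.shape[0] == 0 or fb.shape[0] == 0:
        raise ValueError("both classes need at least one sample")
    if fa.shape[1] != fb.shape[1]:
        raise ValueError("feature lengths differ between groups")
    x = np.vstack([fa, fb])
    y = np.concatenate([np.ones(fa.shape[0]), -np.ones(fb.shape[0])])
    clf = SVC(kernel="linear", C=svm_c, tol=1e-6)
    clf.fit(x, y)
    return np.abs(clf.coef_.ravel())


@dataclass
class FeatureWeightState:
    """Accumulated SVM feature weights and their ROI-level matrix form."""

    x: np.ndarray  # length n_rois*(n_rois-1)/2, non-negative
    b: np.ndarray  # n_rois x n_rois symmetric zero-diagonal


def mkl_total_weights(
    pop_a: MultiViewPopulation,
    pop_b: MultiViewPopulation,
    k_folds: int = 5,
    seed: int | None = None,
    svm_c: float = 1.0,
) -> FeatureWeightState:
    """Total SVM feature weights across all views and cross-group fold pairs.

    Each population is split into ``k_folds`` seeded folds; for every view
    and every fold pair one linear SVM is fitted on that pair's vectorized
    networks and its absolute weights are accumulated.
    """
    if pop_a.n_rois != pop_b.n_rois or pop_a.n_views != pop_b.n_views:
        raise ValueError("populations must share n_rois and n_views")
    r, m = pop_a.n_rois, pop_a.n_views
    folds_a = kfold_split(pop_a.n_subjects, k_folds, seed=seed)
    folds_b = kfold_split(pop_b.n_subjects, k_folds, seed=None if seed is None else seed + 1)
    feats_a = np.stack(
        [[vectorize(pop_a.networks[i, v]) for v in range(m)] for i in range(pop_a.n_subjects)]
    )
    feats_b = np.stack(
        [[vectorize(pop_b.networks[i, v]) for v in range(m)] for i in range(pop_b.n_subjects)]
    )
    x = np.zeros(r * (r - 1) // 2)
    for view in range(m):
        for fi in range(k_folds):
            ia = np.flatnonzero(folds_a == fi)
            for fj in range(k_folds):
                ib = np.flatnonzero(folds_b == fj)
                if ia.size == 0 or ib.size == 0:
                    warnings.warn("empty fold skipped in weight accumulation", RuntimeWarning)
                    continue
                x += svm_feature_weights(feats_a[ia, view], feats_b[ib, view], svm_c=svm_c)
    return FeatureWeightState(x=x, b=antivectorize(x, r))


def roi_scores_from_weights(state: FeatureWeightState) -> tuple[np.ndarray, np.ndarray]:
    """Row-sum ROI scores of the anti-linearized weight matrix."""
    alpha = state.b.sum(axis=1)  # diagonal is zero, so this is sum over j != i
    return alpha, rank_rois(alpha)


def ranking_overlap(ranking_a, ranking_b, top_k: int) -> float:
    """Percentage overlap of two rankings' top-k ROI sets."""
    ranking_a = np.asarray(ranking_a)
    ranking_b = np.asarray(ranking_b)
    if top_k > ranking_a.size or top_k > ranking_b.size:
        raise ValueError("top_k exceeds the ranking length")
    shared = len(set(ranking_a[:top_k].tolist()) & set(ranking_b[:top_k].tolist()))
    return 100.0 * shared / top_k


def foldwise_cbts(population: MultiViewPopulation, k_folds: int, seed: int | None = None, **params):
    """One template per fold of a population.

    Estimates an :class:`~mvcbt.templates.MVCFNet` template on each of the
    ``k_folds`` seeded sub-populations and returns the list of matrices.
    """
    folds = kfold_split(population.n_subjects, k_folds, seed=seed)
    cbts = []
    for f in range(k_folds):
        sub = population.subset(np.flatnonzero(folds == f))
        cbts.append(MVCFNet(random_state=seed, **params).fit(sub).cbt_)
    return cbts


def discriminative_roi_report(
    pop_a: MultiViewPopulation,
    pop_b: MultiViewPopulation,
    k_folds: int = 5,
    top_k: int = 15,
    seed: int | None = None,
    svm_c: float = 1.0,
    **cbt_params,
) -> dict:
    """Both ROI rankings and their top-k overlap for a two-group comparison."""
    cbts_a = foldwise_cbts(pop_a, k_folds, seed=seed, **cbt_params)
    cbts_b = foldwise_cbts(
        pop_b, k_folds, seed=None if seed is None else seed + 1, **cbt_params
    )
    t = cumulative_difference(cbts_a, cbts_b)
    alpha_diff, rank_diff = roi_scores_from_difference(t)
    state = mkl_total_weights(pop_a, pop_b, k_folds=k_folds, seed=seed, svm_c=svm_c)
    alpha_mkl, rank_mkl = roi_scores_from_weights(state)
    return {
        "alpha_cbt_difference": alpha_diff,
        "ranking_cbt_difference": rank_diff,
        "alpha_mkl": alpha_mkl,
        "ranking_mkl": rank_mkl,
        "overlap_percent": ranking_overlap(rank_diff, rank_mkl, top_k),
        "difference_matrix": t,
        "weight_matrix": state.b,
    }
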