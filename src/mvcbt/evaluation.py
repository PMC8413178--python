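"""Template centeredness metrics, fold protocol and significance testing.

A template is "centered" for a population when its average Frobenius
distance to every subject's network in every view is small and its average
matrix-wide Pearson correlation is high.  For method comparison, templates
are re-estimated per cross-validation fold and the fold-wise Frobenius
distances are normalized to ``(d - mean) / (max - mean) + 1.5`` before a
two-tailed paired t-test across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .networks import MultiViewPopulation

__all__ = [
    "frobenius_distance",
    "pearson_correlation",
    "CenterednessReport",
    "centeredness_report",
    "normalize_fold_distance",
    "kfold_split",
    "paired_two_tailed_ttest",
]


def frobenius_distance(g, h) -> float:
    """sqrt of the sum of squared entrywise differences."""
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != h.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {h.shape}")
    return float(np.sqrt(np.sum((g - h) ** 2)))


def pearson_correlation(g, h, *, upper_triangle_only: bool = False) -> float:
    """Pearson correlation between two matrices over all entries.

    Means are taken matrix-wide; with ``upper_triangle_only`` the strict
    upper triangles are correlated instead.
    """
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != h.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {h.shape}")
    if upper_triangle_only:
        iu = np.triu_indices(g.shape[0], k=1)
        gv, hv = g[iu], h[iu]
    else:
        gv, hv = g.ravel(), h.ravel()
    gd = gv - gv.mean()
    hd = hv - hv.mean()
    denom = np.sqrt(np.sum(gd**2) * np.sum(hd**2))
    if denom == 0:
        raise ValueError("Pearson correlation undefined for a constant matrix")
    return float(np.sum(gd * hd) / denom)


@dataclass
class CenterednessReport:
    """Per-view and averaged distance/correlation of a template to a population."""

    per_view_frobenius: np.ndarray
    mean_frobenius: float
    per_view_pearson: np.ndarray
    mean_pearson: float


def centeredness_report(cbt, population, *, upper_triangle_only: bool = False) -> CenterednessReport:
    """Average Frobenius distance and Pearson correlation of a template.

    For each view the template is compared to every subject's network and
    the per-view means are averaged across views.
    """
    nets = population.networks if isinstance(population, MultiViewPopulation) else np.asarray(population, dtype=float)
    cbt = np.asarray(cbt, dtype=float)
    n, m = nets.shape[0], nets.shape[1]
    frob = np.empty(m)
    pear = np.empty(m)
    for view in range(m):
        frob[view] = np.mean([frobenius_distance(cbt, nets[i, view]) for i in range(n)])
        pear[view] = np.mean(
            [
                pearson_correlation(cbt, nets[i, view], upper_triangle_only=upper_triangle_only)
                for i in range(n)
            ]
        )
    return CenterednessReport(
        per_view_frobenius=frob,
        mean_frobenius=float(frob.mean()),
        per_view_pearson=pear,
        mean_pearson=float(pear.mean()),
    )


def normalize_fold_distance(d_f: float, fold_mean: float, fold_max: float) -> float:
    """Fold-wise normalized distance ``(d_F - mean)/(max - mean) + 1.5``."""
    if fold_max < fold_mean:
        raise ValueError("fold_max must be >= fold_mean")
    if fold_max == fold_mean:
        warnings.warn("all methods equal within fold; normalized distance is 1.5", RuntimeWarning)
        return 1.5
    return (d_f - fold_mean) / (fold_max - fold_mean) + 1.5


def kfold_split(n_subjects: int, k: int, seed: int | None = None) -> np.ndarray:
    """Seeded random partition into K folds with sizes differing by <= 1.

    Returns a length-``n_subjects`` array of fold indices in ``0..k-1``.
    """
    if k < 1 or k > n_subjects:
        raise ValueError(f"k must be in 1..{n_subjects}, got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    folds = np.empty(n_subjects, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def paired_two_tailed_ttest(a, b) -> tuple[float, float]:
    """Paired two-sided t-test on matched samples; returns ``(t, p)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ValueError("paired t-test undefined: differences have zero variance")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
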