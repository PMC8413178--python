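"""Seeded synthetic multi-view network populations with planted structure.

The generator emulates the data regime the pipeline targets: each subject
carries M morphological networks over a shared ROI set, subjects fall into
planted clusters whose partition is shared across views (optionally with one
"differential" view whose partition is independently shuffled), and a second
group can carry a planted attribute shift on designated ROIs.

Effects are injected at the ROI-mean level — cluster centroids are ROI-mean
vectors, subjects add Gaussian within-cluster noise, and networks are built
as absolute mean differences — so planted group differences propagate into
edges exactly as real attribute differences would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import MultiViewPopulation, build_cmn

__all__ = ["SyntheticConfig", "PlantedTruth", "simulate_population", "simulate_two_groups"]

#: Baseline ROI mean (attribute units); roughly a cortical-thickness scale.
_BASE_MEAN = 2.5


@dataclass
class SyntheticConfig:
    """Generator settings.

    Parameters
    ----------
    n_subjects, n_views, n_rois, n_clusters : population dimensions.
    within_noise : float
        Standard deviation of the per-subject Gaussian perturbation of its
        cluster centroid (attribute units).
    cluster_separation : float
        Scale of the centroid spread: each cluster centroid's ROI means are
        drawn as ``base + separation * N(0, 1)``, so typical centroid
        distances grow linearly with it.
    differential_view : int or None
        Index of a view whose planted partition is an independent shuffle of
        the shared one (view-specific cluster structure).
    group_effect_rois : tuple of int
        0-based ROI indices carrying the planted group effect.
    effect_size : float
        Attribute shift added to those ROIs' means in group B.
    seed : int or None
    """

    n_subjects: int = 60
    n_views: int = 3
    n_rois: int = 35
    n_clusters: int = 3
    within_noise: float = 0.05
    cluster_separation: float = 0.5
    differential_view: int | None = None
    group_effect_rois: tuple[int, ...] = ()
    effect_size: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_subjects:
            raise ValueError("n_clusters cannot exceed n_subjects")
        if min(self.within_noise, self.cluster_separation, self.effect_size) < 0:
            raise ValueError("noise, separation and effect size must be non-negative")
        if any(r < 0 or r >= self.n_rois for r in self.group_effect_rois):
            raise ValueError("group_effect_rois must be 0-based indices in 0..n_rois-1")
        if self.differential_view is not None and not (
            0 <= self.differential_view < self.n_views
        ):
            raise ValueError("differential_view out of range")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated population."""

    labels: np.ndarray  # (n_views, n_subjects) planted partition per view
    discriminative_rois: tuple[int, ...] = ()
    centroids: np.ndarray | None = None  # (n_views, n_clusters, n_rois)
    extra: dict = field(default_factory=dict)


def _balanced_labels(n_subjects: int, n_clusters: int, rng) -> np.ndarray:
    labels = np.arange(n_subjects) % n_clusters
    return rng.permutation(labels)


def _draw_centroids(config: SyntheticConfig, rng) -> np.ndarray:
    return _BASE_MEAN + config.cluster_separation * rng.standard_normal(
        (config.n_views, config.n_clusters, config.n_rois)
    )


def _roi_means(config: SyntheticConfig, rng, centroids=None, shift=None):
    """Per-view planted labels, centroids and subject-level ROI means."""
    base_labels = _balanced_labels(config.n_subjects, config.n_clusters, rng)
    labels = np.tile(base_labels, (config.n_views, 1))
    if config.differential_view is not None:
        labels[config.differential_view] = rng.permutation(base_labels)
    if centroids is None:
        centroids = _draw_centroids(config, rng)
    means = np.empty((config.n_subjects, config.n_views, config.n_rois))
    for v in range(config.n_views):
        means[:, v] = centroids[v, labels[v]] + config.within_noise * rng.standard_normal(
            (config.n_subjects, config.n_rois)
        )
    if shift is not None:
        means += shift[None, None, :]
    return labels, centroids, means


def _population_from_means(means: np.ndarray, prefix: str = "s") -> MultiViewPopulation:
    n, m, _ = means.shape
    nets = np.stack([[build_cmn(means[i, v]) for v in range(m)] for i in range(n)])
    return MultiViewPopulation(networks=nets, subject_ids=[f"{prefix}{i:03d}" for i in range(n)])


def simulate_population(config: SyntheticConfig) -> tuple[MultiViewPopulation, PlantedTruth]:
    """Single population with planted (possibly view-differential) clusters."""
    rng = np.random.default_rng(config.seed)
    labels, centroids, means = _roi_means(config, rng)
    pop = _population_from_means(means)
    return pop, PlantedTruth(labels=labels, centroids=centroids)


def simulate_two_groups(
    config: SyntheticConfig,
) -> tuple[MultiViewPopulation, MultiViewPopulation, PlantedTruth]:
    """Two populations differing by a planted ROI-mean shift in group B.

    Both groups share the same planted cluster centroids (two human
    populations share the same underlying brain organization); group B adds
    ``effect_size`` to the ROI means of ``group_effect_rois`` in every view,
    shifting every edge incident to those ROIs.  Subject-level noise is drawn
    independently per group, so with ``effect_size=0`` the groups are
    independent draws from one process and the cumulative template
    difference carries no planted structure.
    """
    rng = np.random.default_rng(config.seed)
    shift = np.zeros(config.n_rois)
    shift[list(config.group_effect_rois)] = config.effect_size

    centroids = _draw_centroids(config, rng)
    labels_a, cents_a, means_a = _roi_means(config, rng, centroids=centroids)
    labels_b, _, means_b = _roi_means(config, rng, centroids=centroids, shift=shift)
    pop_a = _population_from_means(means_a, prefix="a")
    pop_b = _population_from_means(means_b, prefix="b")
    truth = PlantedTruth(
        labels=labels_a,
        discriminative_rois=tuple(config.group_effect_rois),
        centroids=cents_a,
        extra={"labels_b": labels_b},
    )
    return pop_a, pop_b, truth
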