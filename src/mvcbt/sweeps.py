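"""Parameter and view-subset sweeps of template centeredness."""

from __future__ import annotations

from itertools import combinations
import warnings

import pandas as pd

from .evaluation import centeredness_report
from .networks import MultiViewPopulation
from .templates import MVCFNet

__all__ = ["parameter_sweep", "view_subset_sweep"]


def parameter_sweep(
    population: MultiViewPopulation,
    n_clusters_grid=range(2, 16),
    k_neighbors_grid=(5, 10, 15, 20),
    seed: int | None = None,
    **params,
) -> pd.DataFrame:
    """Grid-search mean Frobenius distance / Pearson correlation.

    Runs the full pipeline for every ``(n_clusters, k_neighbors)``
    combination and evaluates the resulting template against the whole
    population.  Combinations with ``n_clusters >= n_subjects`` or
    ``k_neighbors >= n_subjects`` are skipped with a warning.
    """
    rows = []
    n = population.n_subjects
    for nc in n_clusters_grid:
        for kn in k_neighbors_grid:
            if nc >= n or kn >= n:
                warnings.warn(
                    f"skipping n_clusters={nc}, k_neighbors={kn} (population size {n})",
                    RuntimeWarning,
                )
                continue
            est = MVCFNet(n_clusters=nc, k_neighbors=kn, random_state=seed, **params).fit(
                population
            )
            rep = centeredness_report(est.cbt_, population)
            rows.append(
                {
                    "n_clusters": nc,
                    "k_neighbors": kn,
                    "mean_frobenius": rep.mean_frobenius,
                    "mean_pearson": rep.mean_pearson,
                }
            )
    return pd.DataFrame(rows)


def view_subset_sweep(
    population: MultiViewPopulation,
    seed: int | None = None,
    **params,
) -> pd.DataFrame:
    """Centeredness for every view combination of every size >= 2.

    For each subset size, every combination of views is evaluated
    (template estimated on the subset, compared against the subset) and the
    mean and standard deviation per size are reported alongside the
    per-combination rows.
    """
    m = population.n_views
    if m < 2:
        raise ValueError("need at least two views for a subset sweep")
    rows = []
    for size in range(2, m + 1):
        for combo in combinations(range(m), size):
            sub = population.view_subset(combo)
            est = MVCFNet(random_state=seed, **params).fit(sub)
            rep = centeredness_report(est.cbt_, sub)
            rows.append(
                {
                    "n_views": size,
                    "views": "+".join(population.view_ids[v] for v in combo),
                    "mean_frobenius": rep.mean_frobenius,
                    "mean_pearson": rep.mean_pearson,
                }
            )
    return pd.DataFrame(rows)
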