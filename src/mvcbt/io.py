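"""Population directory I/O and run configuration.

A population lives in a directory of tab-delimited square matrix files, one
per subject per view, named ``<subject>__<view>.tsv``, plus a ``manifest.tsv``
listing each subject's id, optional group label, and per-view file paths
(relative to the manifest).  ROI indices are 1-based in files and 0-based in
memory.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import MultiViewPopulation, check_morph_network, compute_roi_means

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_population",
    "write_population",
    "read_vertex_table",
]


@dataclass
class RunConfig:
    """Pipeline defaults: N_c=3, K_n=5, N_t=20, beta=1, K=5 folds."""

    n_clusters: int = 3
    k_neighbors: int = 5
    snf_iterations: int = 20
    beta: float = 1.0
    folds: int = 5
    top_k: int = 15
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-8
    snf_row_norm: str = "reference"
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_clusters", "k_neighbors", "snf_iterations", "folds", "top_k", "max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def estimator_params(self) -> dict:
        """Keyword arguments for :class:`~mvcbt.templates.MVCFNet`."""
        return dict(
            n_clusters=self.n_clusters,
            k_neighbors=self.k_neighbors,
            snf_iterations=self.snf_iterations,
            beta=self.beta,
            snf_row_norm=self.snf_row_norm,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.seed,
        )

    def as_dict(self) -> dict:
        return asdict(self)


def read_matrix(path, *, header: bool = False) -> np.ndarray:
    """Read a tab-delimited square matrix (no headers by default)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    if header:
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", header=None)
    x = df.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got shape {x.shape}")
    return x


def write_matrix(path, matrix, *, float_format: str = "%.17g") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt=float_format)


def read_population(manifest_path, *, header: bool = False) -> MultiViewPopulation:
    """Load a population from a manifest.

    The manifest is tab-delimited with columns ``subject``, optionally
    ``group``, and one column per view holding matrix file paths relative to
    the manifest's directory.  Every subject must have every view; matrices
    must share size and be symmetric within tolerance.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, sep="\t", comment="#")
    if "subject" not in df.columns:
        raise ValueError(f"{manifest_path}: manifest needs a 'subject' column")
    view_cols = [c for c in df.columns if c not in ("subject", "group")]
    if not view_cols:
        raise ValueError(f"{manifest_path}: manifest lists no view columns")
    if df[view_cols].isna().any().any():
        bad = df.loc[df[view_cols].isna().any(axis=1), "subject"].iloc[0]
        raise ValueError(f"{manifest_path}: subject {bad!r} is missing a view entry")
    root = manifest_path.parent
    nets = []
    n_rois = None
    for _, row in df.iterrows():
        per_view = []
        for col in view_cols:
            fpath = root / str(row[col])
            x = read_matrix(fpath, header=header)
            x = check_morph_network(x, name=str(fpath))
            if n_rois is None:
                n_rois = x.shape[0]
            elif x.shape[0] != n_rois:
                raise ValueError(
                    f"{fpath}: inconsistent matrix size {x.shape[0]} (expected {n_rois})"
                )
            per_view.append(x)
        nets.append(per_view)
    groups = df["group"].to_numpy() if "group" in df.columns else None
    return MultiViewPopulation(
        networks=np.asarray(nets),
        subject_ids=[str(s) for s in df["subject"]],
        view_ids=view_cols,
        groups=groups,
    )


def write_population(population: MultiViewPopulation, out_dir) -> Path:
    """Write a population directory + manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(population.subject_ids):
        row = {"subject": sid}
        if population.groups is not None:
            row["group"] = population.groups[i]
        for v, vid in enumerate(population.view_ids):
            fname = f"{sid}__{vid}.tsv"
            write_matrix(out_dir / fname, population.networks[i, v])
            row[vid] = fname
        rows.append(row)
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_vertex_table(path, n_rois: int | None = None) -> np.ndarray:
    """ROI means from a two-column (roi_label, value) vertex table.

    ROI labels are 1-based; a header row is detected automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vertex table not found: {path}")
    first = path.read_text().lstrip().splitlines()[0]
    has_header = any(c.isalpha() for c in first.split("\t")[0] + first.split("\t")[-1])
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (roi_label, value)")
    labels = df.iloc[:, 0].to_numpy(dtype=int)
    values = df.iloc[:, 1].to_numpy(dtype=float)
    if n_rois is None:
        n_rois = int(labels.max())
    return compute_roi_means(values, labels, n_rois)
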