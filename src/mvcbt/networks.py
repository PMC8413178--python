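"""Cortical morphological networks (CMNs) and their vector codecs.

A CMN encodes one cortical attribute (e.g. mean thickness, sulcal depth) of
one subject as a complete graph over ``n_rois`` cortical regions: the edge
``(i, j)`` is the absolute difference of the attribute's ROI-wise means,
``|mc_i - mc_j|``.  Every network is therefore symmetric, non-negative and
zero on the diagonal.  Populations of such networks, one per subject per
attribute ("view"), are the input to template estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiViewPopulation",
    "SYMMETRY_RTOL",
    "compute_roi_means",
    "build_cmn",
    "vectorize",
    "antivectorize",
    "check_morph_network",
]

#: Relative symmetry tolerance: max|X - X.T| <= SYMMETRY_RTOL * max|X|.
SYMMETRY_RTOL = 1e-8


@dataclass
class MultiViewPopulation:
    """N subjects x M views of morphological networks with a shared ROI set.

    Parameters
    ----------
    networks : ndarray of shape (n_subjects, n_views, n_rois, n_rois)
        Stacked symmetric, non-negative, zero-diagonal matrices.
    subject_ids, view_ids : list of str, optional
        Identifiers; generated as ``s000..`` / ``view0..`` when omitted.
    roi_names : list of str, optional
    groups : ndarray of str, optional
        Per-subject group label (e.g. ``"A"`` / ``"B"``).
    """

    networks: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    view_ids: list[str] = field(default_factory=list)
    roi_names: list[str] | None = None
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.networks = np.asarray(self.networks, dtype=float)
        if self.networks.ndim != 4:
            raise ValueError(
                "networks must have shape (n_subjects, n_views, n_rois, n_rois), "
                f"got ndim={self.networks.ndim}"
            )
        n, m, r1, r2 = self.networks.shape
        if r1 != r2:
            raise ValueError(f"network matrices must be square, got {r1}x{r2}")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:03d}" for i in range(n)]
        if not self.view_ids:
            self.view_ids = [f"view{m_i}" for m_i in range(m)]
        if len(self.subject_ids) != n or len(self.view_ids) != m:
            raise ValueError("subject_ids / view_ids lengths do not match networks")

    @property
    def n_subjects(self) -> int:
        return self.networks.shape[0]

    @property
    def n_views(self) -> int:
        return self.networks.shape[1]

    @property
    def n_rois(self) -> int:
        return self.networks.shape[2]

    def subset(self, subject_idx) -> "MultiViewPopulation":
        """Population restricted to the given subject indices."""
        subject_idx = np.asarray(subject_idx)
        return MultiViewPopulation(
            networks=self.networks[subject_idx],
            subject_ids=[self.subject_ids[i] for i in subject_idx],
            view_ids=list(self.view_ids),
            roi_names=self.roi_names,
            groups=None if self.groups is None else np.asarray(self.groups)[subject_idx],
        )

    def view_subset(self, view_idx) -> "MultiViewPopulation":
        """Population restricted to the given view indices."""
        view_idx = list(view_idx)
        return MultiViewPopulation(
            networks=self.networks[:, view_idx],
            subject_ids=list(self.subject_ids),
            view_ids=[self.view_ids[m] for m in view_idx],
            roi_names=self.roi_names,
            groups=self.groups,
        )


def compute_roi_means(values, roi_labels, n_rois: int) -> np.ndarray:
    """Mean attribute value per ROI.

    Parameters
    ----------
    values : array-like of shape (n_vertices,)
        Per-vertex scalar measurement (attribute units, e.g. mm).
    roi_labels : array-like of shape (n_vertices,)
        1-based ROI index of each vertex.
    n_rois : int
        Number of ROIs; every index in ``1..n_rois`` must occur.

    Returns
    -------
    ndarray of shape (n_rois,)
        Entry ``i`` is the arithmetic mean over vertices labelled ``i + 1``.
    """
    values = np.asarray(values, dtype=float)
    roi_labels = np.asarray(roi_labels, dtype=int)
    if values.shape != roi_labels.shape or values.ndim != 1:
        raise ValueError("values and roi_labels must be 1-D arrays of equal length")
    if roi_labels.size and (roi_labels.min() < 1 or roi_labels.max() > n_rois):
        raise ValueError("roi_labels must lie in 1..n_rois")
    counts = np.bincount(roi_labels - 1, minlength=n_rois)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"ROI {empty[0] + 1} has no vertices")
    sums = np.bincount(roi_labels - 1, weights=values, minlength=n_rois)
    return sums / counts


def build_cmn(roi_means) -> np.ndarray:
    """Morphological network from ROI means: edge ``(i, j) = |mc_i - mc_j|``."""
    roi_means = np.asarray(roi_means, dtype=float)
    if roi_means.ndim != 1 or roi_means.size < 2:
        raise ValueError("roi_means must be a 1-D vector with at least 2 ROIs")
    net = np.abs(roi_means[:, None] - roi_means[None, :])
    np.fill_diagonal(net, 0.0)
    return net


def check_morph_network(matrix, *, name: str = "network") -> np.ndarray:
    """Validate and symmetrize a single network matrix.

    Inputs within the relative symmetry tolerance are symmetrized as
    ``(X + X.T) / 2``; larger asymmetry is an error.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {x.shape}")
    scale = np.abs(x).max() if x.size else 0.0
    asym = np.abs(x - x.T).max() if x.size else 0.0
    if asym > SYMMETRY_RTOL * max(scale, 1e-300):
        raise ValueError(f"{name} is asymmetric beyond tolerance (max|X-X.T|={asym:g})")
    return (x + x.T) / 2.0


def vectorize(net) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major.

    Ordering is ``(0,1), (0,2), ..., (0,R-1), (1,2), ...`` and is shared by
    :func:`antivectorize` and the SVM weight anti-linearization.
    """
    net = check_morph_network(net)
    r = net.shape[0]
    iu = np.triu_indices(r, k=1)
    return net[iu]


def antivectorize(vec, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: symmetric zero-diagonal matrix."""
    vec = np.asarray(vec, dtype=float)
    expected = n_rois * (n_rois - 1) // 2
    if vec.ndim != 1 or vec.size != expected:
        raise ValueError(
            f"vector length {vec.size} does not match n_rois={n_rois} "
            f"(expected {expected})"
        )
    out = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    out[iu] = vec
    out += out.T
    return out
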