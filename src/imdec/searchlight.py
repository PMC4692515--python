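"""Volumetric searchlight information mapping.

A sphere of integer voxel offsets (inclusive Euclidean boundary; 257
voxels at radius 4) is moved over every center voxel of a ribbon mask.
The sphere's in-volume voxels form the feature set for a leave-one-run-out
decoding *without* voxel pre-selection and without permutation testing;
each center stores its mean accuracy and pooled confusion matrix.
Significance per center comes from a Pearson chi-square test of the
4 x 4 confusion table, thresholded over centers by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .containers import BOLDDataset, EventTable, StatMap, TrialFeatureMatrix, VolumeMask
from .decode import cross_validate
from .preprocess import extract_trial_features

__all__ = [
    "SphereSpec",
    "sphere_offsets",
    "run_searchlight",
    "SearchlightResult",
    "chisq_confusion",
    "fdr_mask",
    "cluster_filter",
]


@dataclass
class SphereSpec:
    """Integer offsets of a searchlight sphere of the given voxel radius."""

    radius_voxels: int
    offsets: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.offsets)


def sphere_offsets(radius_voxels: int) -> SphereSpec:
    """All integer (di, dj, dk) with di^2 + dj^2 + dk^2 <= radius^2.

    The inclusive Euclidean boundary in voxel units gives 257 offsets at
    radius 4.  Offsets are in lexicographic order and include (0, 0, 0).
    """
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius_voxels)
    rng = np.arange(-r, r + 1)
    di, dj, dk = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = di**2 + dj**2 + dk**2 <= r**2
    offsets = np.column_stack([di[keep], dj[keep], dk[keep]])
    return SphereSpec(r, offsets)


@dataclass
class SearchlightResult:
    """Per-center searchlight outputs on the ribbon.

    ``accuracy`` is a :class:`StatMap` of mean CV accuracies (NaN outside
    swept centers); ``confusions`` maps center index tuples to pooled
    4 x 4 confusion matrices.
    """

    accuracy: StatMap
    confusions: dict[tuple[int, int, int], np.ndarray] = field(repr=False)
    classes: np.ndarray = field(default_factory=lambda: np.arange(1, 5))

    @property
    def n_centers(self) -> int:
        return len(self.confusions)

    def chi_square_maps(self) -> tuple[StatMap, StatMap]:
        """Chi-square statistic and p-value maps over all swept centers."""
        chi = np.full(self.accuracy.values.shape, np.nan)
        p = np.full(self.accuracy.values.shape, np.nan)
        for center, conf in self.confusions.items():
            c2, _, pv = chisq_confusion(conf)
            chi[center] = c2
            p[center] = pv
        return StatMap(chi, "chi2"), StatMap(p, "p")

    def significant(self, q: float = 0.05) -> StatMap:
        """FDR-thresholded significance mask of the chi-square map."""
        _, pmap = self.chi_square_maps()
        return fdr_mask(pmap, q=q)


def run_searchlight(
    dataset: BOLDDataset,
    events: EventTable,
    ribbon: VolumeMask,
    sphere: SphereSpec | int = 4,
    C: float = 1.0,
    strict_members: bool = False,
) -> SearchlightResult:
    """Sweep the sphere over every ribbon voxel and decode its feature set.

    ``dataset`` must already be preprocessed (filtered and z-scored).
    Sphere members are any in-volume voxels at the sphere offsets — only
    the *center* must lie in the ribbon — unless ``strict_members`` also
    restricts members to the ribbon.  Spheres are clipped at the volume
    border.  Decoding is the standard leave-one-run-out pipeline with no
    feature selection and no permutation test.
    """
    if isinstance(sphere, int):
        sphere = sphere_offsets(sphere)
    if ribbon.grid.shape != dataset.shape:
        raise ValueError("ribbon mask shape does not match the dataset grid")
    if ribbon.n_voxels == 0:
        raise ValueError("ribbon mask is empty")
    shape = np.asarray(dataset.shape)
    if 2 * sphere.radius_voxels + 1 > shape.max():
        raise ValueError("sphere diameter exceeds the volume along every axis")

    # Features for every voxel once; spheres then select columns.
    features = extract_trial_features(dataset, events)
    col_of = np.full(dataset.shape, -1, dtype=int)
    vi = features.voxel_index
    col_of[vi[:, 0], vi[:, 1], vi[:, 2]] = np.arange(features.n_voxels)

    acc = np.full(dataset.shape, np.nan)
    confusions: dict[tuple[int, int, int], np.ndarray] = {}
    classes = features.classes
    for center in ribbon.indices():
        members = center + sphere.offsets
        inside = np.all((members >= 0) & (members < shape), axis=1)
        members = members[inside]
        if strict_members:
            members = members[ribbon.grid[members[:, 0], members[:, 1], members[:, 2]]]
        cols = col_of[members[:, 0], members[:, 1], members[:, 2]]
        cols = np.sort(cols[cols >= 0])
        result = cross_validate(features.select_voxels(cols), n_features=None, C=C)
        key = tuple(int(c) for c in center)
        acc[key] = result.mean_accuracy
        confusions[key] = result.confusion
    return SearchlightResult(
        accuracy=StatMap(acc, "accuracy", voxel_size_mm=dataset.voxel_size_mm),
        confusions=confusions,
        classes=classes,
    )


def chisq_confusion(confusion: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a confusion matrix.

    Expected counts come from the row/column margins; df is fixed by the
    table size ((R-1)(C-1) = 9 for 4 classes).  Cells in an all-zero
    predicted column contribute nothing (their observed counts are
    necessarily zero), which scipy's contingency test would reject — a
    class that is never predicted is legitimate classifier behaviour.
    An all-zero *row* (a class never tested) is an error.
    """
    obs = np.asarray(confusion, dtype=float)
    if obs.ndim != 2:
        raise ValueError("confusion matrix must be 2D")
    total = obs.sum()
    if total <= 0:
        raise ValueError("confusion matrix has zero total count")
    row = obs.sum(axis=1)
    colsum = obs.sum(axis=0)
    if np.any(row == 0):
        raise ValueError("confusion matrix has an all-zero row (class never tested)")
    expected = np.outer(row, colsum) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - expected) ** 2 / expected
    terms[expected == 0] = 0.0
    chi2 = float(terms.sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def fdr_mask(p_map: StatMap, q: float = 0.05) -> StatMap:
    """Benjamini-Hochberg step-up over all swept centers.

    True where the BH-adjusted p falls below ``q``; NaN cells (outside
    the sweep) stay undefined in the returned mask map.
    """
    vals = p_map.values
    defined = np.isfinite(vals)
    if not defined.any():
        raise ValueError("p map has no defined centers")
    p = vals[defined]
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    out = np.full(vals.shape, np.nan)
    out[defined] = reject.astype(float)
    return StatMap(out, "mask", voxel_size_mm=p_map.voxel_size_mm)


def cluster_filter(mask: StatMap, min_voxels: int) -> StatMap:
    """Drop connected components (6-connectivity) below ``min_voxels``.

    A volumetric stand-in for surface cluster-size thresholding; off by
    default in the pipeline.
    """
    grid = np.nan_to_num(mask.values) > 0
    labeled, n = ndimage.label(grid, structure=ndimage.generate_binary_structure(3, 1))
    keep = np.zeros_like(grid)
    for lab in range(1, n + 1):
        comp = labeled == lab
        if comp.sum() >= min_voxels:
            keep |= comp
    out = np.where(np.isfinite(mask.values), keep.astype(float), np.nan)
    return StatMap(out, "mask", voxel_size_mm=mask.voxel_size_mm)
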