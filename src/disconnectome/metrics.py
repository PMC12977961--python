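"""The disconnectome core.

Quantifies how a resection cavity relates to a white-matter fibre bundle in
three complementary ways:

* **virtual lesion** — the fraction of a subject's own preoperative
  streamlines that traverse the resection mask (``transection_fraction``);
  the surviving streamlines are a proxy for postoperative tractography;
* **atlas-based** — the maximum cohort-atlas probability over resected
  voxels (``disconnection_probability``), the Tractotron rule: a single
  resected voxel overlapping 50% of the cohort's bundle reconstructions is
  sufficient for a 50% disconnection probability, independent of how many
  voxels overlap;
* **volumetric** — remaining bundle-mask volume normalized by intracranial
  volume and min-max rescaled across the cohort.

Also provides per-bundle visitation/probability maps and median
microstructure (FA/MD) extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import streamline_voxels
from .io import BinaryMask, TractBundle, VolumeGrid

__all__ = [
    "TransectionResult",
    "ProbabilisticAtlas",
    "DisconnectionResult",
    "streamline_visitation",
    "bundle_probability_map",
    "threshold_map",
    "transection_fraction",
    "build_atlas",
    "disconnection_probability",
    "tract_volume_metrics",
    "cohort_rescale",
    "tract_median_metric",
]


@dataclass
class TransectionResult:
    """Streamline counts before/after virtual lesioning."""

    n_pre: int
    n_post: int

    @property
    def n_cut(self) -> int:
        return self.n_pre - self.n_post

    @property
    def percent_cut(self) -> float:
        """100 * (n_pre - n_post) / n_pre, in %."""
        return 100.0 * (self.n_pre - self.n_post) / self.n_pre


@dataclass
class ProbabilisticAtlas:
    """Cohort overlap atlas: per-voxel fraction of subjects whose bundle
    mask covers the voxel (0 = none, 1 = all)."""

    grid: VolumeGrid
    n_subjects: int


@dataclass
class DisconnectionResult:
    probability: float
    threshold: float = 0.5

    @property
    def disconnected(self) -> int:
        # a tie at the threshold counts as disconnected (>=)
        return int(self.probability >= self.threshold)


def _check_same_grid(a: VolumeGrid, b: VolumeGrid, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError(f"{what}: affine mismatch")


def streamline_visitation(
    bundle: TractBundle,
    grid: VolumeGrid,
    step: float | None = None,
    method: str = "exact",
) -> VolumeGrid:
    """Per-voxel count of distinct streamlines visiting each voxel."""
    if bundle.count == 0:
        raise ValueError("cannot compute visitation of an empty bundle")
    if step is not None and step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    counts = np.zeros(grid.shape, dtype=np.int64)
    for sl in bundle:
        idx = streamline_voxels(sl, grid, method=method, step=step)
        if len(idx):
            counts[idx[:, 0], idx[:, 1], idx[:, 2]] += 1
    return grid.like(counts)


def bundle_probability_map(
    bundle: TractBundle,
    grid: VolumeGrid,
    step: float | None = None,
    method: str = "exact",
) -> VolumeGrid:
    """Visitation counts divided by streamline count; values in [0, 1]."""
    visits = streamline_visitation(bundle, grid, step=step, method=method)
    return grid.like(visits.data / bundle.count)


def threshold_map(prob_map: VolumeGrid, threshold: float = 0.01) -> BinaryMask:
    """Zero values below threshold, binarize the rest."""
    return BinaryMask((prob_map.data >= threshold).astype(np.uint8), prob_map.affine)


def transection_fraction(
    bundle: TractBundle,
    resection: BinaryMask,
    step: float | None = None,
    method: str = "exact",
) -> TransectionResult:
    """Virtual lesion: remove streamlines traversing the resection mask.

    A streamline is cut iff it visits any set voxel of the mask; the
    percentage cut compares streamline counts before and after exclusion.
    """
    if bundle.count == 0:
        raise ValueError("transection fraction is undefined for an empty bundle")
    mask = resection.data.astype(bool)
    n_cut = 0
    for sl in bundle:
        idx = streamline_voxels(sl, resection, method=method, step=step)
        if len(idx) and mask[idx[:, 0], idx[:, 1], idx[:, 2]].any():
            n_cut += 1
    return TransectionResult(n_pre=bundle.count, n_post=bundle.count - n_cut)


def surviving_streamlines(
    bundle: TractBundle,
    resection: BinaryMask,
    step: float | None = None,
    method: str = "exact",
) -> TractBundle:
    """The estimated postoperative bundle: streamlines not traversing the mask."""
    mask = resection.data.astype(bool)
    kept = []
    for sl in bundle:
        idx = streamline_voxels(sl, resection, method=method, step=step)
        if not (len(idx) and mask[idx[:, 0], idx[:, 1], idx[:, 2]].any()):
            kept.append(sl)
    return TractBundle(kept)


def build_atlas(masks: list[BinaryMask]) -> ProbabilisticAtlas:
    """Combine per-subject bundle masks into an overlap atlas rescaled to
    [0, 1]; 1 means every subject's mask covers the voxel."""
    if len(masks) == 0:
        raise ValueError("need at least one mask to build an atlas")
    ref = masks[0]
    for i, m in enumerate(masks[1:], start=1):
        _check_same_grid(ref, m, f"atlas mask {i}")
    tally = np.zeros(ref.shape, dtype=np.int64)
    for m in masks:
        tally += m.data.astype(np.int64)
    atlas = ref.like(tally / len(masks))
    return ProbabilisticAtlas(grid=atlas, n_subjects=len(masks))


def disconnection_probability(
    resection: BinaryMask,
    atlas: ProbabilisticAtlas,
    threshold: float = 0.5,
) -> DisconnectionResult:
    """Maximum atlas probability over resected voxels (0 if disjoint).

    The value is deliberately independent of how many resected voxels
    intersect the bundle: one voxel at the maximum decides it.  The result
    is binarized at ``threshold`` (default 50%), a tie counting as
    disconnected.
    """
    _check_same_grid(resection, atlas.grid, "disconnection")
    set_vox = resection.data.astype(bool)
    prob = float(atlas.grid.data[set_vox].max()) if set_vox.any() else 0.0
    return DisconnectionResult(probability=prob, threshold=threshold)


def tract_volume_metrics(bundle_mask: BinaryMask, icv_mask: BinaryMask) -> float:
    """Bundle-mask volume normalized against intracranial volume."""
    if icv_mask.n_voxels == 0:
        raise ValueError("intracranial volume mask is empty")
    return bundle_mask.volume_mm3 / icv_mask.volume_mm3


def cohort_rescale(values) -> np.ndarray:
    """Min-max rescale a cohort's values to [0, 1] (min -> 0, max -> 1)."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        warnings.warn(
            "cohort values are constant; rescaled values set to 0", stacklevel=2
        )
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def tract_median_metric(
    bundle: TractBundle,
    scalar_map: VolumeGrid,
    step: float | None = None,
    method: str = "exact",
) -> float:
    """Median scalar value over the distinct voxels the bundle visits.

    The median (not the mean) is taken across the entire bundle to limit
    the influence of outlier voxels; each visited voxel contributes once so
    long streamlines do not overweight their voxels.
    """
    if bundle.count == 0:
        raise ValueError("median metric is undefined for an empty bundle")
    visited = np.zeros(scalar_map.shape, dtype=bool)
    for sl in bundle:
        idx = streamline_voxels(sl, scalar_map, method=method, step=step)
        if len(idx):
            visited[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if not visited.any():
        raise ValueError("bundle visits no in-bounds voxels of the scalar map")
    return float(np.median(scalar_map.data[visited]))
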