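"""Streamline geometry primitives: arc-length resampling and voxel traversal.

The voxel-membership convention everywhere is nearest-voxel: a continuous
voxel-space coordinate x belongs to voxel i iff floor(x + 0.5) == i, i.e.
voxel i owns the half-open cube [i - 0.5, i + 0.5) along each axis.

Two visitation semantics are provided:

``exact``
    the set of voxels whose cube the polyline passes through, computed by
    enumerating half-integer boundary crossings per segment.  This is the
    continuum limit of ever-denser point sampling and is independent of any
    resampling step.

``points``
    the set of voxels receiving at least one point after resampling the
    streamline to uniform arc-length spacing <= step.  With step at most
    half the smallest voxel dimension a segment cannot skip a voxel it
    passes through by more than a corner clip.
"""

from __future__ import annotations

import numpy as np

from .io import VolumeGrid, world_to_voxel_continuous

__all__ = ["resample_streamline", "polyline_voxels", "streamline_voxels"]


def resample_streamline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline to uniform arc-length spacing <= step (mm).

    Endpoints are preserved.  A zero-length streamline returns its first
    point twice.
    """
    if step <= 0:
        raise ValueError(f"resampling step must be > 0, got {step}")
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return np.repeat(pts[:1], 2, axis=0)
    n = int(np.ceil(total / step)) + 1
    t = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(t, arc, pts[:, k]) for k in range(3)])


def _segment_cells(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Integer cells crossed by the voxel-space segment p -> q (exact)."""
    d = q - p
    ts = [0.0, 1.0]
    for ax in range(3):
        if d[ax] == 0.0:
            continue
        c0 = np.floor(p[ax] + 0.5)
        c1 = np.floor(q[ax] + 0.5)
        lo, hi = (c0, c1) if c0 <= c1 else (c1, c0)
        # cell boundaries sit at half-integers k - 0.5
        for k in np.arange(lo + 1.0, hi + 1.0):
            t = (k - 0.5 - p[ax]) / d[ax]
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = np.sort(np.asarray(ts))
    mids = 0.5 * (ts[:-1] + ts[1:])
    cells = np.floor(p[None, :] + mids[:, None] * d[None, :] + 0.5)
    return cells.astype(np.int64)


def polyline_voxels(points_vox: np.ndarray) -> np.ndarray:
    """Unique integer voxel indices a voxel-space polyline passes through."""
    pts = np.asarray(points_vox, dtype=float)
    chunks = [_segment_cells(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]
    if not chunks:
        return np.floor(pts + 0.5).astype(np.int64)
    return np.unique(np.concatenate(chunks, axis=0), axis=0)


def streamline_voxels(
    streamline: np.ndarray,
    grid: VolumeGrid,
    method: str = "exact",
    step: float | None = None,
) -> np.ndarray:
    """Unique in-bounds voxel indices visited by a world-mm streamline.

    Out-of-bounds portions of the streamline simply contribute nothing.
    ``step`` (mm) is required for ``method="points"``; it defaults to half
    the smallest voxel dimension.
    """
    vox = world_to_voxel_continuous(np.asarray(streamline, dtype=float), grid)
    if method == "exact":
        idx = polyline_voxels(vox)
    elif method == "points":
        if step is None:
            step = 0.5 * float(np.min(grid.voxel_sizes))
        if step <= 0:
            raise ValueError(f"step must be > 0, got {step}")
        # resample in world space (arc length is physical), then map
        dense = resample_streamline(np.asarray(streamline, dtype=float), step)
        dvox = world_to_voxel_continuous(dense, grid)
        idx = np.unique(np.floor(dvox + 0.5).astype(np.int64), axis=0)
    else:
        raise ValueError(f"unknown visitation method {method!r}")
    keep = np.all((idx >= 0) & (idx < np.array(grid.shape)), axis=1)
    return idx[keep]
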