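"""Volume and tractogram I/O plus the coordinate/morphology primitives.

All volumes are NIfTI-1 with a 4x4 voxel-index -> world-mm affine; all
tractograms are TCK with streamline points in scanner-space millimetres.
Every distance used internally is a physical distance in mm, never a voxel
count, so anisotropic grids behave correctly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "TractBundle",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_tractogram",
    "write_tractogram",
    "world_to_voxel",
    "voxel_to_world",
    "dilate_mask",
]


@dataclass
class VolumeGrid:
    """A 3-D scalar or label array with its voxel->world (mm) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume, got {self.data.ndim} dimensions"
            )
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular (zero voxel volume)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Physical extent of one voxel step along each axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def in_bounds(self, idx: np.ndarray) -> np.ndarray:
        """Boolean array: which integer index triples lie inside the grid."""
        idx = np.atleast_2d(idx)
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """New grid sharing this affine."""
        return VolumeGrid(data, self.affine.copy())


class BinaryMask(VolumeGrid):
    """VolumeGrid whose data are exactly 0/1 (stored as uint8)."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != np.uint8:
            # binarize at > 0.5: tolerant of interpolation artefacts from
            # cross-space registration of masks
            self.data = (np.asarray(self.data, dtype=float) > 0.5).astype(np.uint8)
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume


@dataclass
class TractBundle:
    """Ordered 3-D point sequences (world mm), one per streamline."""

    streamlines: list = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for i, s in enumerate(self.streamlines):
            pts = np.asarray(s, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3:
                raise ValueError(f"streamline {i} is not an (n, 3) point array")
            if pts.shape[0] < 2:
                raise ValueError(f"streamline {i} has fewer than 2 points")
            if not np.all(np.isfinite(pts)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            cleaned.append(pts)
        self.streamlines = cleaned

    @property
    def count(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __len__(self) -> int:
        return self.count


# ---------------------------------------------------------------------------
# file I/O


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI-1 volume; must be 3-D with an invertible affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path} is a {data.ndim}-D image; expected a 3-D volume"
        )
    return VolumeGrid(data, img.affine)


def write_volume(grid: VolumeGrid, path) -> None:
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))


def read_mask(path) -> BinaryMask:
    """Read a volume and binarize at > 0.5."""
    vol = read_volume(path)
    return BinaryMask(vol.data, vol.affine)


def read_tractogram(path) -> TractBundle:
    """Read a TCK tractogram (points already in scanner-space mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tractogram file not found: {path}")
    tck = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=float) for s in tck.streamlines]
    for i, s in enumerate(streamlines):
        if not np.all(np.isfinite(s)):
            raise ValueError(f"streamline {i} in {path} has non-finite coordinates")
    return TractBundle(streamlines)


def write_tractogram(bundle: TractBundle, path) -> None:
    """Write TCK; an empty bundle is a valid (empty) file."""
    tractogram = Tractogram(
        [np.asarray(s, dtype=np.float32) for s in bundle.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))


# ---------------------------------------------------------------------------
# coordinates


def world_to_voxel(points, grid: VolumeGrid) -> np.ndarray:
    """Map world-mm points to nearest integer voxel indices.

    Applies the inverse affine, then rounds each coordinate half-up
    (``floor(x + 0.5)``).  Indices may lie outside the grid; callers check
    bounds where it matters.
    """
    vox = world_to_voxel_continuous(points, grid)
    return np.floor(vox + 0.5).astype(np.int64)


def world_to_voxel_continuous(points, grid: VolumeGrid) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(grid.affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    return vox if np.asarray(points).ndim == 2 else vox[0]


def voxel_to_world(indices, grid: VolumeGrid) -> np.ndarray:
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    world = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return world if np.asarray(indices).ndim == 2 else world[0]


# ---------------------------------------------------------------------------
# morphology


def dilate_mask(mask: BinaryMask, radius: float) -> BinaryMask:
    """Dilate a binary mask by a physical radius in mm.

    A voxel is set iff some originally-set voxel centre lies within
    Euclidean world distance <= radius of its centre.  radius 0 is the
    identity.  Works for anisotropic and oblique affines because offsets are
    measured through the affine's linear part.
    """
    if radius < 0:
        raise ValueError(f"dilation radius must be >= 0, got {radius}")
    if radius == 0:
        return BinaryMask(mask.data.copy(), mask.affine.copy())

    lin = mask.affine[:3, :3]
    # smallest voxel step bounds how far (in index units) the radius reaches
    step = np.linalg.norm(lin, axis=0)
    reach = [int(np.floor(radius / s + 1e-9)) for s in step]
    offsets = []
    for off in itertools.product(*(range(-r, r + 1) for r in reach)):
        if np.linalg.norm(lin @ np.array(off, dtype=float)) <= radius + 1e-12:
            offsets.append(off)
    structure = np.zeros([2 * r + 1 for r in reach], dtype=bool)
    for off in offsets:
        structure[tuple(np.array(off) + reach)] = True
    dilated = ndimage.binary_dilation(mask.data.astype(bool), structure=structure)
    return BinaryMask(dilated.astype(np.uint8), mask.affine.copy())
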