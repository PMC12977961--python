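import numpy as np
import pytest

from disconnectome import BinaryMask, TractBundle, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def unit_grid():
    """16^3 grid, 1 mm isotropic, identity affine."""
    return VolumeGrid(np.zeros((16, 16, 16)), np.eye(4))


def random_bundle(rng, n_streamlines: int, extent: float, n_eval: int = 40) -> TractBundle:
    """Smooth random cubic-Bezier streamlines spanning a cube of given extent."""
    sls = []
    t = np.linspace(0.0, 1.0, n_eval)
    basis = np.stack([(1 - t) ** 3, 3 * t * (1 - t) ** 2, 3 * t**2 * (1 - t), t**3])
    for _ in range(n_streamlines):
        ctrl = rng.uniform(-2.0, extent + 2.0, size=(4, 3))
        sls.append(basis.T @ ctrl)
    return TractBundle(sls)


def random_blob_mask(rng, shape, affine=None, n_seeds: int = 3, radius: float = 4.0) -> BinaryMask:
    """Union of a few random balls, in world mm."""
    grid = VolumeGrid(np.zeros(shape), np.eye(4) if affine is None else affine)
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    data = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        c = rng.uniform(0, np.array(shape) * grid.voxel_sizes)
        r = rng.uniform(0.5 * radius, radius)
        data |= (np.linalg.norm(world - c, axis=1) <= r).reshape(shape)
    return BinaryMask(data.astype(np.uint8), grid.affine)


def brute_force_voxels(streamline: np.ndarray, grid: VolumeGrid) -> set:
    """Independent oracle: exact segment/box intersection for every voxel.

    A voxel index c owns the cube [c - 0.5, c + 0.5] in voxel coordinates;
    a streamline visits c iff some segment of the polyline (mapped through
    the inverse affine) intersects that cube (slab test).  This is the
    limit of dense point-sampling as the spacing goes to zero.
    """
    inv = np.linalg.inv(grid.affine)
    pts = np.asarray(streamline, float) @ inv[:3, :3].T + inv[:3, 3]
    shape = np.array(grid.shape)
    visited = set()
    for p, q in zip(pts[:-1], pts[1:]):
        d = q - p
        lo = np.floor(np.minimum(p, q) + 0.5).astype(int)
        hi = np.floor(np.maximum(p, q) + 0.5).astype(int)
        for i in range(lo[0], hi[0] + 1):
            for j in range(lo[1], hi[1] + 1):
                for k in range(lo[2], hi[2] + 1):
                    c = (i, j, k)
                    t0, t1, ok = 0.0, 1.0, True
                    for ax in range(3):
                        b0, b1 = c[ax] - 0.5, c[ax] + 0.5
                        if d[ax] == 0.0:
                            if not (b0 <= p[ax] <= b1):
                                ok = False
                                break
                        else:
                            ta = (b0 - p[ax]) / d[ax]
                            tb = (b1 - p[ax]) / d[ax]
                            if ta > tb:
                                ta, tb = tb, ta
                            t0, t1 = max(t0, ta), min(t1, tb)
                    if ok and t0 <= t1:
                        if np.all(np.array(c) >= 0) and np.all(np.array(c) < shape):
                            visited.add(c)
    return visited
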