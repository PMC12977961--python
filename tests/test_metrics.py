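"""Geometric core: visitation, virtual lesions, atlas and tract metrics."""

import numpy as np
import pytest

from disconnectome import (
    BinaryMask,
    ProbabilisticAtlas,
    TractBundle,
    VolumeGrid,
    build_atlas,
    bundle_probability_map,
    cohort_rescale,
    disconnection_probability,
    streamline_visitation,
    surviving_streamlines,
    threshold_map,
    tract_median_metric,
    tract_volume_metrics,
    transection_fraction,
)
from conftest import brute_force_voxels, random_blob_mask, random_bundle

BOTH = pytest.mark.parametrize("method", ["exact", "points"])


def straight_bundle(ys, z=5.0, x0=0.0, x1=9.0):
    return TractBundle([np.array([[x0, y, z], [x1, y, z]]) for y in ys])


class TestVisitation:
    @BOTH
    def test_straight_line_visits_its_corridor(self, method):
        grid = VolumeGrid(np.zeros((10, 10, 10)), np.eye(4))
        bundle = TractBundle([np.array([[2.0, 4.0, 4.0], [6.0, 4.0, 4.0]])])
        vis = streamline_visitation(bundle, grid, method=method)
        hit = np.argwhere(vis.data > 0)
        assert {tuple(h) for h in hit} == {(x, 4, 4) for x in range(2, 7)}
        assert vis.data.max() == 1

    @BOTH
    def test_duplicate_streamlines_double_counts(self, method):
        grid = VolumeGrid(np.zeros((10, 10, 10)), np.eye(4))
        sl = np.array([[1.0, 5.0, 5.0], [8.0, 5.0, 5.0]])
        vis = streamline_visitation(TractBundle([sl, sl.copy()]), grid, method=method)
        assert vis.data.max() == 2
        assert set(np.unique(vis.data)) == {0, 2}

    def test_empty_bundle_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="empty"):
            streamline_visitation(TractBundle([]), unit_grid)

    def test_nonpositive_step_rejected(self, unit_grid):
        bundle = TractBundle([np.array([[0.0, 0, 0], [1.0, 0, 0]])])
        with pytest.raises(ValueError, match="step"):
            streamline_visitation(bundle, unit_grid, step=0.0, method="points")

    def test_counts_match_brute_force_oracle(self, rng):
        """Exact traversal equals the independent segment/box oracle."""
        for _ in range(10):
            n = int(rng.integers(12, 24))
            grid = VolumeGrid(np.zeros((n, n, n)), np.eye(4))
            bundle = random_bundle(rng, 8, float(n))
            vis = streamline_visitation(bundle, grid, method="exact")
            expected = np.zeros(grid.shape, dtype=int)
            for sl in bundle:
                for c in brute_force_voxels(sl, grid):
                    expected[c] += 1
            np.testing.assert_array_equal(vis.data, expected)

    def test_dense_samples_are_subset_of_exact(self, rng):
        grid = VolumeGrid(np.zeros((16, 16, 16)), np.eye(4))
        bundle = random_bundle(rng, 5, 16.0)
        exact = streamline_visitation(bundle, grid, method="exact").data
        dense = streamline_visitation(bundle, grid, method="points", step=0.01).data
        assert np.all(dense <= exact)


class TestProbabilityMap:
    def test_single_visitor_fraction(self):
        grid = VolumeGrid(np.zeros((12, 12, 12)), np.eye(4))
        sls = [np.array([[1.0, y, 5.0], [10.0, y, 5.0]]) for y in range(10)]
        sls[0] = np.array([[1.0, 0.0, 9.0], [10.0, 0.0, 9.0]])  # lone corridor
        prob = bundle_probability_map(TractBundle(sls), grid)
        assert prob.data[5, 0, 9] == pytest.approx(0.1)
        assert threshold_map(prob, 0.01).data[5, 0, 9] == 1

    def test_full_overlap_gives_one(self):
        grid = VolumeGrid(np.zeros((10, 10, 10)), np.eye(4))
        sl = np.array([[1.0, 5.0, 5.0], [8.0, 5.0, 5.0]])
        prob = bundle_probability_map(TractBundle([sl] * 7), grid)
        assert prob.data.max() == pytest.approx(1.0)

    def test_threshold_rule(self):
        grid = VolumeGrid(np.array([[[0.005, 0.02]]]), np.eye(4))
        out = threshold_map(grid, 0.01)
        np.testing.assert_array_equal(out.data, np.array([[[0, 1]]]))

    def test_empty_bundle_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="empty"):
            bundle_probability_map(TractBundle([]), unit_grid)


class TestTransection:
    @BOTH
    def test_forty_percent_corridor(self, method):
        bundle = straight_bundle(np.arange(10, dtype=float))
        m = np.zeros((10, 10, 10))
        m[:, 0:4, :] = 1
        mask = BinaryMask(m, np.eye(4))
        res = transection_fraction(bundle, mask, method=method)
        assert res.percent_cut == pytest.approx(40.0)
        assert (res.n_pre, res.n_post) == (10, 6)
        assert surviving_streamlines(bundle, mask, method=method).count == 6

    def test_empty_mask_cuts_nothing(self):
        bundle = straight_bundle(np.arange(10, dtype=float))
        mask = BinaryMask(np.zeros((10, 10, 10)), np.eye(4))
        res = transection_fraction(bundle, mask)
        assert res.percent_cut == 0.0
        assert res.n_post == res.n_pre

    def test_empty_bundle_rejected(self):
        mask = BinaryMask(np.zeros((4, 4, 4)), np.eye(4))
        with pytest.raises(ValueError, match="empty bundle"):
            transection_fraction(TractBundle([]), mask)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            mask = random_blob_mask(rng, (16, 16, 16))
            bundle = random_bundle(rng, 12, 16.0)
            res = transection_fraction(bundle, mask, method="exact")
            cut = 0
            set_vox = {tuple(c) for c in np.argwhere(mask.data)}
            for sl in bundle:
                if brute_force_voxels(sl, mask) & set_vox:
                    cut += 1
            assert res.n_pre - res.n_post == cut

    def test_monotone_in_mask(self, rng):
        bundle = random_bundle(rng, 15, 16.0)
        small = random_blob_mask(rng, (16, 16, 16))
        extra = random_blob_mask(rng, (16, 16, 16))
        big = BinaryMask(np.maximum(small.data, extra.data), small.affine)
        assert (
            transection_fraction(bundle, big).percent_cut
            >= transection_fraction(bundle, small).percent_cut
        )

    def test_full_cover_cuts_everything(self, rng):
        bundle = random_bundle(rng, 10, 10.0)
        mask = BinaryMask(np.ones((14, 14, 14)), np.eye(4))
        # bundle extends slightly beyond the grid; only in-grid travel counts,
        # but every streamline crosses the full mask
        assert transection_fraction(bundle, mask).percent_cut == 100.0


class TestAtlas:
    def _mask(self, coords, shape=(6, 6, 6)):
        m = np.zeros(shape)
        for c in coords:
            m[c] = 1
        return BinaryMask(m, np.eye(4))

    def test_identical_masks_reproduce_the_mask(self):
        mask = self._mask([(1, 1, 1), (2, 2, 2)])
        atlas = build_atlas([mask, self._mask([(1, 1, 1), (2, 2, 2)])])
        np.testing.assert_array_equal(atlas.grid.data, mask.data.astype(float))

    def test_half_overlap_counting(self):
        a = self._mask([(1, 1, 1), (3, 3, 3)])
        b = self._mask([(1, 1, 1), (4, 4, 4)])
        atlas = build_atlas([a, b])
        assert atlas.grid.data[1, 1, 1] == 1.0
        assert atlas.grid.data[3, 3, 3] == 0.5
        assert atlas.grid.data[4, 4, 4] == 0.5
        assert atlas.grid.data.sum() == pytest.approx(2.0)

    def test_seven_random_masks_match_tally(self, rng):
        masks = [
            BinaryMask((rng.uniform(size=(5, 5, 5)) < 0.3).astype(np.uint8), np.eye(4))
            for _ in range(7)
        ]
        atlas = build_atlas(masks)
        tally = sum(m.data.astype(int) for m in masks)
        np.testing.assert_allclose(atlas.grid.data, tally / 7.0)
        # values are exact multiples of 1/n
        scaled = atlas.grid.data * 7.0
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = self._mask([(1, 1, 1)])
        b = BinaryMask(np.zeros((7, 6, 6)), np.eye(4))
        with pytest.raises(ValueError, match="shape mismatch"):
            build_atlas([a, b])

    def test_single_mask_is_its_own_atlas(self):
        mask = self._mask([(2, 3, 4)])
        atlas = build_atlas([mask])
        np.testing.assert_array_equal(atlas.grid.data, mask.data.astype(float))
        assert atlas.n_subjects == 1


class TestDisconnection:
    def _setup(self, mask_coords):
        data = np.zeros((6, 6, 6))
        for c, v in {(1, 1, 1): 0.20, (2, 2, 2): 0.35, (3, 3, 3): 0.50, (4, 4, 4): 0.90}.items():
            data[c] = v
        atlas = ProbabilisticAtlas(VolumeGrid(data, np.eye(4)), n_subjects=20)
        m = np.zeros((6, 6, 6))
        for c in mask_coords:
            m[c] = 1
        return BinaryMask(m, np.eye(4)), atlas

    def test_tractotron_rule_half_probability(self):
        """One resected voxel at 50% bundle probability suffices for a 50%
        disconnection probability, classified disconnected at threshold."""
        mask, atlas = self._setup([(1, 1, 1), (2, 2, 2), (3, 3, 3)])
        res = disconnection_probability(mask, atlas)
        assert res.probability == pytest.approx(0.50)
        assert res.disconnected == 1

    def test_disjoint_mask_gives_zero(self):
        mask, atlas = self._setup([(0, 5, 0)])
        res = disconnection_probability(mask, atlas)
        assert res.probability == 0.0
        assert res.disconnected == 0

    def test_max_rule(self):
        mask, atlas = self._setup([(1, 1, 1), (4, 4, 4)])
        assert disconnection_probability(mask, atlas).probability == pytest.approx(0.90)

    def test_independent_of_extra_lower_valued_overlap(self):
        lean, atlas = self._setup([(4, 4, 4)])
        fat, _ = self._setup([(1, 1, 1), (2, 2, 2), (3, 3, 3), (4, 4, 4)])
        assert (
            disconnection_probability(lean, atlas).probability
            == disconnection_probability(fat, atlas).probability
        )

    def test_monotone_in_mask(self, rng):
        data = rng.uniform(size=(8, 8, 8))
        atlas = ProbabilisticAtlas(VolumeGrid(data, np.eye(4)), n_subjects=10)
        small = (rng.uniform(size=(8, 8, 8)) < 0.1).astype(np.uint8)
        big = np.maximum(small, (rng.uniform(size=(8, 8, 8)) < 0.1).astype(np.uint8))
        p_small = disconnection_probability(BinaryMask(small, np.eye(4)), atlas).probability
        p_big = disconnection_probability(BinaryMask(big, np.eye(4)), atlas).probability
        assert p_big >= p_small

    def test_mismatched_grid_rejected(self):
        _, atlas = self._setup([])
        with pytest.raises(ValueError, match="mismatch"):
            disconnection_probability(BinaryMask(np.zeros((5, 5, 5)), np.eye(4)), atlas)


class TestVolumesAndMedians:
    def test_normalized_volume_arithmetic(self):
        bundle_data = np.zeros((10, 10, 10))
        bundle_data.flat[:100] = 1
        bundle = BinaryMask(bundle_data, np.diag([2.0, 2.0, 2.0, 1.0]))  # 100 * 8 mm^3
        icv = BinaryMask(np.ones((100, 100, 100)), np.eye(4))  # 1e6 mm^3
        assert tract_volume_metrics(bundle, icv) == pytest.approx(8.0e-4)

    def test_empty_icv_rejected(self):
        b = BinaryMask(np.ones((2, 2, 2)), np.eye(4))
        with pytest.raises(ValueError, match="intracranial"):
            tract_volume_metrics(b, BinaryMask(np.zeros((2, 2, 2)), np.eye(4)))

    def test_minmax_rescale(self):
        np.testing.assert_allclose(cohort_rescale([0.2, 0.5, 0.8]), [0.0, 0.5, 1.0])

    def test_constant_cohort_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = cohort_rescale([0.3, 0.3, 0.3])
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_median_constant_map(self, unit_grid):
        smap = unit_grid.like(np.full(unit_grid.shape, 0.7))
        bundle = TractBundle([np.array([[1.0, 5.0, 5.0], [9.0, 5.0, 5.0]])])
        assert tract_median_metric(bundle, smap) == pytest.approx(0.7)

    def test_median_two_voxels(self):
        data = np.zeros((5, 5, 5))
        data[1, 2, 2] = 0.2
        data[2, 2, 2] = 0.8
        smap = VolumeGrid(data, np.eye(4))
        bundle = TractBundle([np.array([[1.0, 2.0, 2.0], [2.0, 2.0, 2.0]])])
        assert tract_median_metric(bundle, smap) == pytest.approx(0.5)

    def test_median_matches_oracle_voxel_set(self, rng):
        for _ in range(5):
            data = rng.uniform(size=(16, 16, 16))
            smap = VolumeGrid(data, np.eye(4))
            bundle = random_bundle(rng, 8, 16.0)
            voxels = set()
            for sl in bundle:
                voxels |= brute_force_voxels(sl, smap)
            expected = np.median([data[c] for c in voxels])
            assert tract_median_metric(bundle, smap) == pytest.approx(expected)

    def test_out_of_bounds_bundle_rejected(self, unit_grid):
        bundle = TractBundle([np.array([[100.0, 100.0, 100.0], [120.0, 100.0, 100.0]])])
        with pytest.raises(ValueError, match="no in-bounds"):
            tract_median_metric(bundle, unit_grid)
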