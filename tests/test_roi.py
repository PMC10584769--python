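"""Geometric ROI operators and the declarative tract protocols."""

import numpy as np
import pytest

import tractweave as tw
from tractweave.roi import (GeometryError, ProtocolError, build_rois,
                            roi_volume_stats, select_labels, split_axis,
                            split_by_plane, union)


def _mask(shape, affine=None, fill=None):
    grid = np.zeros(shape, dtype=np.uint8)
    if fill is not None:
        grid[fill] = 1
    return tw.ScalarMap(grid, np.eye(4) if affine is None else affine,
                        role="binary")


@pytest.fixture
def two_label_volume():
    grid = np.zeros((10, 10, 10), dtype=np.int32)
    grid[1:3, 1:3, 1:3] = 1     # A: 8 voxels
    grid[6:9, 6:9, 6:9] = 2     # B: 27 voxels
    return tw.LabelVolume(grid, np.eye(4), {"A": 1, "B": 2})


class TestSelectLabels:
    def test_union_of_disjoint_labels_adds_counts(self, two_label_volume):
        m = select_labels(two_label_volume, ["A", "B"])
        assert m.voxel_count() == 8 + 27

    def test_empty_selection_gives_empty_mask(self, two_label_volume):
        assert select_labels(two_label_volume, []).voxel_count() == 0

    def test_selection_is_idempotent(self, two_label_volume):
        m1 = select_labels(two_label_volume, ["A"])
        m2 = select_labels(two_label_volume, ["A", "A"])
        assert np.array_equal(m1.grid, m2.grid)

    def test_unresolvable_name_is_protocol_error(self, two_label_volume):
        with pytest.raises(ProtocolError):
            select_labels(two_label_volume, ["missing"])


class TestSplitAxis:
    def test_anterior_half_of_cube_keeps_five_slices(self):
        m = _mask((10, 10, 10), fill=(slice(None), slice(0, 10), slice(None)))
        out = split_axis(m, "AP", "anterior", 0.5)
        # anterior = high y; 10-voxel extent, plane at centre: 5 slices kept
        kept_y = np.unique(np.argwhere(out.grid)[:, 1])
        assert list(kept_y) == [5, 6, 7, 8, 9]

    def test_fraction_zero_keeps_full_mask(self):
        m = _mask((6, 6, 6), fill=(slice(1, 5),) * 3)
        out = split_axis(m, "AP", "anterior", 0.0)
        assert np.array_equal(out.grid, m.grid)

    def test_two_sides_partition_the_mask(self):
        m = _mask((8, 8, 8), fill=(slice(0, 8), slice(1, 7), slice(2, 6)))
        ant = split_axis(m, "IS", "superior", 0.5)
        post = split_axis(m, "IS", "inferior", 0.5)
        assert not np.any(ant.grid & post.grid)
        assert np.array_equal(ant.grid | post.grid, m.grid)

    def test_posterior_third_fraction_rule(self):
        # plane at 2/3 from the anterior end: posterior third kept
        m = _mask((4, 9, 4), fill=(slice(1, 3), slice(0, 9), slice(1, 3)))
        out = split_axis(m, "AP", "posterior", 2.0 / 3.0)
        kept_y = np.unique(np.argwhere(out.grid)[:, 1])
        assert kept_y.max() <= 8.0 / 3.0 + 1e-9

    def test_empty_mask_is_geometry_error(self):
        with pytest.raises(GeometryError):
            split_axis(_mask((4, 4, 4)), "AP", "anterior")


class TestAxialSlab:
    def test_slab_centred_on_reference_midpoint(self):
        # reference spans z in [10, 20] mm; 4 mm slab keeps z in [13, 17]
        ref = _mask((4, 4, 24), fill=(1, 1, slice(10, 21)))
        m = _mask((4, 4, 24), fill=(slice(None), slice(None), slice(None)))
        out = tw.axial_slab(m, ref, 4.0)
        kept_z = np.unique(np.argwhere(out.grid)[:, 2])
        assert list(kept_z) == [13, 14, 15, 16, 17]

    def test_thick_slab_keeps_everything(self):
        ref = _mask((4, 4, 8), fill=(1, 1, 4))
        m = _mask((4, 4, 8), fill=(slice(None),) * 3)
        out = tw.axial_slab(m, ref, 100.0)
        assert np.array_equal(out.grid, m.grid)

    def test_disjoint_slab_warns_and_is_empty(self):
        ref = _mask((4, 4, 20), fill=(1, 1, 0))
        m = _mask((4, 4, 20), fill=(1, 1, slice(15, 20)))
        with pytest.warns(UserWarning):
            out = tw.axial_slab(m, ref, 2.0)
        assert out.voxel_count() == 0


class TestGaussianDilate:
    def test_single_voxel_grows_strictly(self):
        m = _mask((9, 9, 9), fill=(4, 4, 4))
        out = tw.gaussian_dilate(m, 1.5)
        assert out.grid[4, 4, 4] == 1
        assert out.voxel_count() > 1

    def test_vanishing_sigma_recovers_mask(self):
        m = _mask((9, 9, 9), fill=(slice(3, 6),) * 3)
        out = tw.gaussian_dilate(m, 1e-4)
        assert np.array_equal(out.grid, m.grid)

    def test_constraint_equal_to_mask_absorbs_dilation(self):
        m = _mask((9, 9, 9), fill=(slice(3, 6),) * 3)
        out = tw.gaussian_dilate(m, 2.0, constraint=m)
        assert np.array_equal(out.grid, m.grid)

    def test_monotone_in_sigma(self):
        m = _mask((11, 11, 11), fill=(5, 5, 5))
        small = tw.gaussian_dilate(m, 1.0)
        large = tw.gaussian_dilate(m, 2.0)
        assert np.all(large.grid >= small.grid)


class TestSphereBetween:
    def test_radius_from_volume_formula(self):
        # centroids at (0,0,0) and (10,0,0): ball centred (5,0,0),
        # r = (3*24/4pi)^(1/3) ~ 1.79 mm
        a = _mask((12, 7, 7), fill=(0, 3, 3))
        b = _mask((12, 7, 7), fill=(10, 3, 3))
        wm = _mask((12, 7, 7), fill=(slice(None),) * 3)
        a.affine[1, 3] = a.affine[2, 3] = -3  # centroids on the x-axis
        b.affine[1, 3] = b.affine[2, 3] = -3
        wm.affine[1, 3] = wm.affine[2, 3] = -3
        out = tw.sphere_between(a, b, 24.0, wm)
        r = (3 * 24.0 / (4 * np.pi)) ** (1 / 3)
        centers = np.argwhere(out.grid) + np.array([0, -3, -3])
        assert len(centers) > 0
        assert np.all(np.linalg.norm(centers - [5, 0, 0], axis=1) <= r + 1e-9)
        # brute-force reference: every 1 mm voxel centre within r is kept
        expected = sum(
            1 for i in range(12) for j in range(-3, 4) for k in range(-3, 4)
            if (i - 5) ** 2 + j ** 2 + k ** 2 <= r ** 2 + 1e-9)
        assert out.voxel_count() == expected

    def test_tiny_volume_on_coarse_grid_is_one_voxel(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        a = _mask((8, 8, 8), affine=aff, fill=(1, 4, 4))
        b = _mask((8, 8, 8), affine=aff, fill=(7, 4, 4))
        wm = _mask((8, 8, 8), affine=aff, fill=(slice(None),) * 3)
        out = tw.sphere_between(a, b, 8.0, wm)   # r ~ 1.24 mm < 2 mm spacing
        assert out.voxel_count() == 1

    def test_identical_masks_centre_on_common_centroid(self):
        a = _mask((9, 9, 9), fill=(4, 4, 4))
        wm = _mask((9, 9, 9), fill=(slice(None),) * 3)
        out = tw.sphere_between(a, a, 24.0, wm)
        assert out.grid[4, 4, 4] == 1

    def test_empty_input_is_geometry_error(self):
        a = _mask((4, 4, 4), fill=(1, 1, 1))
        with pytest.raises(GeometryError):
            tw.sphere_between(a, _mask((4, 4, 4)), 24.0, a)


class TestSplitByPlane:
    def test_plane_at_landmark_anterior_edge(self):
        m = _mask((4, 21, 4), fill=(slice(1, 3), slice(0, 21), slice(1, 3)))
        genu = _mask((4, 21, 4), fill=(2, slice(6, 9), 2))
        post, ant = split_by_plane(m, genu)
        assert np.argwhere(post.grid)[:, 1].max() == 8
        assert np.argwhere(ant.grid)[:, 1].min() == 9

    def test_landmark_anterior_to_mask_keeps_all_posterior(self):
        m = _mask((4, 21, 4), fill=(slice(1, 3), slice(0, 10), slice(1, 3)))
        lm = _mask((4, 21, 4), fill=(2, 18, 2))
        post, ant = split_by_plane(m, lm)
        assert np.array_equal(post.grid, m.grid)
        assert ant.voxel_count() == 0

    def test_parts_partition_the_mask(self):
        rng = np.random.default_rng(3)
        grid = (rng.random((6, 12, 6)) < 0.4).astype(np.uint8)
        grid[2, 5, 2] = 1
        m = tw.ScalarMap(grid, np.eye(4), role="binary")
        lm = _mask((6, 12, 6), fill=(2, 5, 2))
        post, ant = split_by_plane(m, lm)
        assert not np.any(post.grid & ant.grid)
        assert np.array_equal(post.grid | ant.grid, m.grid)


class TestBuildRois:
    def test_cst_seed_contained_in_brainstem_slab(self, phantom_vol, protocols):
        rois = build_rois(protocols["CST"], phantom_vol)
        seed = rois["seed"]
        brainstem = phantom_vol.mask("brainstem_L")
        assert seed.voxel_count() > 0
        assert np.all(brainstem.grid[seed.grid != 0] == 1)
        # the seed slab is 4 mm thick around the fourth ventricle midpoint
        zs = np.argwhere(seed.grid)[:, 2]
        assert np.ptp(zs) * 2.0 <= 4.0   # 2 mm voxels

    @pytest.mark.parametrize("tract", ["CST", "IFOF", "OR", "AF", "FAT", "SLF3"])
    def test_seed_target_exclude_pairwise_disjoint(self, tract, phantom_vol,
                                                   protocols):
        rois = build_rois(protocols[tract], phantom_vol)
        masks = [rois["seed"]] + rois["targets"] + rois["excludes"] \
            + rois["includes"]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not np.any(masks[i].grid & masks[j].grid), \
                    f"{tract}: ROI {i} overlaps ROI {j}"

    def test_missing_structure_names_the_label(self, phantom_vol, protocols):
        labels = {k: v for k, v in phantom_vol.labels.items()
                  if not k.startswith("lgn")}
        vol = tw.LabelVolume(phantom_vol.grid, phantom_vol.affine, labels)
        with pytest.raises(ProtocolError, match="lgn"):
            build_rois(protocols["OR"], vol)

    @pytest.mark.parametrize("tract", ["CST", "IFOF", "OR", "AF", "FAT", "SLF3"])
    def test_left_right_rois_are_mirror_images(self, tract, phantom_vol,
                                               protocols):
        left = build_rois(protocols[tract].with_hemisphere("left"), phantom_vol)
        right = build_rois(protocols[tract].with_hemisphere("right"), phantom_vol)
        # voxel centres are symmetric about x=0, so mirroring is an axis flip
        assert np.array_equal(left["seed"].grid[::-1], right["seed"].grid)
        for lm, rm in zip(left["targets"], right["targets"]):
            assert np.array_equal(lm.grid[::-1], rm.grid)

    def test_deterministic_rebuild_is_bit_identical(self, phantom_vol, protocols):
        a = build_rois(protocols["IFOF"], phantom_vol)
        b = build_rois(protocols["IFOF"], phantom_vol)
        assert np.array_equal(a["seed"].grid, b["seed"].grid)
        assert np.array_equal(a["includes"][0].grid, b["includes"][0].grid)


class TestRoiVolumeStats:
    def test_identical_volumes_have_zero_sd(self):
        m = _mask((5, 5, 5), fill=(slice(0, 4), 1, 1))
        stats = roi_volume_stats([m, m])
        assert stats["sd_percent"] == 0.0

    def test_hand_computed_sd_percent(self):
        a = _mask((10, 10, 10), fill=(slice(0, 80), 0, 0))
        grid = np.zeros((10, 10, 10), dtype=np.uint8)
        grid.flat[:120] = 1
        b = tw.ScalarMap(grid, np.eye(4), role="binary")
        grid_a = np.zeros((10, 10, 10), dtype=np.uint8)
        grid_a.flat[:80] = 1
        a = tw.ScalarMap(grid_a, np.eye(4), role="binary")
        stats = roi_volume_stats([a, b])
        assert stats["mean_mm3"] == pytest.approx(100.0)
        assert stats["sd_percent"] == pytest.approx(28.2843, abs=1e-3)

    def test_scale_invariance_of_sd_percent(self):
        grids = []
        for n in (30, 50, 90):
            g = np.zeros((6, 6, 6), dtype=np.uint8)
            g.flat[:n] = 1
            grids.append(g)
        small = [tw.ScalarMap(g, np.eye(4), role="binary") for g in grids]
        big = [tw.ScalarMap(g, np.diag([2., 2, 2, 1]), role="binary")
               for g in grids]
        assert roi_volume_stats(small)["sd_percent"] == \
            pytest.approx(roi_volume_stats(big)["sd_percent"])

    def test_single_subject_rejected(self):
        m = _mask((3, 3, 3), fill=(1, 1, 1))
        with pytest.raises(ValueError):
            roi_volume_stats([m])
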