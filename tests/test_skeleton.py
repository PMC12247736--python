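import numpy as np
import pytest
from scipy import ndimage

from conftest import brute_force_edt_at, solid_cylinder, voxel_mask
from vesselmorph.grids import BinaryVesselMask, GridSpec
from vesselmorph.skeleton import (
    BIFURCATION,
    ENDPOINT,
    REGULAR,
    STRUCT_26,
    classify_points,
    radius_at_centerline,
    skeletonize_mask,
    thin_3d,
)


def _points_set(skel):
    return set(map(tuple, skel.points))


class TestThinning:
    def test_thin_line_returned_unchanged(self):
        pts = [(i, 10 + (i // 3), 10) for i in range(4, 16)]  # 26-connected staircase
        mask = voxel_mask((24, 24, 24), pts)
        skel = thin_3d(mask)
        assert _points_set(skel) == set(pts)

    def test_idempotent_on_phantoms(self, straight_tube, y_tree):
        for mask, _ in (straight_tube, y_tree):
            once = thin_3d(mask)
            skel_mask = BinaryVesselMask(
                grid=mask.grid, values=once.to_volume().astype(np.uint8)
            )
            twice = thin_3d(skel_mask)
            assert _points_set(once) == _points_set(twice)

    def test_skeleton_subset_of_mask(self, y_tree):
        mask, _ = y_tree
        skel = thin_3d(mask)
        assert mask.values[tuple(skel.points.T)].all()

    def test_cylinder_centerline_on_axis(self):
        """A solid cylinder thins to a single path within 1 voxel of its axis."""
        mask = solid_cylinder(r_vox=3.0)
        skel = thin_3d(mask)
        d = np.sqrt(((skel.points[:, :2] - 24.0) ** 2).sum(axis=1))
        assert len(skel) > 20
        assert d.max() <= 1.0
        labels, n = ndimage.label(skel.to_volume(), structure=STRUCT_26)
        assert n == 1

    def test_thin_result_has_no_2x2x2_block(self, straight_tube):
        mask, _ = straight_tube
        vol = thin_3d(mask).to_volume().astype(np.uint8)
        blocks = ndimage.uniform_filter(vol.astype(float), size=2, origin=-1)
        assert not np.any(blocks > 0.999)

    def test_component_counts_preserved(self):
        rng = np.random.default_rng(5)
        vals = np.zeros((40, 40, 40), np.uint8)
        # three disjoint solid boxes
        for lo in ((4, 4, 4), (20, 20, 4), (4, 25, 25)):
            sl = tuple(slice(l, l + rng.integers(4, 9)) for l in lo)
            vals[sl] = 1
        mask = BinaryVesselMask(
            grid=GridSpec(shape=vals.shape, spacing=(0.5, 0.5, 0.5)), values=vals
        )
        skel = thin_3d(mask)
        _, n_in = ndimage.label(mask.values, structure=STRUCT_26)
        _, n_out = ndimage.label(skel.to_volume(), structure=STRUCT_26)
        assert n_in == n_out

    def test_empty_mask_empty_skeleton(self):
        mask = voxel_mask((8, 8, 8), np.zeros((0, 3), dtype=int))
        assert len(thin_3d(mask)) == 0


class TestClassification:
    def test_straight_line_classes(self):
        pts = [(i, 5, 5) for i in range(2, 12)]
        skel = classify_points(thin_3d(voxel_mask((16, 16, 16), pts)))
        counts = skel.class_counts()
        assert counts == {"regular": 8, "endpoint": 2, "bifurcation": 0}

    def test_y_shape_junction(self):
        pts = (
            [(8, 8, z) for z in range(2, 9)]
            + [(8 + i, 8 + i, 8 + i) for i in range(1, 7)]
            + [(8 - i, 8 + i, 8 + i) for i in range(1, 7)]
        )
        skel = classify_points(thin_3d(voxel_mask((20, 20, 20), pts)))
        counts = skel.class_counts()
        assert counts["endpoint"] == 3
        assert counts["bifurcation"] >= 1

    def test_isolated_voxel_is_endpoint(self):
        skel = classify_points(thin_3d(voxel_mask((8, 8, 8), [(4, 4, 4)])))
        assert skel.class_counts() == {"regular": 0, "endpoint": 1, "bifurcation": 0}

    def test_class_counts_partition_skeleton(self, y_tree):
        mask, _ = y_tree
        skel = classify_points(thin_3d(mask))
        assert sum(skel.class_counts().values()) == len(skel)


class TestRadii:
    def test_matches_brute_force_oracle_isotropic(self):
        rng = np.random.default_rng(6)
        vals = (rng.random((16, 16, 16)) > 0.5).astype(np.uint8)
        mask = BinaryVesselMask(
            grid=GridSpec(shape=vals.shape, spacing=(0.5, 0.5, 0.5)), values=vals
        )
        pts = np.argwhere(vals)[::7]
        from vesselmorph.skeleton import Skeleton

        skel = radius_at_centerline(mask, Skeleton(points=pts, grid=mask.grid))
        oracle = brute_force_edt_at(mask, pts)
        np.testing.assert_allclose(skel.radius_mm, oracle, atol=1e-9)

    def test_cylinder_radius_in_band_and_matches_oracle(self, straight_tube):
        mask, truth = straight_tube
        skel = skeletonize_mask(mask)
        interior = np.abs(
            skel.points[:, 2] - skel.points[:, 2].mean()
        ) <= (np.ptp(skel.points[:, 2]) / 2 - 2)
        mean_r = skel.radius_mm[interior].mean()
        assert abs(mean_r - truth.radius_mm) / truth.radius_mm < 0.125
        oracle = brute_force_edt_at(mask, skel.points[interior][::5])
        np.testing.assert_allclose(skel.radius_mm[interior][::5], oracle, atol=1e-9)

    def test_radius_scales_with_tube_radius(self):
        from vesselmorph.phantom import PhantomSpec, make_phantom

        means = []
        for r in (2.0, 4.0):  # >= 4 voxels, where the EDT convention bias is small
            mask, _ = make_phantom(
                PhantomSpec(kind="straight_tube", radius_mm=r, length_mm=30.0)
            )
            skel = skeletonize_mask(mask)
            means.append(np.mean(skel.radius_mm))
        assert abs(means[1] / means[0] - 2.0) < 0.2

    def test_single_voxel_radius_equals_oracle(self):
        mask = voxel_mask((9, 9, 9), [(4, 4, 4)], spacing=(0.7, 0.7, 0.7))
        skel = skeletonize_mask(mask)
        oracle = brute_force_edt_at(mask, skel.points)
        np.testing.assert_allclose(skel.radius_mm, oracle, atol=1e-9)

    def test_translation_and_permutation_invariance(self):
        base = [(i, 7, 6) for i in range(3, 12)]
        m1 = voxel_mask((16, 16, 16), base, spacing=(0.5, 0.6, 0.7))
        shifted = [(i + 2, 8, 9) for i in range(3, 12)]
        m2 = voxel_mask((16, 16, 16), shifted, spacing=(0.5, 0.6, 0.7))
        r1 = skeletonize_mask(m1).radius_mm
        r2 = skeletonize_mask(m2).radius_mm
        np.testing.assert_allclose(sorted(r1), sorted(r2))
        # permute axes and spacing together
        permuted = [(7, i, 6) for i in range(3, 12)]
        m3 = voxel_mask((16, 16, 16), permuted, spacing=(0.6, 0.5, 0.7))
        r3 = skeletonize_mask(m3).radius_mm
        np.testing.assert_allclose(sorted(r1), sorted(r3))

    def test_point_outside_mask_rejected(self):
        from vesselmorph.skeleton import Skeleton

        mask = voxel_mask((8, 8, 8), [(4, 4, 4)])
        rogue = Skeleton(points=np.array([(1, 1, 1)]), grid=mask.grid)
        with pytest.raises(ValueError, match="outside the mask"):
            radius_at_centerline(mask, rogue)


class TestExports:
    def test_point_table_and_label_volume(self, y_tree):
        mask, _ = y_tree
        skel = skeletonize_mask(mask)
        df = skel.to_dataframe()
        assert list(df.columns) == ["x", "y", "z", "class", "radius_mm"]
        assert len(df) == len(skel)
        lab = skel.to_label_volume()
        vals, counts = np.unique(lab.values, return_counts=True)
        assert set(vals) <= {0, REGULAR, ENDPOINT, BIFURCATION}
        assert counts[vals > 0].sum() == len(skel)
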