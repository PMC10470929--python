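"""Component labeling, size filtering, and per-component shape measures."""

import numpy as np
import pytest

from mitotap.morphometry import (
    axis_lengths,
    label_components,
    mci,
    measure_all,
    measure_surface,
    measure_volume,
    principal_axes,
    records_to_frame,
    remove_small_objects,
)
from mitotap.volumes import LabelVolume, VoxelGrid


def _labels_from(mask):
    return label_components(np.asarray(mask, dtype=bool))


class TestLabeling:
    def test_disjoint_cubes_get_two_labels(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[:2, :2, :2] = True
        m[5:7, 5:7, 5:7] = True
        assert len(_labels_from(m).ids) == 2

    def test_corner_touching_depends_on_connectivity(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[:2, :2, :2] = True
        m[2:, 2:, 2:] = True  # shares only the corner at (2,2,2)/(1,1,1)
        assert len(label_components(m, connectivity=26).ids) == 1
        assert len(label_components(m, connectivity=6).ids) == 2

    def test_empty_mask(self):
        assert len(_labels_from(np.zeros((3, 3, 3), bool)).ids) == 0

    def test_ids_ordered_by_descending_size(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[0, 0, :3] = True  # 3 voxels
        m[5:8, 5:8, 5:8] = True  # 27 voxels
        lab = _labels_from(m)
        assert (lab.labels[6, 6, 6], lab.labels[0, 0, 0]) == (1, 2)


class TestRemoveSmallObjects:
    def test_twenty_voxel_threshold(self):
        m = np.zeros((12, 24, 8), dtype=bool)
        m[0, 0:19, 0] = True  # 19 voxels: removed
        m[4, 0:20, 0] = True  # 20 voxels: kept
        out = remove_small_objects(_labels_from(m))
        assert not out.labels[0].any()
        assert out.labels[4].sum() == 20

    def test_planted_size_family(self):
        m = np.zeros((8, 40, 8), dtype=bool)
        sizes = {5: 0, 19: 2, 20: 4, 100: 6}
        for size, z in sizes.items():
            m.reshape(8, -1)[z, :size] = True
        out = remove_small_objects(_labels_from(m))
        surviving = sorted(
            int((out.labels == i).sum()) for i in out.ids
        )
        assert surviving == [20, 100]

    def test_idempotent(self, rng):
        m = rng.random((12, 12, 12)) > 0.7
        once = remove_small_objects(_labels_from(m), 10)
        twice = remove_small_objects(once, 10)
        assert np.array_equal(once.labels, twice.labels)


class TestVolumeSurface:
    def test_volume_unit_conversion(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m.ravel()[:1000] = True
        lab = _labels_from(m)
        assert measure_volume(lab, 1) == pytest.approx(1.0e-3)  # 1000 * (10nm)^3

    def test_single_voxel_volume(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        assert measure_volume(_labels_from(m), 1) == pytest.approx(1e-6)

    def test_volume_additive_over_components(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[:2, :2, :2] = True
        m[5:, 5:, 5:] = True
        lab = _labels_from(m)
        total = sum(measure_volume(lab, int(i)) for i in lab.ids)
        assert total == pytest.approx(int(m.sum()) * 1e-6)

    def test_cube_surface_boundary_voxels(self):
        # 3x3x3 cube: all but the centre voxel are face-exposed -> 26
        m = np.zeros((7, 7, 7), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        sa = measure_surface(_labels_from(m), 1)
        assert sa == pytest.approx(26 * (10.0**2) * 1e-6)  # 2.6e-3 um^2

    def test_single_voxel_surface(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        assert measure_surface(_labels_from(m), 1) == pytest.approx(1e-4)

    def test_hollowed_cube_outline_count_unchanged(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        solid = measure_surface(_labels_from(m), 1)
        m[3, 3, 3] = False  # interior cavity: remaining 26 voxels all exposed
        hollow = measure_surface(_labels_from(m), 1)
        assert hollow == pytest.approx(solid)

    def test_absent_id_errors(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[0, 0, 0] = True
        with pytest.raises(KeyError):
            measure_volume(_labels_from(m), 9)


class TestPrincipalAxes:
    @staticmethod
    def _box_coords(nz, ny, nx, spacing=10.0):
        return (
            np.argwhere(np.ones((nz, ny, nx), dtype=bool)).astype(float) * spacing
        )

    def test_box_pc1_along_longest_extent(self):
        coords = self._box_coords(2, 4, 10)  # longest along x
        axes, evals = principal_axes(coords)
        assert abs(axes[0] @ np.array([0.0, 0.0, 1.0])) == pytest.approx(1.0)
        assert evals[0] >= evals[1] >= evals[2]

    def test_rotation_equivariance(self, rng):
        coords = self._box_coords(2, 4, 10)
        theta = 0.7
        R = np.array(
            [
                [1, 0, 0],
                [0, np.cos(theta), -np.sin(theta)],
                [0, np.sin(theta), np.cos(theta)],
            ]
        )
        axes0, ev0 = principal_axes(coords)
        axes1, ev1 = principal_axes(coords @ R.T)
        assert np.allclose(ev0, ev1)
        for a0, a1 in zip(axes0, axes1):
            assert abs(a1 @ (R @ a0)) == pytest.approx(1.0)

    def test_translation_invariance(self):
        coords = self._box_coords(3, 5, 7)
        axes0, ev0 = principal_axes(coords)
        axes1, ev1 = principal_axes(coords + np.array([123.0, -55.0, 7.0]))
        assert np.allclose(ev0, ev1) and np.allclose(axes0, axes1)

    def test_isotropic_cube_is_degenerate(self):
        _, evals = principal_axes(self._box_coords(5, 5, 5))
        assert np.allclose(evals, evals[0])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            principal_axes(np.array([[0.0, 0.0, 0.0]]))


class TestAxisLengths:
    def test_box_extent_plus_one_voxel(self):
        grid = VoxelGrid((2, 4, 10))
        coords = np.argwhere(np.ones(grid.shape, dtype=bool)).astype(float) * 10.0
        axes, _ = principal_axes(coords)
        lengths = axis_lengths(coords, axes, grid)
        assert lengths == pytest.approx((0.10, 0.04, 0.02))

    def test_single_voxel_one_voxel_convention(self):
        grid = VoxelGrid((1, 1, 1))
        lengths = axis_lengths(np.array([[0.0, 0.0, 0.0]]), np.eye(3), grid)
        assert lengths == pytest.approx((0.01, 0.01, 0.01))


class TestMci:
    def test_analytic_sphere_is_nine_over_four_pi(self):
        # independent closed form: SA = 4 pi r^2, V = 4/3 pi r^3
        for r in (0.1, 0.5, 1.0, 3.7):
            sa = 4 * np.pi * r**2
            v = 4 / 3 * np.pi * r**3
            assert mci(sa, v) == pytest.approx(9 / (4 * np.pi), abs=1e-12)

    def test_scale_invariance(self):
        base = mci(2.0, 0.3)
        for k in (0.1, 2.0, 17.0):
            assert mci(k**2 * 2.0, k**3 * 0.3) == pytest.approx(base, abs=1e-12)

    def test_elongation_increases_mci(self):
        # boxes of fixed volume: closed-form SA of a1 x a1 x (V/a1^2)
        def box_mci(aspect):
            v = 1.0
            a = (v / aspect) ** (1 / 3)
            c = aspect * a
            sa = 2 * (a * a + 2 * a * c)
            return mci(sa, v)

        assert box_mci(4.0) > box_mci(1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            mci(0.0, 1.0)


class TestMeasureAll:
    def test_frame_columns_and_invariants(self, rng):
        m = np.zeros((16, 16, 32), dtype=bool)
        m[4:10, 4:10, 2:20] = True
        m[12:15, 12:15, 25:30] = True
        frame = records_to_frame(measure_all(_labels_from(m)))
        assert list(frame["id"]) == [1, 2]
        assert (frame["length_max_um"] >= frame["length_mid_um"]).all()
        assert (frame["length_mid_um"] >= frame["length_min_um"]).all()
        assert (frame["aspect_ratio"] >= 1.0).all()
        assert (frame["mci"] > 0).all()
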