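"""Exact scoring, rasterization and search-space geometry.

The central check: every fast counting path must reproduce a naive
per-voxel loop integer-exactly.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrsplace.geometry import (
    PAD_DEFAULT_MM,
    CubePlacement,
    EmptyMaskError,
    GridError,
    build_search_space,
    compute_bbox,
    rasterize_cube,
    rotation_matrix,
    score_placement,
)
from mrsplace.io import BinaryMask, ImageVolume

from conftest import make_mask, seg_from_arrays


def naive_enclosed_count(mask_data, origin, placement):
    """Independent oracle: literal per-voxel loop over nonzero voxels."""
    r = rotation_matrix(placement.angles_deg)
    half = placement.side_mm / 2.0
    n = 0
    for i, j, k in np.argwhere(mask_data):
        x = np.array([i, j, k], dtype=float) + np.asarray(origin)
        q = r.T @ (x - placement.center_mm)
        # same tie-stabilized half-open membership as the implementation
        if np.all(q >= -half - 1e-6) and np.all(q < half - 1e-6):
            n += 1
    return n


class TestRotationMatrix:
    def test_zero_angles_is_identity(self):
        assert np.allclose(rotation_matrix((0, 0, 0)), np.eye(3), atol=1e-12)

    def test_single_axis_quarter_turn(self):
        # 90 deg about x maps +y to +z
        r = rotation_matrix((90, 0, 0))
        assert np.allclose(r @ [0, 1, 0], [0, 0, 1], atol=1e-9)
        # 90 deg about z maps +x to +y
        r = rotation_matrix((0, 0, 90))
        assert np.allclose(r @ [1, 0, 0], [0, 1, 0], atol=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 90), min_size=3, max_size=3))
    def test_orthonormal_proper(self, angles):
        r = rotation_matrix(angles)
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(r), 1.0, atol=1e-9)

    def test_composition_order_is_z_y_x(self):
        ax, ay, az = np.deg2rad([30.0, 50.0, 70.0])

        def rx(t):
            c, s = np.cos(t), np.sin(t)
            return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

        def ry(t):
            c, s = np.cos(t), np.sin(t)
            return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

        def rz(t):
            c, s = np.cos(t), np.sin(t)
            return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

        assert np.allclose(
            rotation_matrix((30, 50, 70)), rz(az) @ ry(ay) @ rx(ax), atol=1e-12
        )


class TestBBox:
    def test_single_voxel(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[5, 5, 5] = 1
        lo, hi = compute_bbox(make_mask(data))
        assert np.allclose(lo, [5, 5, 5]) and np.allclose(hi, [5, 5, 5])

    def test_solid_block(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[2:8, 3:5, 0:10] = 1
        lo, hi = compute_bbox(make_mask(data))
        assert np.allclose(lo, [2, 3, 0]) and np.allclose(hi, [7, 4, 9])

    def test_sphere_extent_matches_closed_form(self):
        c, rad = np.array([20.0, 21.0, 19.0]), 10.0
        ax = np.arange(40)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        lo, hi = compute_bbox(make_mask((d2 <= rad**2).astype(np.uint8)))
        assert np.all(np.abs(lo - (c - rad)) <= 1.0)
        assert np.all(np.abs(hi - (c + rad)) <= 1.0)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            compute_bbox(make_mask(np.zeros((5, 5, 5), dtype=np.uint8)))


class TestScorePlacement:
    def test_all_masks_empty(self):
        z = np.zeros((40, 40, 40), dtype=np.uint8)
        seg = seg_from_arrays(core=z, necrosis=z, whole=z)
        s = score_placement(CubePlacement((20, 20, 20), (0, 0, 0)), seg)
        assert (s.core_mm3, s.necrosis_mm3, s.whole_mm3) == (0, 0, 0)
        assert s.feasible

    def test_axis_aligned_cube_footprint_counts_8000(self):
        """Half-open membership: [c-10, c+10) holds exactly 20^3 centers."""
        data = np.zeros((40, 40, 40), dtype=np.uint8)
        data[10:30, 10:30, 10:30] = 1  # exactly the cube footprint
        seg = seg_from_arrays(core=data)
        s = score_placement(CubePlacement((20, 20, 20), (0, 0, 0)), seg)
        assert s.core_mm3 == 8000

    def test_matches_naive_loop_on_random_placements(self, small_seg):
        rng = np.random.default_rng(11)
        origin = small_seg.grid.origin
        for _ in range(25):
            p = CubePlacement(rng.uniform(15, 45, 3), rng.uniform(0, 90, 3))
            s = score_placement(p, small_seg)
            assert s.core_mm3 == naive_enclosed_count(
                small_seg.core.data, origin, p
            )
            assert s.necrosis_mm3 == naive_enclosed_count(
                small_seg.necrosis.data, origin, p
            )
            assert s.whole_mm3 == naive_enclosed_count(
                small_seg.whole.data, origin, p
            )

    def test_monotone_in_mask_support(self, small_seg):
        """A superset mask can never score lower at a fixed placement."""
        rng = np.random.default_rng(5)
        small = small_seg.core.data
        big = small | small_seg.necrosis.data
        for _ in range(10):
            p = CubePlacement(rng.uniform(20, 44, 3), rng.uniform(0, 90, 3))
            a = score_placement(p, seg_from_arrays(core=small)).core_mm3
            b = score_placement(p, seg_from_arrays(core=big)).core_mm3
            assert b >= a

    def test_translation_equivariance(self, small_seg):
        """Integer-mm shift of masks and center leaves every score unchanged."""
        shift = np.array([3, -2, 4])
        rolled = {
            name: np.roll(m.data, shift, axis=(0, 1, 2))
            for name, m in small_seg.masks().items()
        }
        seg2 = seg_from_arrays(**rolled)
        rng = np.random.default_rng(9)
        for _ in range(10):
            c = rng.uniform(22, 42, 3)
            a = rng.uniform(0, 90, 3)
            s1 = score_placement(CubePlacement(c, a), small_seg)
            s2 = score_placement(CubePlacement(c + shift, a), seg2)
            assert (s1.core_mm3, s1.necrosis_mm3, s1.whole_mm3) == (
                s2.core_mm3,
                s2.necrosis_mm3,
                s2.whole_mm3,
            )

    def test_non_isotropic_grid_rejected(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[4, 4, 4] = 1
        seg = seg_from_arrays(core=data, spacing=2.0)
        with pytest.raises(GridError, match="1 mm isotropic"):
            score_placement(CubePlacement((10, 10, 10), (0, 0, 0)), seg)


class TestRasterizeCube:
    def test_identity_rotation_integer_center_has_8000_voxels(self):
        grid = ImageVolume(data=np.zeros((64, 64, 64)), affine=np.eye(4))
        cube = rasterize_cube(CubePlacement((32, 32, 32), (0, 0, 0)), grid)
        assert cube.n_voxels == 20**3

    def test_quarter_turn_preserves_lattice_count(self):
        """90 deg about one axis maps the voxel lattice onto itself."""
        grid = ImageVolume(data=np.zeros((64, 64, 64)), affine=np.eye(4))
        for angles in ((90, 0, 0), (0, 90, 0), (0, 0, 90)):
            cube = rasterize_cube(CubePlacement((32, 32, 32), angles), grid)
            assert cube.n_voxels == 8000

    def test_consistency_with_score(self, small_seg):
        """count(rasterize & mask) == score for random placements."""
        rng = np.random.default_rng(21)
        grid = small_seg.grid
        for _ in range(20):
            p = CubePlacement(rng.uniform(18, 46, 3), rng.uniform(0, 90, 3))
            cube = rasterize_cube(p, grid)
            s = score_placement(p, small_seg)
            assert int((cube.data & small_seg.core.data).sum()) == s.core_mm3
            assert int((cube.data & small_seg.whole.data).sum()) == s.whole_mm3

    def test_cube_outside_grid_warns_and_is_empty(self):
        grid = ImageVolume(data=np.zeros((30, 30, 30)), affine=np.eye(4))
        with pytest.warns(UserWarning, match="outside"):
            cube = rasterize_cube(CubePlacement((500, 500, 500), (0, 0, 0)), grid)
        assert cube.n_voxels == 0


class TestSearchSpace:
    def test_center_limit_box_is_bbox_padded_by_full_cube_diagonal(self):
        data = np.zeros((200, 200, 200), dtype=np.uint8)
        data[0:11, 0:11, 0:11] = 1  # bbox (0,0,0)-(10,10,10)
        space = build_search_space(make_mask(data))
        lo, hi = space.center_box_mm
        assert np.allclose(lo, -PAD_DEFAULT_MM, atol=1e-9)
        assert np.allclose(hi, 10.0 + PAD_DEFAULT_MM, atol=1e-9)
        assert np.isclose(PAD_DEFAULT_MM, 34.64101615137755)

    def test_angle_grid_includes_both_endpoints(self):
        data = np.zeros((120, 120, 120), dtype=np.uint8)
        data[55:66, 55:66, 55:66] = 1
        space = build_search_space(make_mask(data), angle_step_deg=45.0)
        assert np.allclose(space.angle_axis, [0, 45, 90])
        assert space.n_angles == 27
        space = build_search_space(make_mask(data), angle_step_deg=40.0)
        assert np.allclose(space.angle_axis, [0, 40, 80, 90])

    def test_candidate_count_matches_closed_form(self):
        data = np.zeros((200, 200, 200), dtype=np.uint8)
        data[95:106, 97:104, 90:101] = 1
        stride = 2.0
        space = build_search_space(make_mask(data), center_stride_mm=stride)
        lo, hi = compute_bbox(make_mask(data))
        r_circ = space.side_mm * np.sqrt(3) / 2.0
        for d in range(3):
            ext = hi[d] - lo[d]
            mid = 0.5 * (lo[d] + hi[d])
            m = int(np.floor((ext / 2 + PAD_DEFAULT_MM) / stride))
            vals = mid + np.arange(-m, m + 1) * stride
            n_expected = int(
                ((vals - r_circ >= -0.5) & (vals + r_circ <= 199.5)).sum()
            )
            assert len(space.center_axes[d]) == n_expected

    def test_candidates_stay_inside_padded_box_and_domain(self, small_seg):
        space = build_search_space(small_seg.core, center_stride_mm=4.0)
        lo, hi = space.center_box_mm
        centers = space.centers()
        assert np.all(centers >= lo - 1e-9) and np.all(centers <= hi + 1e-9)
        r_circ = space.side_mm * np.sqrt(3) / 2.0
        dlo, dhi = space.image_domain
        assert np.all(centers - r_circ >= dlo - 1e-9)
        assert np.all(centers + r_circ <= dhi + 1e-9)

    def test_image_too_small_for_cube_raises(self):
        data = np.zeros((16, 16, 16), dtype=np.uint8)
        data[8, 8, 8] = 1
        with pytest.raises(ValueError, match="cannot fit"):
            build_search_space(make_mask(data))
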