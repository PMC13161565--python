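"""Search correctness: oracle equivalence, modes, fallback, heatmaps."""

import numpy as np
import pytest

from mrsplace.geometry import TumorSegmentation, rasterize_cube
from mrsplace.io import BinaryMask, ImageVolume
from mrsplace.optimize import (
    InfeasibleError,
    ModeError,
    PlacementConfig,
    brute_force_oracle,
    generate_heatmap,
    optimize,
    select_mode,
)
from mrsplace.phantom import PhantomSpec, generate_phantom, phantom_suite

from conftest import seg_from_arrays

COARSE = PlacementConfig(center_stride_mm=8.0, angle_step_deg=45.0)


def reports_equal(a, b):
    return (
        a.placement == b.placement
        and a.score == b.score
        and a.fallback_used == b.fallback_used
        and a.mode == b.mode
    )


class TestSelectMode:
    def test_empty_core_selects_flair_only(self):
        z = np.zeros((48, 48, 48), dtype=np.uint8)
        w = z.copy()
        w[20:30, 20:30, 20:30] = 1
        seg = seg_from_arrays(core=z, whole=w)
        assert select_mode(seg) == "flair_only"

    def test_large_core_selects_enhancing(self, small_seg):
        assert select_mode(small_seg, min_core_mm3=100.0) == "enhancing"

    def test_speckle_core_below_threshold_falls_through(self):
        core = np.zeros((48, 48, 48), dtype=np.uint8)
        core[24:28, 24:28, 24:28] = 1  # 64 mm^3 of speckle
        w = np.zeros_like(core)
        w[18:34, 18:34, 18:34] = 1
        seg = seg_from_arrays(core=core, whole=w)
        assert select_mode(seg, min_core_mm3=100.0) == "flair_only"

    def test_flair_only_without_whole_mask_errors(self):
        core = np.zeros((48, 48, 48), dtype=np.uint8)
        core[24, 24, 24] = 1
        seg = seg_from_arrays(core=core)
        with pytest.raises(ModeError, match="whole"):
            select_mode(seg, min_core_mm3=100.0)


class TestOptimizeAgainstOracle:
    @pytest.mark.parametrize(
        "name", ["small_enhancing", "non_enhancing", "necrosis_everywhere"]
    )
    def test_exhaustive_equivalence_on_suite(self, name):
        """The fast search must equal the literal loop integer-exactly."""
        _, _, seg = generate_phantom(phantom_suite(name)[0])
        assert reports_equal(optimize(seg, COARSE), brute_force_oracle(seg, COARSE))

    def test_equivalence_with_noninteger_stride(self, small_seg):
        """Non-integer strides use the direct counting path."""
        cfg = PlacementConfig(center_stride_mm=7.5, angle_step_deg=90.0)
        assert reports_equal(
            optimize(small_seg, cfg), brute_force_oracle(small_seg, cfg)
        )

    def test_oracle_guard(self, small_seg):
        with pytest.raises(ValueError, match="guard"):
            brute_force_oracle(
                small_seg,
                PlacementConfig(center_stride_mm=1.0, angle_step_deg=5.0),
            )


class TestOptimize:
    def test_containable_core_fully_enclosed(self):
        """A sphere of radius 8 fits in the cube: optimum encloses 100%."""
        spec = PhantomSpec(
            shape=(96, 96, 96), core_center_mm=(48.0, 47.0, 49.0),
            core_radii_mm=(8.0, 8.0, 8.0), edema_radii_mm=(13.0, 13.0, 13.0),
            noise_sd=1.0, seed=5,
        )
        _, _, seg = generate_phantom(spec)
        report = optimize(seg, PlacementConfig(center_stride_mm=2.0, angle_step_deg=45.0))
        assert report.score.core_mm3 == seg.core.n_voxels
        assert not report.fallback_used

    def test_fallback_on_global_infeasibility(self):
        _, _, seg = generate_phantom(phantom_suite("necrosis_everywhere")[0])
        report = optimize(seg, COARSE)
        assert report.fallback_used
        assert report.score.necrosis_mm3 > 0
        # fallback minimizes necrosis first: equal to the oracle's minimum
        oracle = brute_force_oracle(seg, COARSE)
        assert report.score.necrosis_mm3 == oracle.score.necrosis_mm3

    def test_fallback_forbidden_raises(self):
        _, _, seg = generate_phantom(phantom_suite("necrosis_everywhere")[0])
        cfg = PlacementConfig(
            center_stride_mm=8.0, angle_step_deg=45.0, fallback="forbid"
        )
        with pytest.raises(InfeasibleError):
            optimize(seg, cfg)

    def test_feasibility_guarantee_rasterized(self, small_seg):
        """Non-fallback: the rasterized cube never touches necrosis."""
        report = optimize(small_seg, COARSE)
        assert not report.fallback_used
        cube = rasterize_cube(report.placement, small_seg.grid)
        assert int((cube.data & small_seg.necrosis.data).sum()) == 0

    def test_flair_only_mode_scores_no_core(self):
        _, _, seg = generate_phantom(phantom_suite("non_enhancing")[0])
        report = optimize(seg, COARSE)
        assert report.mode == "flair_only"
        assert report.score.core_mm3 == 0
        assert report.score.whole_mm3 > 0

    def test_determinism(self, small_seg):
        r1 = optimize(small_seg, COARSE)
        r2 = optimize(small_seg, COARSE)
        assert reports_equal(r1, r2)
        assert r1.to_dict() == r2.to_dict()

    def test_refinement_monotonicity(self, small_seg):
        """Nested lattices/angle grids can only improve the optimum."""
        key = lambda r: (r.score.core_mm3, r.score.whole_mm3)
        base = optimize(small_seg, PlacementConfig(8.0, 60.0))
        assert key(optimize(small_seg, PlacementConfig(4.0, 60.0))) >= key(base)
        assert key(optimize(small_seg, PlacementConfig(8.0, 30.0))) >= key(base)


class TestHeatmap:
    def test_no_necrosis_phantom_all_cells_valid(self):
        _, _, seg = generate_phantom(phantom_suite("small_enhancing")[0])
        hm = generate_heatmap(seg, (0, 0, 0), COARSE)
        assert hm.valid.all()
        assert hm.target == "core"
        assert hm.values.max() <= hm.side_mm**3

    def test_argmax_matches_optimizer_restricted_to_rotation(self, small_seg):
        report = optimize(small_seg, COARSE)
        hm = generate_heatmap(small_seg, report.placement.angles_deg, COARSE)
        assert hm.values[hm.valid].max() == report.score.core_mm3

    def test_all_necrosis_phantom_has_zero_valid_cells(self):
        _, _, seg = generate_phantom(phantom_suite("necrosis_everywhere")[0])
        hm = generate_heatmap(seg, (0, 0, 0), COARSE)
        assert not hm.valid.any()

    def test_export_roundtrip_and_midslice(self, small_seg, tmp_path):
        import nibabel as nib

        from mrsplace.optimize import export_heatmap

        hm = generate_heatmap(small_seg, (0, 0, 0), COARSE)
        out = tmp_path / "hm.nii.gz"
        png = tmp_path / "hm.png"
        export_heatmap(hm, small_seg.grid, out, midslice_path=png)
        img = nib.load(out)
        assert img.shape == small_seg.grid.shape
        data = np.asanyarray(img.dataobj)
        # lattice points must carry their values; off-lattice cells are NaN
        ax = hm.center_axes
        finite = np.isfinite(data)
        assert finite.any() and not finite.all()
        i = tuple(int(round(a[0])) for a in ax)
        if hm.valid[0, 0, 0]:
            assert data[i] == hm.values[0, 0, 0]
        assert png.exists()
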