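import numpy as np
import pytest

from conftest import tube_mask_3d
from mitometry.core import Calibration, LabelMap, LabelMapError
from mitometry.morpho3d import (
    MoasParams,
    analyze_objects_3d,
    branch_stats,
    detect_moas,
    measure_objects_3d,
    moas_rule,
    object_length,
    skeletonize_object,
)
from mitometry.phantom import PhantomSpec, render


def _lm(mask, cal):
    return LabelMap(mask.astype(np.uint8), "mitochondrion", cal)


class TestMeasure3D:
    def test_sphere_volume_within_2pct(self):
        maps, gt = render(PhantomSpec("sphere", {"radius_nm": 200.0}))
        rec = measure_objects_3d(maps["mito"])[0]
        assert rec.volume_um3 == pytest.approx(gt.volume_um3, rel=0.02)

    def test_sphere_surface_within_5pct(self):
        maps, gt = render(PhantomSpec("sphere", {"radius_nm": 200.0}))
        rec = measure_objects_3d(maps["mito"])[0]
        assert rec.surface_area_um2 == pytest.approx(gt.surface_area_um2, rel=0.05)

    def test_surface_error_decreases_with_radius(self):
        errs = []
        for r_vox in (10, 20, 40):
            maps, gt = render(PhantomSpec("sphere", {"radius_nm": r_vox * 10.0}))
            rec = measure_objects_3d(maps["mito"])[0]
            errs.append(abs(rec.surface_area_um2 / gt.surface_area_um2 - 1.0))
        assert errs[0] >= errs[1] >= errs[2]

    def test_single_voxel_anisotropic(self, cal3d_aniso):
        arr = np.zeros((3, 3, 3), dtype=np.uint8)
        arr[1, 1, 1] = 1
        rec = measure_objects_3d(LabelMap(arr, "mitochondrion", cal3d_aniso))[0]
        assert rec.volume_um3 == pytest.approx(5e-6)

    def test_volume_exact_voxel_count(self, cal3d):
        arr = np.zeros((4, 5, 6), dtype=np.uint8)
        arr[1:3, 1:4, 1:5] = 1  # 2*3*4 = 24 voxels
        rec = measure_objects_3d(LabelMap(arr, "mitochondrion", cal3d))[0]
        assert rec.volume_um3 == pytest.approx(24 * 1e3 / 1e9)

    def test_empty_volume_raises(self, cal3d):
        with pytest.raises(LabelMapError):
            measure_objects_3d(
                LabelMap(np.zeros((4, 4, 4), dtype=np.uint8), "mitochondrion", cal3d)
            )

    def test_axis_permutation_invariance(self, cal3d):
        mask = tube_mask_3d((24, 24, 60), [((12, 12, 6), (12, 12, 54))], 5)
        base = measure_objects_3d(_lm(mask, cal3d))[0]
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            rec = measure_objects_3d(_lm(np.transpose(mask, perm), cal3d))[0]
            assert rec.volume_um3 == pytest.approx(base.volume_um3)
            assert rec.surface_area_um2 == pytest.approx(
                base.surface_area_um2, rel=0.01
            )


class TestSkeleton:
    def test_straight_tube_topology(self, cal3d):
        mask = tube_mask_3d((20, 20, 80), [((10, 10, 5), (10, 10, 75))], 4)
        skel = skeletonize_object(_lm(mask, cal3d), 1)
        assert len(skel.endpoints()) == 2
        assert branch_stats(skel)[0] == 0

    def test_y_tube_topology(self, cal3d):
        segs = [
            ((10, 30, 5), (10, 30, 30)),
            ((10, 30, 30), (10, 10, 55)),
            ((10, 30, 30), (10, 50, 55)),
        ]
        skel = skeletonize_object(_lm(tube_mask_3d((20, 60, 60), segs, 4), cal3d), 1)
        assert len(skel.endpoints()) == 3
        assert branch_stats(skel)[0] == 1

    def test_h_tube_topology(self, cal3d):
        segs = [
            ((10, 10, 5), (10, 10, 75)),
            ((10, 50, 5), (10, 50, 75)),
            ((10, 10, 40), (10, 50, 40)),
        ]
        skel = skeletonize_object(_lm(tube_mask_3d((20, 60, 80), segs, 4), cal3d), 1)
        assert len(skel.endpoints()) == 4
        assert branch_stats(skel)[0] == 2

    def test_tiny_object_degenerate(self, cal3d):
        arr = np.zeros((5, 5, 5), dtype=np.uint8)
        arr[2, 2, 2] = 1
        skel = skeletonize_object(LabelMap(arr, "mitochondrion", cal3d), 1)
        assert skel.degenerate
        assert skel.n_nodes == 1


class TestLength:
    def test_straight_tube_2um(self):
        maps, gt = render(
            PhantomSpec("cylinder", {"length_nm": 2000.0, "radius_nm": 40.0})
        )
        skel = skeletonize_object(maps["mito"], 1)
        length, fallback = object_length(skel, maps["mito"])
        assert not fallback
        assert length == pytest.approx(gt.length_um, rel=0.05)

    @pytest.mark.parametrize("r_vox", [2, 4, 8])
    def test_tube_length_radius_invariant(self, r_vox):
        maps, gt = render(
            PhantomSpec("cylinder", {"length_nm": 2000.0, "radius_nm": r_vox * 10.0})
        )
        length, _ = object_length(skeletonize_object(maps["mito"], 1), maps["mito"])
        assert length == pytest.approx(gt.length_um, rel=0.05)

    def test_quarter_torus_arc_length(self):
        maps, gt = render(
            PhantomSpec("bent_tube", {"arc_radius_nm": 1000.0, "tube_radius_nm": 100.0})
        )
        length, fallback = object_length(skeletonize_object(maps["mito"], 1), maps["mito"])
        assert not fallback
        assert length == pytest.approx(gt.length_um, rel=0.05)

    def test_sphere_feret_fallback(self):
        maps, gt = render(PhantomSpec("sphere", {"radius_nm": 200.0}))
        length, fallback = object_length(skeletonize_object(maps["mito"], 1), maps["mito"])
        assert fallback
        assert length == pytest.approx(0.4, rel=0.05)

    def test_anisotropic_resampling(self, cal3d_aniso):
        # 2 um tube along z in a 10x10x50 nm grid
        mask = np.zeros((50, 24, 24), dtype=bool)
        z = np.arange(50)[:, None, None]
        y = np.arange(24)[None, :, None]
        x = np.arange(24)[None, None, :]
        mask |= ((y - 12) ** 2 + (x - 12) ** 2 <= 16) & (z >= 5) & (z <= 45)
        length, _ = object_length(
            skeletonize_object(_lm(mask, cal3d_aniso), 1), _lm(mask, cal3d_aniso)
        )
        assert length == pytest.approx(2.0, rel=0.08)


class TestBranching:
    def test_straight_not_hyperbranched(self, cal3d):
        mask = tube_mask_3d((20, 20, 80), [((10, 10, 5), (10, 10, 75))], 4)
        n, hyper = branch_stats(skeletonize_object(_lm(mask, cal3d), 1))
        assert (n, hyper) == (0, False)

    def test_four_side_branches_hyperbranched(self, cal3d):
        segs = [((10, 30, 5), (10, 30, 115))]
        for xb in (25, 45, 65, 85):
            segs.append(((10, 30, xb), (10, 55, xb)))
        mask = tube_mask_3d((20, 64, 120), segs, 4)
        n, hyper = branch_stats(skeletonize_object(_lm(mask, cal3d), 1))
        assert n == 4
        assert hyper


class TestMoas:
    def test_moas_params_validation(self):
        with pytest.raises(ValueError):
            MoasParams(tunnel_radius_frac=1.5)
        with pytest.raises(ValueError):
            MoasParams(min_bulbs=1)

    def test_beads_on_string_detected(self):
        maps, gt = render(
            PhantomSpec(
                "beads_on_string",
                {
                    "n_bulbs": 3,
                    "bulb_radius_nm": 200.0,
                    "tunnel_radius_nm": 40.0,
                    "tunnel_length_nm": 500.0,
                },
            )
        )
        assert gt.moas is True
        skel = skeletonize_object(maps["mito"], 1)
        moas, tunnels = detect_moas(skel)
        assert moas
        assert tunnels == 2

    def test_uniform_tube_not_moas(self):
        maps, _ = render(
            PhantomSpec("cylinder", {"length_nm": 2000.0, "radius_nm": 150.0})
        )
        moas, _ = detect_moas(skeletonize_object(maps["mito"], 1))
        assert not moas

    def test_single_ellipsoid_not_moas(self):
        maps, _ = render(PhantomSpec("sphere", {"radius_nm": 250.0}))
        moas, _ = detect_moas(skeletonize_object(maps["mito"], 1))
        assert not moas

    def test_analytic_rule_matches_defaults(self):
        assert moas_rule(200.0, 40.0, 500.0, 3)
        assert not moas_rule(150.0, 60.0, 500.0, 3)  # 60 > 0.35*150
        assert not moas_rule(200.0, 40.0, 100.0, 3)  # tunnel too short
        assert not moas_rule(80.0, 20.0, 500.0, 3)  # bulbs too small


class TestPipeline:
    def test_analyze_full_record(self):
        maps, gt = render(PhantomSpec("beads_on_string", {}))
        rec = analyze_objects_3d(maps["mito"])[0]
        assert rec.moas == gt.moas
        assert rec.tunnel_segments == gt.tunnel_segments
        assert rec.junction_count == 0
        assert rec.volume_um3 > 0
        assert rec.surface_area_um2 > 0
        assert rec.moas is False or rec.tunnel_segments >= 1
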