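import numpy as np
import pytest

from mitometry.core import Calibration, LabelMap, LabelMapError
from mitometry.merc import (
    MercConfig,
    annotate_ca_band,
    boundary_gap_field,
    brute_force_gap_field,
    detect_contacts_2d,
    detect_contacts_3d,
)
from mitometry.phantom import PhantomSpec, render


def _pair_2d(mito_arr, er_arr, px_nm=10.0):
    cal = Calibration(px_nm, px_nm)
    return (
        LabelMap(mito_arr.astype(np.uint8), "mitochondrion", cal),
        LabelMap(er_arr.astype(np.uint8), "er", cal),
    )


class TestConfig:
    def test_defaults(self):
        cfg = MercConfig()
        assert cfg.gap_threshold_nm == 50.0
        assert cfg.ca_band_nm == (15.0, 30.0)
        assert cfg.merge_gap_px == 2

    def test_validation(self):
        with pytest.raises(ValueError):
            MercConfig(gap_threshold_nm=0)
        with pytest.raises(ValueError):
            MercConfig(ca_band_nm=(30.0, 15.0))


class TestGapField:
    def test_parallel_edges_30nm(self):
        mito = np.zeros((20, 20))
        er = np.zeros((20, 20))
        mito[5, 2:18] = 1
        er[8, 2:18] = 1  # 3 px apart at 10 nm/px
        m, e = _pair_2d(mito, er)
        gap, er_b, _ = boundary_gap_field(m, e)
        facing = gap[8, 4:16]
        np.testing.assert_allclose(facing, 30.0)

    def test_distant_organelles(self):
        mito = np.zeros((120, 120))
        er = np.zeros((120, 120))
        mito[2:6, 2:6] = 1
        er[112:116, 112:116] = 1
        m, e = _pair_2d(mito, er)
        gap, er_b, _ = boundary_gap_field(m, e)
        assert gap[er_b].min() >= 1000.0

    def test_overlap_zero_with_warning(self):
        arr = np.zeros((10, 10))
        arr[3:7, 3:7] = 1
        m, e = _pair_2d(arr, arr)
        with pytest.warns(UserWarning, match="overlap"):
            gap, er_b, _ = boundary_gap_field(m, e)
        assert gap[er_b].max() == 0.0

    def test_matches_bruteforce_2d(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            mito = (rng.random((48, 64)) < 0.07).astype(np.uint8)
            er = (rng.random((48, 64)) < 0.07).astype(np.uint8)
            er[mito > 0] = 0
            if not mito.any() or not er.any():
                continue
            m, e = _pair_2d(mito, er)
            gap, er_b, _ = boundary_gap_field(m, e)
            brute = brute_force_gap_field(m, e)
            np.testing.assert_allclose(gap[er_b], brute[er_b], rtol=1e-9)

    def test_matches_bruteforce_3d_anisotropic(self):
        rng = np.random.default_rng(9)
        cal = Calibration(10.0, 10.0, 50.0)
        mito = (rng.random((12, 24, 32)) < 0.05).astype(np.uint8)
        er = (rng.random((12, 24, 32)) < 0.05).astype(np.uint8)
        er[mito > 0] = 0
        m = LabelMap(mito, "mitochondrion", cal)
        e = LabelMap(er, "er", cal)
        gap, er_b, _ = boundary_gap_field(m, e)
        brute = brute_force_gap_field(m, e)
        np.testing.assert_allclose(gap[er_b], brute[er_b], rtol=1e-9)

    def test_shape_mismatch(self, cal2d):
        m = LabelMap(np.ones((5, 5), dtype=np.uint8), "mitochondrion", cal2d)
        e = LabelMap(np.ones((6, 6), dtype=np.uint8), "er", cal2d)
        with pytest.raises(LabelMapError):
            boundary_gap_field(m, e)


class TestDetect2D:
    def test_parallel_membranes_phantom(self):
        maps, gt = render(PhantomSpec("apposed_pair_2d", {"gap_nm": 30.0}))
        sites = detect_contacts_2d(maps["mito"], maps["er"])
        assert len(sites) == 1
        s = sites[0]
        assert s.mean_gap_nm == pytest.approx(30.0)
        assert s.contact_length_um == pytest.approx(gt.contact_length_um, rel=0.02)
        assert s.min_gap_nm <= s.mean_gap_nm <= s.max_gap_nm <= 50.0

    def test_gap_above_threshold_no_sites(self):
        maps, _ = render(PhantomSpec("apposed_pair_2d", {"gap_nm": 60.0}))
        assert detect_contacts_2d(maps["mito"], maps["er"]) == []

    def test_coverage_er_quarter(self):
        # square ER loop, one full side within threshold -> ~25%
        mito = np.zeros((80, 80))
        er = np.zeros((80, 80))
        er[30:51, 30:51] = 1  # 21x21 solid square: boundary is its outline
        mito[10:28, 28:53] = 1  # slab above the top side, 3 px center gap
        m, e = _pair_2d(mito, er)
        sites = detect_contacts_2d(m, e, MercConfig(gap_threshold_nm=32.0))
        assert len(sites) == 1
        assert sites[0].coverage_er_pct == pytest.approx(25.0, abs=5.0)

    def test_threshold_monotonicity(self):
        maps, _ = render(PhantomSpec("apposed_pair_2d", {"gap_nm": 30.0}))
        totals = []
        for thr in (30.0, 40.0, 60.0, 100.0):
            sites = detect_contacts_2d(
                maps["mito"], maps["er"], MercConfig(gap_threshold_nm=thr)
            )
            totals.append(sum(s.contact_length_um for s in sites))
        assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_coverage_bounded(self):
        maps, _ = render(PhantomSpec("wrap_sheath", {}))
        for s in detect_contacts_2d(maps["mito"], maps["er"]):
            assert 0.0 <= s.coverage_mito_pct <= 100.0
            assert 0.0 <= s.coverage_er_pct <= 100.0

    def test_wrap_sheath_full_mito_coverage(self):
        maps, _ = render(PhantomSpec("wrap_sheath", {}))
        sites = detect_contacts_2d(maps["mito"], maps["er"])
        assert len(sites) == 1
        assert sites[0].coverage_mito_pct == pytest.approx(100.0, abs=2.0)

    def test_merge_gap_bridges_small_breaks(self):
        mito = np.zeros((20, 60))
        er = np.zeros((20, 60))
        mito[5, 2:58] = 1
        er[8, 2:28] = 1
        er[8, 30:58] = 1  # 2-px break
        m, e = _pair_2d(mito, er)
        sites = detect_contacts_2d(m, e, MercConfig(merge_gap_px=2))
        assert len(sites) == 1
        sites = detect_contacts_2d(m, e, MercConfig(merge_gap_px=0))
        assert len(sites) == 2


class TestDetect3D:
    def test_parallel_slabs_phantom(self):
        maps, gt = render(
            PhantomSpec("apposed_slabs_3d", {"gap_nm": 30.0, "side_nm": 1000.0})
        )
        sites = detect_contacts_3d(maps["mito"], maps["er"])
        assert len(sites) == 1
        s = sites[0]
        assert s.mean_gap_nm == pytest.approx(30.0)
        assert s.contact_area_um2 == pytest.approx(gt.contact_area_um2, rel=0.02)
        assert s.cleft_volume_um3 == pytest.approx(gt.cleft_volume_um3, rel=0.05)

    def test_slabs_geodesic_diagonal(self):
        maps, gt = render(
            PhantomSpec("apposed_slabs_3d", {"gap_nm": 30.0, "side_nm": 1000.0})
        )
        s = detect_contacts_3d(maps["mito"], maps["er"])[0]
        assert s.contact_length_um == pytest.approx(np.sqrt(2.0), rel=0.02)

    def test_200nm_gap_no_patches(self):
        maps, _ = render(PhantomSpec("apposed_slabs_3d", {"gap_nm": 200.0}))
        assert detect_contacts_3d(maps["mito"], maps["er"]) == []

    def test_threshold_monotone_area(self):
        maps, _ = render(
            PhantomSpec("apposed_slabs_3d", {"gap_nm": 30.0, "side_nm": 500.0})
        )
        areas = []
        for thr in (30.0, 50.0, 80.0):
            sites = detect_contacts_3d(
                maps["mito"], maps["er"], MercConfig(gap_threshold_nm=thr)
            )
            areas.append(sum(s.contact_area_um2 for s in sites))
        assert all(b >= a - 1e-12 for a, b in zip(areas, areas[1:]))

    def test_anisotropic_gap_recovery(self):
        # px_z = 5 x px_x; error bounded by one voxel's physical diagonal
        maps, gt = render(
            PhantomSpec(
                "apposed_slabs_3d",
                {"gap_nm": 100.0, "side_nm": 500.0, "px_z_nm": 50.0},
            )
        )
        sites = detect_contacts_3d(
            maps["mito"], maps["er"], MercConfig(gap_threshold_nm=150.0)
        )
        diag = np.sqrt(50.0**2 + 10.0**2 + 10.0**2)
        assert abs(sites[0].mean_gap_nm - gt.gap_nm) <= diag


class TestCaBand:
    def _site(self, mean_gap):
        from mitometry.merc import ContactSite

        return ContactSite(
            mito_id=1, er_id=1, dims=2, contact_length_um=1.0,
            mean_gap_nm=mean_gap, min_gap_nm=mean_gap, max_gap_nm=mean_gap,
            coverage_mito_pct=10.0, coverage_er_pct=10.0,
        )

    @pytest.mark.parametrize(
        "gap,expected",
        [(20.0, True), (40.0, False), (30.0, True), (15.0, True), (14.9, False)],
    )
    def test_band_inclusive(self, gap, expected):
        (out,) = annotate_ca_band([self._site(gap)])
        assert out.in_ca_band is expected


class TestSymmetry:
    def test_swapped_roles_swap_coverages(self):
        # same-size mirrored slabs: swapping maps swaps the coverage roles
        cal = Calibration(10.0, 10.0)
        a = np.zeros((30, 60), dtype=np.uint8)
        b = np.zeros((30, 60), dtype=np.uint8)
        a[8:13, 5:55] = 1
        b[16:21, 5:55] = 1
        m1 = LabelMap(a, "mitochondrion", cal)
        e1 = LabelMap(b, "er", cal)
        m2 = LabelMap(b, "mitochondrion", cal)
        e2 = LabelMap(a, "er", cal)
        s1 = detect_contacts_2d(m1, e1)[0]
        s2 = detect_contacts_2d(m2, e2)[0]
        assert s1.coverage_mito_pct == pytest.approx(s2.coverage_er_pct, abs=2.0)
        assert s1.coverage_er_pct == pytest.approx(s2.coverage_mito_pct, abs=2.0)
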