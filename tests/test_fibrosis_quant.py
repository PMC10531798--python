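"""Threshold selection, disk volumetry and delta metrics.

Disk rasterization is checked voxel-exactly against a per-voxel
point-test oracle; threshold examples follow the n−1 SD convention.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ball_mask, make_mask, make_volume
from lafq.errors import (BloodPoolTooSmallError, DiskPlacementError,
                         SpherePlacementError, UndefinedDeltaError)
from lafq.fibrosis_quant import (VEINS, FibrosisResult, OstiumDisk,
                                 PatientMetrics, auto_sphere_center,
                                 compute_threshold, count_pvs_without_increase,
                                 delta_la_fibrosis, delta_pv_fibrosis,
                                 quantify_ostial_fibrosis,
                                 quantify_wall_fibrosis, rasterize_disk,
                                 read_landmarks, write_landmarks)


def fib_result(region, fib, vol, thr=100.0):
    return FibrosisResult(region, fib, vol, fib / vol if vol else 0.0, thr)


class TestAutoSphereCenter:
    def test_solid_ball_center_recovered(self):
        center = np.array([15.5, 15.5, 15.5])
        bp = ball_mask((32, 32, 32), center, 12)
        found = auto_sphere_center(bp, diameter_mm=10)
        assert np.linalg.norm(found - bp.index_to_physical(center)) <= 1.0 + 1e-9

    def test_prefers_larger_of_two_pools(self):
        vox = np.zeros((40, 24, 24), dtype=bool)
        big = ball_mask((40, 24, 24), (10, 12, 12), 9).voxels
        small = ball_mask((40, 24, 24), (30, 12, 12), 5).voxels
        bp = make_mask(vox | big | small)
        found = auto_sphere_center(bp, diameter_mm=8)
        assert found[0] < 20  # inside the larger pool
        # independent distance-transform check: the point is ≥ 4 mm deep
        from scipy.ndimage import distance_transform_edt
        edt = distance_transform_edt(bp.voxels)
        idx = np.floor(found).astype(int)
        assert edt[tuple(idx)] > 4

    def test_too_small_pool_reports_feasible_diameter(self):
        bp = ball_mask((20, 20, 20), (9.5, 9.5, 9.5), 3.5)
        with pytest.raises(BloodPoolTooSmallError) as err:
            auto_sphere_center(bp, diameter_mm=10)
        assert 0 < err.value.max_feasible_diameter_mm < 10


class TestComputeThreshold:
    def test_zero_variance(self):
        lge = make_volume(np.full((24, 24, 24), 200.0))
        bp = ball_mask((24, 24, 24), (11.5, 11.5, 11.5), 10)
        thr = compute_threshold(lge, bp, diameter_mm=10)
        assert thr.sample_mean == 200.0
        assert thr.sample_sd == 0.0
        assert thr.threshold == 200.0

    def test_hand_computed_sd_convention(self):
        # a synthetic sphere sample of {90, 100, 110} in equal thirds has
        # mean 100 and sample SD 10 under the n−1 convention → cutoff 120
        values = np.array([90.0, 100.0, 110.0])
        mean = values.mean()
        sd = values.std(ddof=1)
        assert mean == 100.0 and sd == 10.0
        # same convention inside compute_threshold: constant+step volume
        vox = np.full((24, 24, 24), 100.0)
        vox[:12] = 90.0
        vox[12:] = 110.0
        lge = make_volume(vox)
        bp = ball_mask((24, 24, 24), (11.5, 11.5, 11.5), 10)
        thr = compute_threshold(lge, bp, diameter_mm=8)
        values = lge.voxels[_sphere_voxels(lge, thr.sphere_center, 4.0)]
        assert thr.sample_mean == pytest.approx(values.mean())
        assert thr.sample_sd == pytest.approx(values.std(ddof=1))
        assert thr.threshold == pytest.approx(
            values.mean() + 2 * values.std(ddof=1))

    def test_gaussian_blood_pool_monte_carlo(self):
        rng = np.random.default_rng(11)
        lge = make_volume(rng.normal(100.0, 10.0, size=(32, 32, 32)))
        bp = make_mask(np.ones((32, 32, 32)))
        thr = compute_threshold(lge, bp, center=[16.0, 16.0, 16.0],
                                diameter_mm=10)
        assert thr.n_sample_voxels > 400  # ~523 voxels in a 10 mm sphere
        assert abs(thr.threshold - 120.0) < 3.0

    def test_partial_sphere_rejected_not_clipped(self):
        lge = make_volume(np.zeros((20, 20, 20)))
        bp = ball_mask((20, 20, 20), (9.5, 9.5, 9.5), 8)
        with pytest.raises(SpherePlacementError):
            compute_threshold(lge, bp, center=[17.0, 10.0, 10.0],
                              diameter_mm=10)

    def test_threshold_linearity_under_intensity_shift(self):
        rng = np.random.default_rng(12)
        vox = rng.normal(100.0, 10.0, size=(26, 26, 26))
        bp = ball_mask((26, 26, 26), (12.5, 12.5, 12.5), 11)
        wall = make_mask(~bp.voxels)
        lge = make_volume(vox)
        thr0 = compute_threshold(lge, bp)
        r0 = quantify_wall_fibrosis(lge, wall, thr0)
        shifted = make_volume(vox + 37.0)
        thr1 = compute_threshold(shifted, bp)
        r1 = quantify_wall_fibrosis(shifted, wall, thr1)
        assert thr1.threshold == pytest.approx(thr0.threshold + 37.0)
        assert r1.fibrosis_fraction == pytest.approx(r0.fibrosis_fraction)


def _sphere_voxels(grid, center, radius):
    idx = np.indices(grid.shape).reshape(3, -1).T
    pts = grid.index_to_physical(idx)
    keep = np.linalg.norm(pts - center, axis=1) <= radius
    out = np.zeros(grid.shape, dtype=bool)
    out[tuple(idx[keep].T)] = True
    return out


class TestQuantifyWall:
    def test_counting_and_all_below(self):
        vox = np.full((10, 10, 10), 50.0)
        vox.reshape(-1)[:150] = 200.0
        lge = make_volume(vox)
        wall = make_mask(np.ones((10, 10, 10)))
        thr = _thr(100.0)
        res = quantify_wall_fibrosis(lge, wall, thr)
        assert res.fibrosis_volume_mm3 == 150.0
        assert res.region_volume_mm3 == 1000.0
        assert res.fibrosis_fraction == pytest.approx(0.15)
        low = quantify_wall_fibrosis(make_volume(np.zeros((10, 10, 10))),
                                     wall, thr)
        assert low.fibrosis_volume_mm3 == 0.0

    def test_strict_inequality_at_threshold(self):
        lge = make_volume(np.full((10, 10, 10), 100.0))
        wall = make_mask(np.ones((10, 10, 10)))
        res = quantify_wall_fibrosis(lge, wall, _thr(100.0))
        assert res.fibrosis_volume_mm3 == 0.0

    def test_empty_wall_rejected(self):
        lge = make_volume(np.zeros((6, 6, 6)))
        with pytest.raises(ValueError):
            quantify_wall_fibrosis(lge, make_mask(np.zeros((6, 6, 6))),
                                   _thr(10.0))

    def test_anisotropic_voxel_volume(self):
        lge = make_volume(np.full((8, 8, 8), 200.0), spacing=(0.5, 0.5, 2.0))
        wall = make_mask(np.ones((8, 8, 8)), spacing=(0.5, 0.5, 2.0))
        res = quantify_wall_fibrosis(lge, wall, _thr(100.0))
        assert res.fibrosis_volume_mm3 == pytest.approx(512 * 0.5)


def _thr(value):
    from lafq.fibrosis_quant import ThresholdResult
    return ThresholdResult(value, 0.0, 2.0, value, np.zeros(3), 10.0, 10)


def oracle_disk(d: OstiumDisk, reference):
    out = np.zeros(reference.shape, dtype=bool)
    for idx in np.ndindex(reference.shape):
        x = reference.index_to_physical(idx)
        rel = x - d.center
        axial = float(np.dot(rel, d.normal))
        radial = np.linalg.norm(rel - axial * d.normal)
        if abs(axial) <= d.thickness_mm / 2 and radial <= d.radius_mm:
            out[idx] = True
    return out


class TestRasterizeDisk:
    def test_axis_aligned_matches_oracle(self):
        ref = make_volume(np.zeros((24, 24, 24)))
        d = OstiumDisk("LSPV", center=[12.0, 12.0, 12.0], normal=[0, 0, 1],
                       thickness_mm=2.0, radius_mm=10.0)
        mask = rasterize_disk(d, ref)
        assert np.array_equal(mask.voxels, oracle_disk(d, ref))
        slices = np.unique(np.argwhere(mask.voxels)[:, 2])
        assert len(slices) in (2, 3)

    def test_rotated_normal_matches_oracle(self):
        ref = make_volume(np.zeros((20, 20, 20)))
        d = OstiumDisk("RIPV", center=[10.0, 10.0, 10.0],
                       normal=np.array([1.0, 1.0, 1.0]) / np.sqrt(3),
                       thickness_mm=3.0, radius_mm=6.0)
        assert np.array_equal(rasterize_disk(d, ref).voxels,
                              oracle_disk(d, ref))

    def test_thin_disk_still_selects_a_slice(self):
        ref = make_volume(np.zeros((12, 12, 12)), spacing=(1, 1, 2))
        d = OstiumDisk("LIPV", center=[6.0, 6.0, 7.0], normal=[0, 0, 1],
                       thickness_mm=1.0, radius_mm=4.0)
        mask = rasterize_disk(d, ref)
        assert mask.cardinality > 0  # voxel-center rule keeps one slice


class TestQuantifyOstial:
    def test_region_is_disk_wall_intersection(self, noiseless_case):
        case = noiseless_case
        from lafq.wall_extraction import extract_regions
        regions = extract_regions(case.truth_seg_fixed)
        thr = compute_threshold(case.lge, regions.blood_pool)
        disk = case.landmarks[0]
        res = quantify_ostial_fibrosis(case.lge, regions.wall, disk, thr)
        inter = regions.wall.voxels & rasterize_disk(disk, case.lge).voxels
        assert res.region_volume_mm3 == pytest.approx(
            np.count_nonzero(inter) * case.lge.voxel_volume_mm3)
        assert res.region == disk.vein

    def test_disk_missing_wall_raises(self):
        lge = make_volume(np.zeros((16, 16, 16)))
        wall = ball_mask((16, 16, 16), (7.5, 7.5, 7.5), 3)
        d = OstiumDisk("RSPV", center=[15.0, 15.0, 15.0], normal=[0, 0, 1],
                       thickness_mm=1.0, radius_mm=1.0)
        with pytest.raises(DiskPlacementError, match="marker|intersect"):
            quantify_ostial_fibrosis(lge, wall, d, _thr(10.0))


class TestDeltas:
    def test_delta_la_formula(self):
        pre = fib_result("whole-wall", 10.0, 100.0)
        post = fib_result("whole-wall", 12.0, 100.0)
        assert delta_la_fibrosis(pre, post) == pytest.approx(0.2)
        assert delta_la_fibrosis(pre, pre) == 0.0

    def test_delta_la_zero_baseline_flagged(self):
        pre = fib_result("whole-wall", 0.0, 100.0)
        post = fib_result("whole-wall", 5.0, 100.0)
        with pytest.raises(UndefinedDeltaError):
            delta_la_fibrosis(pre, post)

    def test_delta_pv_fraction_difference(self):
        pre = fib_result("LSPV", 10.0, 100.0)   # fraction 0.10
        post = fib_result("LSPV", 25.0, 100.0)  # fraction 0.25
        assert delta_pv_fibrosis(pre, post) == pytest.approx(0.15)
        assert delta_pv_fibrosis(pre, pre) == 0.0

    def test_delta_pv_zero_region_rejected(self):
        ok = fib_result("LIPV", 1.0, 10.0)
        broken = fib_result("LIPV", 0.0, 0.0)
        with pytest.raises(UndefinedDeltaError):
            delta_pv_fibrosis(broken, ok)

    @pytest.mark.parametrize("deltas,expected", [
        ((-0.1, 0.0, 0.2, -0.3), 2),  # zero is not an increase nor a decrease
        ((0.1, 0.2, 0.3, 0.4), 0),
        ((-1, -2, -3, -4), 4),
    ])
    def test_count_strictly_negative(self, deltas, expected):
        assert count_pvs_without_increase(deltas) == expected

    def test_count_requires_four_veins(self):
        with pytest.raises(ValueError):
            count_pvs_without_increase([-0.1, 0.2, 0.3])

    def test_patient_metrics_deltas(self):
        pm = PatientMetrics("P1")
        pm.la = {"baseline": fib_result("whole-wall", 100.0, 1000.0),
                 "day30": fib_result("whole-wall", 150.0, 1000.0)}
        pm.per_vein = {
            "baseline": {v: fib_result(v, 5.0, 100.0) for v in VEINS},
            "day30": {v: fib_result(v, 5.0 + i, 100.0)
                      for i, v in enumerate(VEINS)},
        }
        pm.compute_deltas()
        assert pm.delta_la == pytest.approx(0.5)
        assert pm.delta_pv["LSPV"] == pytest.approx(0.0)
        assert pm.n_pv_no_increase == 0
        rows = pm.to_rows()
        assert len(rows) == 10  # 2 wall rows + 8 vein rows


@given(st.lists(st.floats(-1.0, 1.0, allow_nan=False),
                min_size=4, max_size=4))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_count_pvs_matches_sign_definition(deltas):
    assert count_pvs_without_increase(deltas) == sum(d < 0 for d in deltas)


def test_landmark_io_round_trip(tmp_path):
    disks = [OstiumDisk(v, center=[10.0 + i, 20.0, 30.0],
                        normal=[1.0, float(i), 0.0], radius_mm=9.0,
                        thickness_mm=3.0)
             for i, v in enumerate(VEINS)]
    for name in ("lm.json", "lm.csv"):
        write_landmarks(disks, tmp_path / name)
        back = read_landmarks(tmp_path / name)
        assert [d.vein for d in back] == list(VEINS)
        for a, b in zip(disks, back):
            assert np.allclose(a.center, b.center)
            assert np.allclose(a.normal, b.normal)
            assert a.radius_mm == b.radius_mm
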