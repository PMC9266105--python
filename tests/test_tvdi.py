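import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from tvdizone.featurespace import EdgeFit
from tvdizone.rasters import Raster, ZoneMap
from tvdizone.tvdi import (classify_drought, composite_max, compute_tvdi,
                           mosaic_zones, smooth_ndvi)


def edge(a1=20.0, b1=5.0, a2=40.0, b2=-10.0, lo=0.0, hi=1.0):
    return EdgeFit(zone_id=1, a1=a1, b1=b1, a2=a2, b2=b2, r2_wet=1, r2_dry=1,
                   n_bins_used=10, ndvi_lo=lo, ndvi_hi=hi)


class TestCompositeMax:
    def test_single_raster_is_identity(self):
        r = Raster(np.array([[1.0, np.nan], [3.0, 4.0]]))
        out = composite_max([r])
        np.testing.assert_array_equal(out.data, r.data)

    def test_matches_brute_force_elementwise_max(self):
        rng = np.random.default_rng(0)
        stack = rng.normal(size=(12, 15, 15))
        stack[rng.random(stack.shape) < 0.2] = np.nan
        rasters = [Raster(s) for s in stack]
        out = composite_max(rasters)
        expected = np.full((15, 15), np.nan)
        for i in range(15):
            for j in range(15):
                vals = stack[:, i, j]
                vals = vals[~np.isnan(vals)]
                if vals.size:
                    expected[i, j] = vals.max()
        np.testing.assert_array_equal(out.data, expected)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            composite_max([])


class TestSmoothNdvi:
    def test_polynomial_sequences_pass_through(self):
        t = np.arange(15, dtype=float)
        quad = 0.1 + 0.02 * t - 0.001 * t**2
        np.testing.assert_allclose(smooth_ndvi(quad, 5, 2), quad, atol=1e-10)
        ramp = 0.1 + 0.03 * t
        np.testing.assert_allclose(smooth_ndvi(ramp, 5, 2), ramp, atol=1e-10)

    def test_spike_reduced_and_matches_sg_convolution(self):
        seq = np.full(11, 0.5)
        seq[5] = 0.9
        out = smooth_ndvi(seq, 5, 2)
        assert abs(out[5] - 0.5) < abs(seq[5] - 0.5)
        # centre value equals explicit convolution with the SG kernel
        coeffs = savgol_coeffs(5, 2)
        assert out[5] == pytest.approx(coeffs @ seq[3:8], abs=1e-12)

    def test_short_series_passthrough_and_nan_remasked(self):
        short = np.array([0.1, 0.2, 0.3])
        np.testing.assert_array_equal(smooth_ndvi(short, 5, 2), short)
        seq = np.linspace(0, 1, 12)
        seq[4] = np.nan
        out = smooth_ndvi(seq, 5, 2)
        assert np.isnan(out[4]) and np.isfinite(np.delete(out, 4)).all()

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_ndvi(np.zeros(10), 4, 2)


class TestComputeTvdi:
    def test_wet_and_dry_edge_endpoints(self):
        e = edge()
        ndvi = Raster(np.array([[0.4, 0.4]]))
        wet_val = e.wet(0.4)
        dry_val = e.dry(0.4)
        lst = Raster(np.array([[wet_val, dry_val]]))
        res = compute_tvdi(lst, ndvi, e)
        np.testing.assert_allclose(res.grid.data, [[0.0, 1.0]], atol=1e-12)

    def test_midpoint_arithmetic(self):
        # LST 30 between LSTmin 20 and LSTmax 40 -> 0.5
        e = edge(a1=20.0, b1=0.0, a2=40.0, b2=0.0)
        res = compute_tvdi(Raster(np.array([[30.0]])), Raster(np.array([[0.5]])), e)
        assert res.grid.data[0, 0] == pytest.approx(0.5)

    def test_noiseless_scene_inverts_to_one_minus_wetness(self, noiseless_scene):
        s = noiseless_scene
        for z in s.zone_map.zone_ids:
            a1, b1, a2, b2 = s.config.true_edges_per_zone[z - 1]
            e = edge(a1, b1, a2, b2)
            res = compute_tvdi(s.lst_raster(0, 0), s.ndvi_raster(0, 0), e,
                               mask=s.zone_map.mask_for(z))
            m = s.zone_map.mask_for(z)
            err = np.abs(res.grid.data[m] - (1 - s.wetness_truth[0, 0][m]))
            assert np.nanmax(err) <= 1e-10

    def test_out_of_range_ndvi_and_degenerate_pixels_masked(self):
        e = edge(lo=0.2, hi=1.0)
        ndvi = Raster(np.array([[0.1, 0.5]]))
        lst = Raster(np.array([[25.0, 25.0]]))
        res = compute_tvdi(lst, ndvi, e)
        assert np.isnan(res.grid.data[0, 0]) and res.n_out_of_range == 1
        # edges meeting at the pixel's NDVI -> degenerate
        e2 = edge(a1=20.0, b1=20.0, a2=40.0, b2=-20.0)  # meet at ndvi 0.5
        res2 = compute_tvdi(lst, Raster(np.array([[0.5, 0.5]])), e2)
        assert res2.n_degenerate == 2

    def test_values_clipped_into_unit_interval_and_counted(self):
        e = edge(a1=20.0, b1=0.0, a2=40.0, b2=0.0)
        lst = Raster(np.array([[15.0, 45.0, 30.0]]))
        res = compute_tvdi(lst, Raster(np.full((1, 3), 0.5)), e)
        assert res.n_clipped == 2
        assert np.nanmin(res.grid.data) >= 0 and np.nanmax(res.grid.data) <= 1


class TestClassifyDrought:
    def test_boundaries_belong_to_lower_class(self):
        vals = Raster(np.array([[0.0, 0.2, 0.4, 0.6, 0.8, 1.0]]))
        grades, types = classify_drought(vals)
        np.testing.assert_array_equal(grades.data, [[1, 1, 2, 3, 4, 5]])
        np.testing.assert_array_equal(types.data, [[0, 0, 0, 0, 1, 2]])

    def test_typical_drought_pixel(self):
        grades, types = classify_drought(Raster(np.array([[0.66]])))
        assert grades.data[0, 0] == 4  # dry
        assert types.data[0, 0] == 1   # drought

    def test_grades_partition_dense_unit_interval(self):
        vals = Raster(np.linspace(0, 1, 5001).reshape(1, -1))
        grades, types = classify_drought(vals)
        assert set(np.unique(grades.data)) <= {1, 2, 3, 4, 5}
        assert (grades.data > 0).all()  # every pixel in exactly one grade
        # types consistent with grades
        assert np.array_equal(types.data == 1, grades.data == 4)
        assert np.array_equal(types.data == 2, grades.data == 5)

    def test_nodata_propagates(self):
        grades, _ = classify_drought(Raster(np.array([[np.nan, 0.3]])))
        assert grades.data[0, 0] == -1 and grades.data[0, 1] == 2


class TestMosaic:
    def test_single_zone_identity(self):
        zones = ZoneMap(np.ones((4, 4), dtype=int))
        grid = Raster(np.random.default_rng(0).random((4, 4)))
        out, diag = mosaic_zones({1: grid}, zones)
        np.testing.assert_array_equal(out.data, grid.data)
        assert diag.n_boundary_pairs == 0

    def test_missing_zone_grid_raises_with_ids(self):
        zones = ZoneMap(np.array([[1, 2], [1, 2]]))
        with pytest.raises(ValueError, match=r"\[2\]"):
            mosaic_zones({1: Raster(np.zeros((2, 2)))}, zones)

    def test_boundary_diagnostic_detects_edge_effect(self):
        rng = np.random.default_rng(1)
        zones = ZoneMap(np.repeat([[1, 1, 1, 2, 2, 2]], 6, axis=0))
        smooth = rng.random((6, 6)) * 0.05
        identical = {1: Raster(smooth), 2: Raster(smooth)}
        _, diag_same = mosaic_zones(identical, zones)
        shifted = {1: Raster(smooth), 2: Raster(smooth + 0.5)}
        _, diag_diff = mosaic_zones(shifted, zones)
        # identical edges: boundary pairs look like within-zone pairs
        assert diag_same.boundary_mean_abs_diff == pytest.approx(
            diag_same.within_mean_abs_diff, abs=0.05)
        # offset zones: discontinuity shows up only across the boundary
        assert diag_diff.boundary_mean_abs_diff > diag_diff.within_mean_abs_diff

    def test_diagnostic_matches_brute_force_neighbor_differences(self):
        rng = np.random.default_rng(2)
        zones = ZoneMap(np.repeat([[1, 1, 2, 2]], 4, axis=0))
        grids = {1: Raster(rng.random((4, 4))), 2: Raster(rng.random((4, 4)))}
        out, diag = mosaic_zones(grids, zones)
        b, w = [], []
        for i in range(4):
            for j in range(4):
                for di, dj in ((0, 1), (1, 0)):
                    ii, jj = i + di, j + dj
                    if ii < 4 and jj < 4:
                        d = abs(out.data[i, j] - out.data[ii, jj])
                        (w if zones.data[i, j] == zones.data[ii, jj] else b).append(d)
        assert diag.boundary_mean_abs_diff == pytest.approx(np.mean(b), abs=1e-12)
        assert diag.within_mean_abs_diff == pytest.approx(np.mean(w), abs=1e-12)
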