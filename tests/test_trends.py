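import numpy as np
import pytest

from tvdizone.rasters import Raster, ZoneMap
from tvdizone.trends import (area_fractions, classify_trend, trend_grid,
                             trend_slope, trend_test)


class TestTrendSlope:
    def test_constant_series_has_zero_slope(self):
        assert trend_slope(np.full(10, 0.4)) == pytest.approx(0.0, abs=1e-14)

    def test_exact_line_recovers_slope(self):
        i = np.arange(1, 21)
        assert trend_slope(0.01 * i) == pytest.approx(0.01, abs=1e-14)

    def test_closed_form_equals_ols_on_random_series(self):
        rng = np.random.default_rng(0)
        series = rng.random((500, 20))
        ours = trend_slope(series)
        i = np.arange(1, 21, dtype=float)
        oracle = np.array([np.polyfit(i, s, 1)[0] for s in series])
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_short_or_gappy_series(self):
        assert np.isnan(trend_slope(np.array([0.1, 0.2])))
        gappy = np.array([0.1, np.nan, 0.3, 0.4, np.nan, 0.6])
        i = np.array([1, 3, 4, 6], dtype=float)
        y = np.array([0.1, 0.3, 0.4, 0.6])
        assert trend_slope(gappy) == pytest.approx(np.polyfit(i, y, 1)[0], abs=1e-12)


class TestTrendTest:
    def test_exact_line_is_maximally_significant(self):
        _s, t, p = trend_test(0.02 * np.arange(1, 21))
        assert p < 1e-15

    def test_t_matches_scipy_linregress(self):
        from scipy.stats import linregress
        rng = np.random.default_rng(1)
        y = rng.random(20)
        _s, t, p = trend_test(y)
        ref = linregress(np.arange(1, 21), y)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_type_one_error_near_nominal_level(self):
        rng = np.random.default_rng(2)
        series = rng.normal(size=(5000, 20))
        _s, _t, p = trend_test(series)
        rate = (p <= 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.012)

    def test_null_t_distribution_symmetric(self):
        rng = np.random.default_rng(3)
        _s, t, _p = trend_test(rng.normal(size=(4000, 15)))
        assert np.mean(t) == pytest.approx(0.0, abs=0.05)
        assert abs((t > 0).mean() - 0.5) < 0.03


class TestClassifyTrend:
    @pytest.mark.parametrize("slope,p,expected", [
        (-0.003, 0.2, 3),    # non-significant decrease
        (0.004, 0.03, 5),    # significant increase
        (-0.01, 0.005, 1),   # extremely significant decrease
        (0.01, 0.06, 4),
        (0.01, 0.05, 5),     # boundary -> more significant class
        (0.01, 0.01, 6),
        (-0.01, 0.05, 2),
        (-0.01, 0.01, 1),
        (0.0, 0.5, 4),       # zero slope -> non-significant increase
    ])
    def test_rule_table(self, slope, p, expected):
        assert classify_trend(np.array(slope), np.array(p)) == expected

    def test_grid_matches_independent_rule(self):
        def oracle(slope, p):
            if not (np.isfinite(slope) and np.isfinite(p)):
                return -1
            if p <= 0.01:
                level = "extreme"
            elif p <= 0.05:
                level = "significant"
            else:
                level = "none"
            if slope < 0:
                return {"extreme": 1, "significant": 2, "none": 3}[level]
            return {"extreme": 6, "significant": 5, "none": 4}[level]

        rng = np.random.default_rng(4)
        slopes = rng.normal(0, 0.01, 400)
        ps = np.concatenate([rng.uniform(0, 1, 396), [0.01, 0.05, 0.049, 0.011]])
        ours = classify_trend(slopes, ps)
        expected = np.array([oracle(s, p) for s, p in zip(slopes, ps)])
        np.testing.assert_array_equal(ours, expected)

    def test_classes_exhaustive_on_boundary_grid(self):
        slopes = np.array([-1e-3, 1e-3]).repeat(6)
        ps = np.tile([0.0, 0.01, 0.049999, 0.05, 0.050001, 1.0], 2)
        cls = classify_trend(slopes, ps)
        assert set(cls) <= set(range(1, 7))


class TestAreaFractions:
    def test_uniform_and_hand_counted_grids(self):
        zones = ZoneMap(np.ones((4, 4), dtype=int))
        uniform = Raster(np.full((4, 4), 4), nodata=-1)
        frac = area_fractions(uniform, zones)
        assert frac.loc[1, "TVDI-t4"] == 1.0
        assert frac.loc[1].sum() == pytest.approx(1.0)

        hand = np.full((4, 4), 3)
        hand[0, :2] = 6
        hand[3, 3] = 1
        frac2 = area_fractions(Raster(hand, nodata=-1), zones)
        assert frac2.loc[1, "TVDI-t6"] == pytest.approx(2 / 16)
        assert frac2.loc[1, "TVDI-t1"] == pytest.approx(1 / 16)
        assert frac2.loc[1, "TVDI-t3"] == pytest.approx(13 / 16)

    def test_fractions_sum_to_one_per_zone(self, small_scene):
        from tvdizone.pipeline import (PipelineConfig, annual_composites,
                                       fit_zone_edges, tvdi_mosaic)
        s = small_scene
        cfg = PipelineConfig(scene=s.config)
        annual = []
        for yi in range(len(s.config.years)):
            n, l = annual_composites(s, yi)
            annual.append(tvdi_mosaic(n, l, s.zone_map, fit_zone_edges(n, l, s.zone_map, cfg)))
        _slope, _p, cls = trend_grid(annual)
        frac = area_fractions(cls, s.zone_map)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_zone_gives_nan_row(self):
        zones = ZoneMap(np.array([[1, 2], [1, 2]]))
        cls = Raster(np.array([[4, -1], [4, -1]]), nodata=-1)
        frac = area_fractions(cls, zones)
        assert frac.loc[2].isna().all()
        assert frac.loc[1, "TVDI-t4"] == 1.0


def test_rejection_rate_increases_with_planted_slope():
    rng = np.random.default_rng(5)
    rates = []
    for planted in (0.0, 0.006, 0.02):
        series = planted * np.arange(1, 21) + rng.normal(0, 0.05, (800, 20))
        _s, _t, p = trend_test(series)
        rates.append((p <= 0.05).mean())
    assert rates[0] < rates[1] < rates[2]


def test_planted_trend_fraction_recovered():
    rng = np.random.default_rng(6)
    n_years, side = 15, 30
    base = rng.normal(0.5, 0.03, (side, side, n_years))
    planted = np.zeros((side, side), dtype=bool)
    planted[: side // 2] = True  # top half trends upward strongly
    base[planted] += 0.02 * np.arange(1, n_years + 1)
    grids = [Raster(base[:, :, k]) for k in range(n_years)]
    _s, _p, cls = trend_grid(grids)
    zones = ZoneMap(np.ones((side, side), dtype=int))
    frac = area_fractions(cls, zones)
    # planted pixels are overwhelmingly significant increases, null pixels
    # only at the test's false-positive rate, so the significant-increase
    # fraction recovers the planted proportion
    strong = frac.loc[1, ["TVDI-t5", "TVDI-t6"]].sum()
    assert strong == pytest.approx(0.5, abs=0.05)
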