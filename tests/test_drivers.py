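import numpy as np
import pytest

from tvdizone.drivers import (DRIVER_CLASS_NAMES, driver_zoning,
                              driver_zoning_grid, multiple_F, multiple_corr,
                              partial_corr, partial_t)
from tvdizone.rasters import Raster


def orthogonalize(v, *others):
    """Residual of v after projecting onto span{1, others} (sample-exact)."""
    A = np.column_stack([np.ones(len(v)), *others])
    beta, *_ = np.linalg.lstsq(A, v, rcond=None)
    return v - A @ beta


class TestPartialCorr:
    def test_reduces_to_pearson_when_control_orthogonal(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 30))
        z = orthogonalize(rng.normal(size=30), x, y)
        rxy = np.corrcoef(x, y)[0, 1]
        assert partial_corr(x, y, z) == pytest.approx(rxy, abs=1e-10)

    def test_duplicate_series_gives_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        assert partial_corr(x, x.copy(), z) == pytest.approx(1.0, abs=1e-12)

    def test_equals_residual_correlation_oracle(self):
        rng = np.random.default_rng(2)
        x, y, z = rng.normal(size=(3, 1000, 18))
        ours = partial_corr(x, y, z)
        oracle = np.empty(1000)
        for i in range(1000):
            rx = x[i] - np.polyval(np.polyfit(z[i], x[i], 1), z[i])
            ry = y[i] - np.polyval(np.polyfit(z[i], y[i], 1), z[i])
            oracle[i] = np.corrcoef(rx, ry)[0, 1]
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_symmetric_in_first_two_arguments(self):
        rng = np.random.default_rng(3)
        x, y, z = rng.normal(size=(3, 50, 18))
        np.testing.assert_allclose(partial_corr(x, y, z), partial_corr(y, x, z),
                                   atol=1e-13)

    def test_degenerate_inputs_give_nan(self):
        x = np.arange(10.0)
        assert np.isnan(partial_corr(x, np.ones(10), x))       # constant y
        assert np.isnan(partial_corr(x, x[::-1], 2 * x + 1))   # |Rxz| = 1


class TestMultipleCorr:
    def test_perfect_and_null_relationships(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=24)
        z = rng.normal(size=24)
        assert multiple_corr(x, x.copy(), z) == pytest.approx(1.0, abs=1e-10)
        y2 = orthogonalize(rng.normal(size=24), x)
        z2 = orthogonalize(rng.normal(size=24), x, y2)
        assert multiple_corr(x, y2, z2) == pytest.approx(0.0, abs=1e-10)

    def test_equals_two_covariate_regression_r2(self):
        rng = np.random.default_rng(5)
        x, y, z = rng.normal(size=(3, 1000, 18))
        ours = multiple_corr(x, y, z)
        oracle = np.empty(1000)
        for i in range(1000):
            A = np.column_stack([np.ones(18), y[i], z[i]])
            beta, *_ = np.linalg.lstsq(A, x[i], rcond=None)
            resid = x[i] - A @ beta
            oracle[i] = 1 - resid @ resid / ((x[i] - x[i].mean()) @ (x[i] - x[i].mean()))
        np.testing.assert_allclose(ours**2, oracle, atol=1e-10)

    def test_at_least_max_of_simple_correlations(self):
        rng = np.random.default_rng(6)
        x, y, z = rng.normal(size=(3, 200, 18))
        R = multiple_corr(x, y, z)
        rxy = np.array([np.corrcoef(a, b)[0, 1] for a, b in zip(x, y)])
        rxz = np.array([np.corrcoef(a, b)[0, 1] for a, b in zip(x, z)])
        assert (R + 1e-10 >= np.maximum(np.abs(rxy), np.abs(rxz))).all()


class TestSignificance:
    def test_null_statistics(self):
        t, p = partial_t(0.0, 18)
        assert t == 0.0 and p == pytest.approx(1.0)
        F, pF = multiple_F(0.0, 18)
        assert F == 0.0 and pF == pytest.approx(1.0)

    def test_perfect_correlation_limits(self):
        t, p = partial_t(1.0, 18)
        assert np.isinf(t) and p == 0.0

    def test_partial_t_type_one_error_near_nominal(self):
        rng = np.random.default_rng(7)
        x, y, z = rng.normal(size=(3, 5000, 18))
        r = partial_corr(x, y, z)
        _t, p = partial_t(r, 18)
        assert (p <= 0.05).mean() == pytest.approx(0.05, abs=0.012)


class TestDriverZoning:
    def test_explicit_rule_rows(self):
        n = 18
        strong, weak = 0.9, 0.1
        # precip partial significant, temp not, F significant
        assert driver_zoning(strong, weak, 0.9, n) == 1
        assert driver_zoning(weak, strong, 0.9, n) == 2
        assert driver_zoning(strong, strong, 0.95, n) == 3
        assert driver_zoning(weak, weak, 0.8, n) == 3   # F sig, neither partial
        assert driver_zoning(strong, weak, 0.2, n) == 4  # F not significant

    def test_grid_classes_match_independent_rule_oracle(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        n = 18
        r_p = rng.uniform(-1, 1, 500)
        r_t = rng.uniform(-1, 1, 500)
        R = rng.uniform(0, 1, 500)
        ours = driver_zoning(r_p, r_t, R, n)

        def oracle(rp, rt, RR):
            tp = abs(rp) * np.sqrt((n - 3) / (1 - rp**2))
            tt = abs(rt) * np.sqrt((n - 3) / (1 - rt**2))
            FF = (RR**2 / 2) / ((1 - RR**2) / (n - 3))
            t_crit = stats.t.ppf(1 - 0.025, n - 3)
            F_crit = stats.f.ppf(0.95, 2, n - 3)
            if FF < F_crit:
                return 4
            if tp >= t_crit and tt < t_crit:
                return 1
            if tt >= t_crit and tp < t_crit:
                return 2
            return 3

        expected = np.array([oracle(a, b, c) for a, b, c in zip(r_p, r_t, R)])
        np.testing.assert_array_equal(ours, expected)

    def test_classes_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(9)
        cls = driver_zoning(rng.uniform(-0.99, 0.99, 1000),
                            rng.uniform(-0.99, 0.99, 1000),
                            rng.uniform(0, 0.99, 1000), 18)
        assert set(np.unique(cls)) <= set(DRIVER_CLASS_NAMES)

    def test_planted_precipitation_driver_recovered(self):
        rng = np.random.default_rng(10)
        ny, side = 18, 25
        precip = rng.normal(500, 40, (ny, side, side))
        temp = rng.normal(5, 1, (ny, side, side))
        # TVDI responds to precipitation anomalies only
        tvdi = 0.5 - 0.002 * (precip - 500) + rng.normal(0, 0.01, precip.shape)
        res = driver_zoning_grid(tvdi, precip, temp, Raster(np.zeros((side, side))))
        assert res.area_percent.loc["precipitation driven", "percent"] > 50

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            driver_zoning_grid(np.zeros((3, 2, 2)), np.zeros((3, 2, 2)),
                               np.zeros((3, 2, 2)), Raster(np.zeros((2, 2))))
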