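"""Decay engine: Q10, rate rescaling, pool models, fitting, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from biochar_ghg import parameters
from biochar_ghg.decay import (
    CalibrationError,
    DecaySeries,
    PoolSet,
    calibrate_class_pools,
    fit_pools,
    fraction_remaining,
    q10,
    read_series,
    rescale_rate,
    select_model,
    simulate_series,
    write_series,
)


class TestQ10:
    def test_at_zero(self):
        assert q10(0.0) == pytest.approx(13.1)

    def test_hand_evaluated_at_10(self):
        # 1.1 + 12.0 * e^-1.9, hand calculation
        assert q10(10.0) == pytest.approx(1.1 + 12.0 * math.exp(-1.9),
                                          rel=1e-12)
        assert q10(10.0) == pytest.approx(2.8948, abs=1e-4)

    def test_asymptote(self):
        assert q10(1e6) == pytest.approx(1.1)
        assert q10(80.0) - 1.1 < 1e-4

    @given(st.floats(min_value=-20.0, max_value=60.0),
           st.floats(min_value=0.01, max_value=10.0))
    def test_strictly_decreasing_and_above_asymptote(self, t, dt):
        assert q10(t) > q10(t + dt) > 1.1


def _oracle_factor(t_ref, t_target, n=200_001):
    """Independent fine-step trapezoid of ln Q10(T)/10."""
    grid = np.linspace(t_ref, t_target, n)
    vals = np.log(1.1 + 12.0 * np.exp(-0.19 * grid)) / 10.0
    return math.exp(np.trapezoid(vals, grid))


class TestRescaleRate:
    def test_identity(self):
        assert rescale_rate(0.37, 15.0, 15.0) == 0.37

    def test_against_independent_quadrature(self):
        k = 0.01
        expect = k * _oracle_factor(14.9, 10.0)
        assert rescale_rate(k, 14.9, 10.0) == pytest.approx(expect, rel=1e-6)

    def test_against_scipy_quad(self):
        integral, _ = quad(
            lambda u: math.log(1.1 + 12.0 * math.exp(-0.19 * u)) / 10.0,
            14.9, 25.0,
        )
        assert rescale_rate(1.0, 14.9, 25.0) == pytest.approx(
            math.exp(integral), rel=1e-8)

    def test_round_trip_inverse(self):
        k = 0.05
        back = rescale_rate(rescale_rate(k, 10.0, 22.3), 22.3, 10.0)
        assert back == pytest.approx(k, rel=1e-9)

    @given(st.floats(min_value=0.0, max_value=30.0),
           st.floats(min_value=0.1, max_value=10.0))
    def test_monotone_in_target(self, t, dt):
        assert rescale_rate(0.01, 14.9, t + dt) > rescale_rate(0.01, 14.9, t)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rescale_rate(-0.1, 10.0, 20.0)


class TestPoolSet:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PoolSet(fractions=(0.5, 0.4), rates=(0.1, 0.01),
                    reference_temp=14.9)

    def test_fast_to_slow_ordering_enforced(self):
        with pytest.raises(ValueError):
            PoolSet(fractions=(0.5, 0.5), rates=(0.01, 0.1),
                    reference_temp=14.9)

    def test_json_round_trip(self):
        p = PoolSet(fractions=(0.2, 0.8), rates=(0.1, 0.001),
                    reference_temp=14.9)
        assert PoolSet.from_json(p.to_json()) == p


class TestFractionRemaining:
    def test_one_at_time_zero(self):
        p = PoolSet(fractions=(0.3, 0.7), rates=(0.2, 0.002),
                    reference_temp=14.9)
        assert fraction_remaining(p, 0.0, 25.0) == pytest.approx(1.0)

    def test_single_pool_closed_form(self):
        p = PoolSet(fractions=(1.0,), rates=(0.01,), reference_temp=15.0)
        assert fraction_remaining(p, 100.0, 15.0) == pytest.approx(
            math.exp(-1.0), rel=1e-12)

    def test_two_pool_hand_value(self):
        # 0.1 e^-50 + 0.9 e^-0.1 at t=100, no temperature rescaling
        p = PoolSet(fractions=(0.1, 0.9), rates=(0.5, 0.001),
                    reference_temp=15.0)
        expect = 0.1 * math.exp(-50.0) + 0.9 * math.exp(-0.1)
        assert fraction_remaining(p, 100.0, 15.0) == pytest.approx(
            expect, rel=1e-12)
        assert expect == pytest.approx(0.8144, abs=5e-4)

    def test_negative_time_rejected(self):
        p = PoolSet(fractions=(1.0,), rates=(0.01,), reference_temp=15.0)
        with pytest.raises(ValueError):
            fraction_remaining(p, -1.0, 15.0)

    @given(st.floats(min_value=0.0, max_value=2000.0),
           st.floats(min_value=1.0, max_value=500.0),
           st.floats(min_value=5.0, max_value=25.0))
    def test_non_increasing_in_time(self, t, dt, temp):
        p = PoolSet(fractions=(0.25, 0.75), rates=(0.3, 0.004),
                    reference_temp=14.9)
        assert fraction_remaining(p, t + dt, temp) <= \
            fraction_remaining(p, t, temp) + 1e-12

    @given(st.floats(min_value=5.0, max_value=24.0),
           st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=0.0, max_value=1000.0))
    def test_non_increasing_in_soil_temp(self, temp, dtemp, t):
        p = PoolSet(fractions=(0.25, 0.75), rates=(0.3, 0.004),
                    reference_temp=14.9)
        assert fraction_remaining(p, t, temp + dtemp) <= \
            fraction_remaining(p, t, temp) + 1e-12

    def test_bounded(self):
        p = PoolSet(fractions=(0.5, 0.5), rates=(1.0, 0.01),
                    reference_temp=14.9)
        for t in (0.0, 1.0, 50.0, 5000.0):
            assert 0.0 <= fraction_remaining(p, t, 25.0) <= 1.0


class TestSimulateSeries:
    POOLS = PoolSet(fractions=(0.15, 0.85), rates=(0.4, 0.008),
                    reference_temp=20.0)

    def test_noiseless_matches_model_exactly(self):
        times = np.linspace(0, 5, 25)
        s = simulate_series(self.POOLS, times, 20.0, noise_sd=0.0)
        expect = fraction_remaining(self.POOLS, times, 20.0)
        assert np.allclose(s.values, expect, rtol=0, atol=0)

    def test_seed_determinism(self):
        times = np.linspace(0, 5, 25)
        a = simulate_series(self.POOLS, times, 20.0, noise_sd=0.02, seed=7)
        b = simulate_series(self.POOLS, times, 20.0, noise_sd=0.02, seed=7)
        assert a == b
        c = simulate_series(self.POOLS, times, 20.0, noise_sd=0.02, seed=8)
        assert a != c

    def test_noise_magnitude(self):
        times = np.linspace(0, 5, 50)
        s = simulate_series(self.POOLS, times, 20.0, noise_sd=0.01, seed=3)
        resid = np.array(s.values) - fraction_remaining(
            self.POOLS, times, 20.0)
        assert 0.006 <= resid.std(ddof=1) <= 0.014

    def test_clipping(self):
        s = simulate_series(self.POOLS, np.linspace(0, 2, 30), 20.0,
                            noise_sd=0.3, seed=1)
        assert max(s.values) <= 1.05 and min(s.values) >= 0.0

    def test_csv_round_trip(self, tmp_path):
        s = simulate_series(self.POOLS, np.linspace(0, 5, 12), 20.0,
                            noise_sd=0.01, seed=5, label="round-trip")
        path = tmp_path / "series.csv"
        write_series(s, path)
        back = read_series(path)
        assert back.incubation_temp == s.incubation_temp
        assert back.label == s.label
        assert np.allclose(back.times, s.times)
        assert np.allclose(back.values, s.values)


class TestDecaySeries:
    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError):
            DecaySeries(times=(0.0, 1.0, 1.0), values=(1.0, 0.9, 0.8),
                        incubation_temp=20.0)

    def test_rejects_large_overshoot(self):
        with pytest.raises(ValueError):
            DecaySeries(times=(0.0, 1.0), values=(1.1, 0.9),
                        incubation_temp=20.0)


class TestFitPools:
    TRUTH = PoolSet(fractions=(0.2, 0.8), rates=(0.5, 0.005),
                    reference_temp=20.0)

    def test_noiseless_recovery(self):
        times = np.linspace(0, 5, 25)
        series = simulate_series(self.TRUTH, times, 20.0, noise_sd=0.0)
        fit = fit_pools(series, 2)
        assert fit.pools.fractions == pytest.approx(self.TRUTH.fractions,
                                                    rel=1e-6)
        assert fit.pools.rates == pytest.approx(self.TRUTH.rates, rel=1e-6)
        assert fit.converged

    def test_noiseless_prediction_equivalence(self):
        times = np.linspace(0, 5, 25)
        series = simulate_series(self.TRUTH, times, 20.0, noise_sd=0.0)
        fit = fit_pools(series, 2)
        probe = np.linspace(0, 100, 40)
        assert np.allclose(
            fraction_remaining(fit.pools, probe, 20.0),
            fraction_remaining(self.TRUTH, probe, 20.0),
            rtol=1e-6, atol=1e-9,
        )

    def test_single_pool_data_nested_degeneracy(self):
        one = PoolSet(fractions=(1.0,), rates=(0.05,), reference_temp=20.0)
        times = np.linspace(0, 5, 25)
        series = simulate_series(one, times, 20.0, noise_sd=0.0)
        fit = fit_pools(series, 2)
        probe = np.linspace(0, 50, 30)
        assert np.allclose(
            fraction_remaining(fit.pools, probe, 20.0),
            fraction_remaining(one, probe, 20.0),
            rtol=0, atol=1e-6,
        )

    def test_noisy_recovery_within_bootstrap_sd(self):
        times = np.linspace(0, 5, 40)
        series = simulate_series(self.TRUTH, times, 20.0, noise_sd=0.01,
                                 seed=11)
        fit = fit_pools(series, 2)
        # residual bootstrap oracle at small B
        rng = np.random.default_rng(0)
        pred = fraction_remaining(fit.pools, np.asarray(series.times), 20.0)
        resid = np.array(series.values) - pred
        boot_fracs = []
        for _ in range(30):
            values = np.clip(pred + rng.choice(resid, size=resid.size,
                                               replace=True), 0.0, 1.05)
            bs = DecaySeries(times=series.times, values=tuple(values),
                             incubation_temp=20.0)
            boot_fracs.append(fit_pools(bs, 2).pools.fractions[0])
        sd = np.std(boot_fracs, ddof=1)
        assert abs(fit.pools.fractions[0] - self.TRUTH.fractions[0]) \
            <= 3 * max(sd, 1e-4)

    def test_short_series_rejected(self):
        times = np.linspace(0, 0.9, 20)
        series = simulate_series(self.TRUTH, times, 20.0)
        with pytest.raises(ValueError, match="1 year"):
            fit_pools(series, 2)

    def test_too_few_observations_rejected(self):
        series = simulate_series(self.TRUTH, np.linspace(0, 2, 4), 20.0)
        with pytest.raises(ValueError):
            fit_pools(series, 2)


class TestSelectModel:
    def test_clean_two_pool_data_selects_two(self):
        truth = PoolSet(fractions=(0.2, 0.8), rates=(0.5, 0.005),
                        reference_temp=20.0)
        series = simulate_series(truth, np.linspace(0, 5, 30), 20.0,
                                 noise_sd=0.002, seed=2)
        assert select_model(series) == 2

    def test_clean_three_pool_data_selects_three(self):
        truth = PoolSet(fractions=(0.3, 0.4, 0.3), rates=(2.0, 0.08, 0.001),
                        reference_temp=20.0)
        series = simulate_series(truth, np.linspace(0, 10, 80), 20.0,
                                 noise_sd=0.001, seed=4)
        assert select_model(series) == 3

    def test_short_data_errors(self):
        truth = PoolSet(fractions=(1.0,), rates=(0.05,), reference_temp=20.0)
        series = simulate_series(truth, np.linspace(0, 0.5, 30), 20.0)
        with pytest.raises(ValueError):
            select_model(series)


class TestCalibration:
    @pytest.mark.parametrize("cls", ["low", "medium", "high"])
    def test_reproduces_all_printed_cells(self, cls):
        pools = calibrate_class_pools(cls)
        assert pools.n_pools == 2
        assert pools.reference_temp == 14.9
        for cell in parameters.permanence_grid().cells:
            value, se = cell.fperm(cls)
            tol = max(0.03, se)
            pred = fraction_remaining(pools, cell.timeframe, cell.soil_temp)
            assert abs(pred - value) <= tol, (cls, cell.soil_temp,
                                              cell.timeframe)

    def test_spec_example_cells(self):
        med = calibrate_class_pools("medium")
        cell = parameters.get_permanence_cell(10.0, 100)
        assert fraction_remaining(med, 100, 10.0) == pytest.approx(
            0.79, abs=max(0.03, cell.fperm_medium[1]))
        low = calibrate_class_pools("low")
        cell = parameters.get_permanence_cell(14.9, 1000)
        assert fraction_remaining(low, 1000, 14.9) == pytest.approx(
            0.084, abs=max(0.03, cell.fperm_low[1]))

    @pytest.mark.parametrize("cls", ["low", "medium", "high"])
    def test_surface_is_one_at_time_zero(self, cls):
        pools = calibrate_class_pools(cls)
        for temp in (5.0, 14.9, 25.0):
            assert fraction_remaining(pools, 0.0, temp) == pytest.approx(1.0)

    def test_dense_grid_monotonicity_and_class_ordering(self):
        pools = {c: calibrate_class_pools(c)
                 for c in ("low", "medium", "high")}
        times = np.linspace(100, 1000, 13)
        temps = np.linspace(5, 25, 11)
        vals = {
            c: np.array([[fraction_remaining(p, t, T) for t in times]
                         for T in temps])
            for c, p in pools.items()
        }
        for v in vals.values():
            assert (np.diff(v, axis=1) <= 1e-12).all()  # time
            assert (np.diff(v, axis=0) <= 1e-12).all()  # temperature
        assert (vals["low"] <= vals["medium"] + 1e-9).all()
        assert (vals["medium"] <= vals["high"] + 1e-9).all()

    def test_failure_reports_worst_cell(self):
        # an infeasible target: temperature-independent values are
        # irreconcilable with the Q10 link between soil temperatures, and
        # near-flat decay to 500 y followed by a collapse at 1000 y violates
        # the complete monotonicity of a sum of exponentials
        grid = parameters.permanence_grid()
        fake = {100.0: 0.90, 500.0: 0.89, 1000.0: 0.05}
        cells = tuple(
            type(c)(
                soil_temp=c.soil_temp, timeframe=c.timeframe,
                fperm_low=(fake[c.timeframe], 0.001),
                fperm_medium=(fake[c.timeframe], 0.001),
                fperm_high=(fake[c.timeframe], 0.001),
                c_hc=c.c_hc, m_hc=c.m_hc, r2=c.r2,
            )
            for c in grid.cells
        )
        bad = type(grid)(cells=cells)
        with pytest.raises(CalibrationError, match="worst cell"):
            calibrate_class_pools("low", bad)
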