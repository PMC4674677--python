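"""Doubling-time estimators, OD calibration chain, transit time."""

import math

import numpy as np
import pytest

from dcdc.growth_inference import (
    EstimationError,
    ODCalibration,
    OnFractionSeries,
    alpha_correction,
    calibrated_od,
    fit_on_fraction_decay,
    fit_quadratic_calibration,
    fit_red_green,
    fold_spread_per_slowest_generation,
    generation_time_from_od,
    generation_times_from_trace,
    median_transit_time,
    percent_transmittance,
    raw_od_from_transmittance,
)


def noiseless_series(tau_h: float, f0: float = 0.7, n_points: int = 9,
                     n_total: int = 10**6) -> OnFractionSeries:
    t = np.arange(n_points) * tau_h
    frac = f0 * 2.0 ** (-t / tau_h)
    return OnFractionSeries(
        time_h=t,
        n_on=np.round(frac * n_total).astype(int),
        n_total=np.full(n_points, n_total),
    )


class TestFitOnFractionDecay:
    @pytest.mark.parametrize("tau", [0.55, 33.8 / 60.0])
    def test_exact_on_noiseless_series(self, tau):
        fit = fit_on_fraction_decay(
            noiseless_series(tau), exclude_lag=0, floor=None
        )
        assert fit.doubling_time == pytest.approx(tau, rel=1e-4)
        assert fit.r_squared > 0.999999

    def test_stochastic_recovery_within_three_percent(self):
        from dcdc.division_simulator import (
            SimulationParams,
            sample_cells,
            simulate_generations,
        )

        tau = 33.0 / 60.0
        params = SimulationParams(
            doubling_time=tau, initial_on=70_000, initial_off=30_000,
            p_false_per_gen=1e-3, seed=11,
        )
        series = simulate_generations(params, 6)
        ons = [
            sample_cells(int(o), int(n), 100_000, seed=500 + i)[0]
            for i, (o, n) in enumerate(zip(series.n_on, series.n_total))
        ]
        fit = fit_on_fraction_decay(
            OnFractionSeries(time_h=series.time_h, n_on=ons,
                             n_total=[100_000] * 7),
            exclude_lag=0,
            floor=None,
        )
        assert abs(fit.doubling_time - tau) / tau <= 0.03

    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 5.0])
    def test_recovery_across_order_of_magnitude(self, tau):
        """Doubling times spanning 0.5-5 h recovered within 5%."""
        from dcdc.division_simulator import (
            SimulationParams,
            sample_cells,
            simulate_generations,
        )

        params = SimulationParams(
            doubling_time=tau, initial_on=70_000, initial_off=30_000, seed=21,
        )
        series = simulate_generations(params, 8)
        ons = [
            sample_cells(int(o), int(n), 100_000, seed=600 + i)[0]
            for i, (o, n) in enumerate(zip(series.n_on, series.n_total))
        ]
        fit = fit_on_fraction_decay(
            OnFractionSeries(time_h=series.time_h, n_on=ons,
                             n_total=[100_000] * 9),
            exclude_lag=0,
            floor=None,
        )
        assert fit.doubling_time == pytest.approx(tau, rel=0.05)

    def test_lag_exclusion_keeps_decay_sign(self):
        """Dropping lag points never flips the slope on decaying input."""
        series = noiseless_series(1.0, n_points=10)
        for lag in range(0, 5):
            fit = fit_on_fraction_decay(series, exclude_lag=lag, floor=None)
            assert fit.slope < 0

    def test_floor_points_excluded_from_window(self):
        t = np.arange(12.0)
        frac = np.maximum(0.7 * 2.0 ** (-t), 1.1e-3)  # flattens at floor
        n_total = 100_000
        series = OnFractionSeries(
            time_h=t, n_on=np.round(frac * n_total).astype(int),
            n_total=np.full(12, n_total),
        )
        fit = fit_on_fraction_decay(series, exclude_lag=0, floor=1e-3)
        no_floor = fit_on_fraction_decay(series, exclude_lag=0, floor=None)
        assert fit.n_points < no_floor.n_points
        assert fit.doubling_time == pytest.approx(1.0, rel=0.01)
        assert no_floor.doubling_time > fit.doubling_time

    def test_no_decay_is_estimation_error(self):
        series = OnFractionSeries(
            time_h=np.arange(5.0), n_on=np.full(5, 500),
            n_total=np.full(5, 1000),
        )
        with pytest.raises(EstimationError, match="no decay"):
            fit_on_fraction_decay(series, exclude_lag=0, floor=None)

    def test_too_few_points_rejected(self):
        series = noiseless_series(1.0, n_points=4)
        with pytest.raises(ValueError):
            fit_on_fraction_decay(series, exclude_lag=2, floor=None)


class TestRedGreen:
    def test_noiseless_mice_pool_exactly(self):
        series = {f"m{i}": noiseless_series(2.91, n_points=6) for i in range(4)}
        fits, pooled, sd = fit_red_green(series, floor=None)
        assert pooled == pytest.approx(2.91, rel=1e-4)
        assert sd == pytest.approx(0.0, abs=1e-4)

    def test_constant_fraction_reports_no_decay(self):
        flat = OnFractionSeries(
            time_h=np.arange(2.0, 14.0, 2.0),
            n_on=np.full(6, 150),
            n_total=np.full(6, 100_000),
        )
        with pytest.warns(RuntimeWarning, match="no decay"):
            with pytest.raises(EstimationError, match="pooled estimate undefined"):
                fit_red_green({"m1": flat, "m2": flat}, floor=None)


class TestAlphaCorrection:
    def test_equal_times_give_zero(self):
        assert alpha_correction(0.5, 0.5).alpha == 0.0

    def test_identity_holds_exactly(self):
        corr = alpha_correction(32.9 / 60, 33.8 / 60)
        assert corr.alpha + 1 / corr.tau_on == pytest.approx(
            1 / corr.tau_od, abs=1e-12
        )
        assert corr.alpha == pytest.approx(0.049, abs=5e-4)

    def test_inverse_use_with_tabulated_alpha(self):
        # alpha = 1/24 h^-1 and tau_OD = 0.5 h imply tau_ON = 24/47 h
        tau_on = 1.0 / (1.0 / 0.5 - 1.0 / 24.0)
        corr = alpha_correction(0.5, tau_on)
        assert corr.alpha == pytest.approx(1 / 24, abs=1e-12)
        assert tau_on == pytest.approx(24 / 47, abs=1e-12)

    def test_negative_alpha_warns(self):
        with pytest.warns(RuntimeWarning):
            alpha_correction(1.0, 0.9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            alpha_correction(-1.0, 1.0)


class TestOdCalibrationChain:
    def test_transmittance_reference(self):
        assert percent_transmittance(500.0, 500.0) == 100.0
        assert percent_transmittance(250.0, 500.0) == 50.0
        assert raw_od_from_transmittance(50.0) == pytest.approx(
            math.log10(2), abs=1e-9
        )

    def test_transmittance_cap_guards_opaque_samples(self):
        assert raw_od_from_transmittance(1e-10) == 4.0
        assert raw_od_from_transmittance(0.0) == 4.0

    def test_identity_calibration(self):
        assert calibrated_od(0.3, ODCalibration(c1=1.0, c2=0.0)) == 0.3

    def test_quadratic_arithmetic(self):
        assert calibrated_od(0.1, ODCalibration(c1=0.5, c2=2.0)) == pytest.approx(
            0.07
        )

    def test_exact_coefficient_recovery(self):
        x = np.linspace(0.05, 0.5, 10)
        pairs = list(zip(x, 0.8 * x + 1.5 * x**2))
        c1, c2 = fit_quadratic_calibration(pairs)
        assert c1 == pytest.approx(0.8, abs=1e-10)
        assert c2 == pytest.approx(1.5, abs=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic_calibration([(0.2, 0.1)] * 5)

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0.05, 0.6, 20)
        errors = []
        for _ in range(20):
            y = (0.8 * x + 1.5 * x**2) * (1 + 0.01 * rng.standard_normal(20))
            c1, c2 = fit_quadratic_calibration(list(zip(x, y)))
            errors.append(max(abs(c1 / 0.8 - 1), abs(c2 / 1.5 - 1)))
            # round-trip OD error stays small
            od = calibrated_od(0.3, ODCalibration(c1=c1, c2=c2))
            assert od == pytest.approx(0.8 * 0.3 + 1.5 * 0.09, rel=0.02)
        assert np.median(errors) < 0.05


class TestGenerationTimeFromOd:
    def test_exact_exponential(self):
        t = np.linspace(0, 1, 10)
        series = list(zip(t, 0.2 * np.exp(1.386 * t)))
        assert generation_time_from_od(series) == pytest.approx(
            math.log(2) / 1.386, rel=1e-9
        )

    def test_reference_doubling_time(self):
        tau = 32.9 / 60.0
        t = np.linspace(0, 1, 12)
        series = list(zip(t, 0.2 * 2.0 ** (t / tau)))
        assert generation_time_from_od(series) == pytest.approx(tau, rel=1e-9)

    def test_declining_od_is_estimation_error(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(EstimationError):
            generation_time_from_od(list(zip(t, np.exp(-t))))

    def test_segmented_trace_recovery(self):
        from dcdc.synthetic_data import generate_turbidostat_trace

        cal = ODCalibration(c1=0.8, c2=1.5, blank=1000.0)
        trace = generate_turbidostat_trace(
            doubling_time=0.55, cal=cal, duration=4.0, noise_sd=0.0, seed=9
        )
        taus = generation_times_from_trace(trace, cal)
        assert len(taus) >= 5
        np.testing.assert_allclose(taus, 0.55, rtol=1e-6)


class TestTransitTime:
    def test_peak_at_six_hours_in_every_mouse(self):
        pulse = [(2.0, 0.0), (4.0, 0.1), (6.0, 0.3), (8.0, 0.2), (10.0, 0.15)]
        med, rate, peaks = median_transit_time({f"m{i}": pulse for i in range(8)})
        assert med == 6.0
        assert rate == pytest.approx(1 / 6)

    def test_single_mouse_symmetric_peak(self):
        pulse = [(2.0, 0.1), (4.0, 0.4), (6.0, 0.1)]
        med, _, _ = median_transit_time({"m1": pulse})
        assert med == 4.0

    def test_monotone_series_is_estimation_error(self):
        rising = [(2.0, 0.1), (4.0, 0.2), (6.0, 0.3)]
        with pytest.raises(EstimationError, match="no transit peak"):
            median_transit_time({"m1": rising})


class TestWorkedExample:
    def test_population_spread_across_doubling_time_range(self):
        """0.5-5 h doubling times: 2**10/2**1 = 512-fold spread."""
        assert fold_spread_per_slowest_generation(0.5, 5.0) == 512.0

    def test_equal_rates_give_unit_spread(self):
        assert fold_spread_per_slowest_generation(1.0, 1.0) == 1.0
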