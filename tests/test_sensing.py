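"""Calibration fit, sensor forward models and the band-filtration statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turbovent.sensing import (
    C_FROM_SYRINGE_TEST,
    C_FROM_TABLE,
    CalibrationTable,
    FilterConfig,
    SensorCalibration,
    analog_to_cmH2O,
    band_filter,
    fit_calibration,
    load_reference_table,
    simulate_flow_sensor,
    simulate_pressure_sensor,
    FLOW_RANGE_ML_S,
)


class TestAnalogConversion:
    def test_offset_reads_zero(self):
        cal = SensorCalibration(analog_offset=102, c_constant=0.208879)
        assert analog_to_cmH2O(102, cal) == 0.0

    def test_table_row_consistency(self):
        # 96 offset-subtracted counts at C = 0.208879 ~ the 20 cmH2O row
        cal = SensorCalibration(analog_offset=0, c_constant=0.208879)
        assert analog_to_cmH2O(96, cal) == pytest.approx(20.05, abs=0.01)

    def test_round_trip_with_forward_model_at_zero_noise(self):
        cal = SensorCalibration(analog_offset=100, c_constant=0.2)
        for counts_true in (0, 5, 96):
            p = counts_true * cal.c_constant
            counts = simulate_pressure_sensor(p, cal, noise_sd=0.0)
            assert analog_to_cmH2O(counts, cal) == pytest.approx(p)

    def test_presets_are_distinct_constants(self):
        assert C_FROM_TABLE == pytest.approx(0.208879)
        assert C_FROM_SYRINGE_TEST == pytest.approx(0.20916)


class TestPressureSensorModel:
    def test_zero_noise_zero_pressure_reads_offset(self):
        cal = SensorCalibration(analog_offset=102)
        assert simulate_pressure_sensor(0.0, cal, 0.0) == 102

    def test_known_pressure_maps_to_expected_counts(self):
        cal = SensorCalibration(analog_offset=102, c_constant=0.208879)
        counts = simulate_pressure_sensor(96 * 0.208879, cal, 0.0)
        assert counts == 102 + 96

    def test_sample_mean_unbiased(self):
        cal = SensorCalibration(analog_offset=102, c_constant=0.208879)
        rng = np.random.default_rng(0)
        n = 10_000
        noiseless = 96 + 102
        draws = [
            simulate_pressure_sensor(20.05237, cal, noise_sd=2.0, seed=rng)
            for _ in range(n)
        ]
        se = 2.0 / np.sqrt(n)
        assert abs(np.mean(draws) - noiseless) < 3 * se + 0.5  # +quantization

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_pressure_sensor(0.0, SensorCalibration(), noise_sd=-1.0)


class TestFitCalibration:
    def test_packaged_reference_table_slope(self):
        table = load_reference_table()
        assert len(table.pressures) == 21
        assert fit_calibration(table) == pytest.approx(0.208879, abs=5e-7)

    def test_exact_line_recovered(self):
        analogs = tuple(range(0, 101, 10))
        table = CalibrationTable(
            pressures=tuple(0.2 * a for a in analogs), analogs=analogs
        )
        assert fit_calibration(table) == pytest.approx(0.2)

    def test_noisy_table_recovers_true_slope_within_ci(self):
        rng = np.random.default_rng(3)
        analogs = np.arange(0, 105, 5, dtype=float)
        true_slope = 0.21
        pressures = true_slope * analogs + rng.normal(0, 0.05, analogs.size)
        table = CalibrationTable(
            pressures=tuple(pressures), analogs=tuple(analogs)
        )
        # 95% CI half-width for the OLS slope at this noise level
        from scipy import stats

        res = stats.linregress(analogs, pressures)
        assert abs(fit_calibration(table) - true_slope) < 2 * res.stderr + 1e-9

    def test_matches_closed_form_ols_slope(self):
        rng = np.random.default_rng(4)
        analogs = np.sort(rng.uniform(0, 100, 15))
        pressures = np.sort(rng.uniform(0, 20, 15))
        table = CalibrationTable(pressures=tuple(pressures), analogs=tuple(analogs))
        x, y = analogs, pressures
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit_calibration(table) == pytest.approx(slope, rel=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration(
                CalibrationTable(pressures=(0.0, 1.0, 2.0), analogs=(5.0, 5.0, 5.0))
            )

    def test_table_invariants(self):
        with pytest.raises(ValueError):
            CalibrationTable(pressures=(0.0,), analogs=(0.0,))
        with pytest.raises(ValueError):
            CalibrationTable(pressures=(0.0, 1.0), analogs=(5.0, 4.0))


class TestBandFilter:
    def test_zero_variance_keeps_everything(self):
        r = band_filter([5, 5, 5, 5], FilterConfig(window_size=4, shrink_percent=0.5))
        assert r.filtered_mean == 5.0
        assert r.n_kept == 4
        assert r.std_dev == 0.0

    def test_hand_computed_spike_example(self):
        # mean 28, population std 36, shrink 0.5 -> band [10, 46] keeps the 10s
        r = band_filter(
            [10, 10, 10, 10, 100], FilterConfig(window_size=5, shrink_percent=0.5)
        )
        assert r.mean == pytest.approx(28.0)
        assert r.std_dev == pytest.approx(36.0)
        assert r.std_shrink == pytest.approx(18.0)
        assert r.filtered_mean == pytest.approx(10.0)
        assert r.n_kept == 4

    def test_std_is_population_form(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = band_filter(x, FilterConfig(window_size=4, shrink_percent=0.0))
        assert r.std_dev == pytest.approx(np.std(x))  # /n, not /(n-1)

    def test_empty_band_falls_back_to_mean(self):
        # two clusters, huge shrink -> nothing inside the band
        r = band_filter(
            [0.0, 1.0], FilterConfig(window_size=2, shrink_percent=0.99)
        )
        assert r.n_kept == 0
        assert r.filtered_mean == r.mean

    def test_spike_rejection_beats_raw_mean(self):
        """On Gaussian windows carrying one 10-sigma spike the filtered mean
        is closer to the true level than the raw mean in >= 95% of seeded
        trials.  A 10-sample window is used so the single spike meaningfully
        corrupts the raw mean (the regime the filter exists for)."""
        rng = np.random.default_rng(42)
        n = 10
        cfg = FilterConfig(window_size=n, shrink_percent=0.5)
        true = 10.0
        wins = 0
        n_trials = 1000
        for _ in range(n_trials):
            x = rng.normal(true, 1.0, n)
            x[rng.integers(0, n)] += 10.0
            r = band_filter(x, cfg)
            if abs(r.filtered_mean - true) < abs(r.mean - true):
                wins += 1
        assert wins / n_trials >= 0.95

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
        st.floats(0.0, 0.99),
    )
    def test_filtered_mean_within_sample_range(self, xs, shrink):
        cfg = FilterConfig(window_size=len(xs), shrink_percent=shrink)
        r = band_filter(xs, cfg)
        assert min(xs) - 1e-9 <= r.filtered_mean <= max(xs) + 1e-9
        assert r.std_shrink == pytest.approx(r.std_dev * (1 - shrink))
        assert 0 <= r.n_kept <= len(xs)

    def test_zero_shrink_all_within_band_reproduces_mean(self):
        x = [9.0, 9.0, 11.0, 11.0]  # every sample exactly one std from the mean
        r = band_filter(x, FilterConfig(window_size=4, shrink_percent=0.0))
        assert r.n_kept == 4
        assert r.filtered_mean == pytest.approx(r.mean)

    def test_window_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="window_size"):
            band_filter([1, 2, 3], FilterConfig(window_size=4))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            FilterConfig(window_size=1)
        with pytest.raises(ValueError):
            FilterConfig(window_size=4, shrink_percent=1.0)


class TestFlowSensor:
    def test_zero_noise_identity(self):
        assert simulate_flow_sensor(123.4, 0.0) == 123.4

    def test_clipping_at_range_limits(self):
        assert simulate_flow_sensor(1e6, 0.0) == FLOW_RANGE_ML_S
        assert simulate_flow_sensor(-1e6, 0.0) == -FLOW_RANGE_ML_S

    def test_integrated_sensed_flow_tracks_volume(self, pcv_run):
        """Integrating the noisy sensed flow over an inhalation reproduces the
        delivered volume to within the noise tolerance."""
        df = pcv_run.to_dataframe()
        b = df[df.breath_index == 5]
        insp = b[b.phase == "inhale"]
        sensed = np.trapezoid(insp.flow_sensed, insp.time)
        true = np.trapezoid(np.clip(insp.flow_lung, 0, None), insp.time)
        assert sensed == pytest.approx(true, rel=0.05, abs=20.0)
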