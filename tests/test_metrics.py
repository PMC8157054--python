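"""Preprocessing steps and the TWA / CV exposure metrics."""

import numpy as np
import pytest

from sprayroom import (ConcentrationSeries, EmissionEvent, FlowParameters,
                       calibrate_signal, cv_over_time, fit_calibration,
                       normalize_by_mass, simulate_model1,
                       smooth_running_average, subtract_background, twa)


def _series(times, values, compartments, stage="calibrated", **meta):
    return ConcentrationSeries(times=np.asarray(times),
                               values=np.asarray(values),
                               compartments=compartments, stage=stage,
                               meta=meta)


@pytest.fixture
def eight(grid):
    times = np.linspace(-0.1, 0.4, 251)
    rng = np.random.default_rng(7)
    vals = rng.uniform(1.0, 10.0, (times.size, 8))
    return _series(times, vals, grid.labels)


class TestCalibration:
    def test_exact_linearity_gives_perfect_fit(self):
        masses = np.array([29.0, 58.0, 87.0])  # -> 100, 200, 300 mg/m3
        conc = masses / 0.29
        curve = fit_calibration(masses, 2.5 * conc)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.slope == pytest.approx(2.5)
        np.testing.assert_allclose(curve.to_concentration(2.5 * conc), conc)

    def test_slope_recovered_from_noisy_line(self):
        rng = np.random.default_rng(0)
        masses = np.linspace(20, 120, 12)
        conc = masses / 0.29
        signals = 3.0 * conc * (1 + 0.01 * rng.standard_normal(12)) + 5.0
        curve = fit_calibration(masses, signals)
        assert curve.slope == pytest.approx(3.0, rel=0.02)

    def test_rejects_underdetermined_or_decreasing_data(self):
        with pytest.raises(ValueError):
            fit_calibration([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_calibration([10.0, 20.0, 30.0], [30.0, 20.0, 10.0])

    def test_calibrate_signal_inverts_the_line(self, grid):
        times = np.linspace(0, 0.1, 11)
        conc = np.tile(np.linspace(1, 5, 11)[:, None], (1, 8))
        raw = _series(times, 4.0 * conc + 2.0, grid.labels,
                      stage="raw_signal")
        curve = fit_calibration([29, 58, 87],
                                4.0 * np.array([100, 200, 300.0]) + 2.0)
        cal = calibrate_signal(raw, curve)
        assert cal.stage == "calibrated"
        np.testing.assert_allclose(cal.values, conc, rtol=1e-9)


class TestBackgroundSubtraction:
    def test_constant_background_is_removed_exactly(self, grid):
        times = np.linspace(-0.1, 0.3, 200)
        b = np.arange(1.0, 9.0)
        vals = np.where(times[:, None] < 0, b, b + 10.0)
        out = subtract_background(_series(times, vals, grid.labels),
                                  (-0.1, 0.0))
        np.testing.assert_allclose(out.values[times < 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values[times >= 0], 10.0)
        assert out.stage == "background_subtracted"
        assert out.meta["background_mg_m3"]["222"] == pytest.approx(8.0)

    def test_zero_background_is_the_identity(self, eight):
        shifted = eight.with_values(np.where(eight.times[:, None] < 0, 0.0,
                                             eight.values))
        out = subtract_background(shifted, (-0.1, 0.0))
        np.testing.assert_allclose(out.values, shifted.values)

    def test_rejects_bad_windows(self, eight):
        with pytest.raises(ValueError):
            subtract_background(eight, (-0.5, -0.4))  # outside series
        with pytest.raises(ValueError):
            subtract_background(eight, (-0.05, -0.03))  # shorter than 5 min


class TestSmoothing:
    def test_constant_series_is_unchanged(self, grid):
        times = np.arange(0, 0.3, 1 / 360)
        out = smooth_running_average(
            _series(times, np.full((times.size, 8), 3.3), grid.labels))
        np.testing.assert_allclose(out.values, 3.3)
        np.testing.assert_array_equal(out.times, times)

    def test_unit_impulse_becomes_a_box_of_height_one_over_k(self, grid):
        times = np.arange(0, 0.5, 1 / 360)  # 10 s sampling
        vals = np.zeros((times.size, 8))
        mid = times.size // 2
        vals[mid, 0] = 1.0
        window = 2.5 / 60
        out = smooth_running_average(_series(times, vals, grid.labels),
                                     window)
        half = int(np.floor(window / (2 * (1 / 360))))
        k = 2 * half + 1
        box = out.values[:, 0]
        assert np.count_nonzero(box) == k
        np.testing.assert_allclose(box[mid - half:mid + half + 1], 1.0 / k)

    def test_noise_variance_shrinks_like_the_window_size(self, grid):
        rng = np.random.default_rng(1)
        times = np.arange(0, 2.0, 1 / 3600)
        sigma = 1.0
        vals = sigma * rng.standard_normal((times.size, 8))
        out = smooth_running_average(_series(times, vals, grid.labels))
        half = int(np.floor((2.5 / 60) / (2 / 3600)))
        k = 2 * half + 1
        interior = out.values[half:-half, :]
        assert interior.std() == pytest.approx(sigma / np.sqrt(k), rel=0.05)

    def test_rejects_window_below_twice_the_sampling_interval(self, grid):
        times = np.arange(0, 0.3, 1 / 60)  # 1 min sampling
        with pytest.raises(ValueError):
            smooth_running_average(
                _series(times, np.zeros((times.size, 8)), grid.labels),
                window=1.5 / 60)


class TestNormalization:
    def test_scaling_by_applied_mass(self, eight):
        out = normalize_by_mass(eight, applied_mass=2.0, reference_mass=1.0)
        np.testing.assert_allclose(out.values, eight.values / 2.0)
        assert out.stage == "normalized"
        same = normalize_by_mass(eight, 1.7, 1.7)
        np.testing.assert_allclose(same.values, eight.values)

    def test_commutes_with_smoothing(self, eight):
        # both operations are linear, so the order cannot matter
        smooth_then_scale = normalize_by_mass(smooth_running_average(eight),
                                              2.0)
        scale_then_smooth = smooth_running_average(
            eight.with_values(eight.values / 2.0))
        np.testing.assert_allclose(smooth_then_scale.values,
                                   scale_then_smooth.values)

    def test_rejects_non_positive_mass(self, eight):
        with pytest.raises(ValueError):
            normalize_by_mass(eight, 0.0)


class TestPipelineOrder:
    def test_out_of_order_application_is_refused(self, eight):
        normalized = normalize_by_mass(eight, 2.0)
        with pytest.raises(ValueError, match="out-of-order"):
            smooth_running_average(normalized)
        with pytest.raises(ValueError, match="out-of-order"):
            subtract_background(normalized, (-0.1, 0.0))
        smoothed = smooth_running_average(eight)
        with pytest.raises(ValueError, match="out-of-order"):
            subtract_background(smoothed, (-0.1, 0.0))


class TestCV:
    def test_equal_compartments_give_zero(self, grid):
        s = _series([0.0, 0.1], np.full((2, 8), 4.0), grid.labels)
        np.testing.assert_allclose(cv_over_time(s)["cv"], 0.0)

    def test_hand_computed_value(self, grid):
        vals = np.array([[1, 1, 1, 1, 1, 1, 1, 9.0]])
        s = _series([0.0], vals, grid.labels)
        # mean 2, sample sd sqrt(8) -> CV = sqrt(2)
        assert cv_over_time(s)["cv"].iloc[0] == pytest.approx(np.sqrt(2.0))
        pop = cv_over_time(s, ddof=0)["cv"].iloc[0]
        assert pop == pytest.approx(np.sqrt(7.0) / 2.0)

    def test_scale_invariance(self, eight):
        scaled = eight.with_values(eight.values * 37.0)
        np.testing.assert_allclose(cv_over_time(eight)["cv"],
                                   cv_over_time(scaled)["cv"])

    def test_low_mean_times_are_masked_not_divided(self, grid):
        vals = np.vstack([np.full(8, 1e-6), np.full(8, 100.0)])
        vals[0, 0] = 2e-6
        s = _series([0.0, 0.1], vals, grid.labels)
        cv = cv_over_time(s)["cv"]
        assert np.isnan(cv.iloc[0]) and cv.iloc[1] == pytest.approx(0.0)

    def test_requires_eight_compartments(self):
        s = _series([0.0], [[1.0, 2.0]], ("111", "112"))
        with pytest.raises(ValueError):
            cv_over_time(s)


class TestTWA:
    def test_constant_trace_has_twa_equal_to_the_constant(self, grid):
        times = np.linspace(0, 0.5, 100)
        s = _series(times, np.full((times.size, 8), 6.5), grid.labels)
        for dur in (0.1, 0.3):
            assert twa(s, "111", dur) == pytest.approx(6.5)

    def test_exponential_decay_window_ratio(self):
        times = np.linspace(0, 0.4, 4001)
        s = _series(times, 12.0 * np.exp(-times), ("WHOLE_ROOM",))
        ratio = twa(s, "WHOLE_ROOM", 0.1) / twa(s, "WHOLE_ROOM", 0.3)
        expected = ((1 - np.exp(-0.1)) / 0.1) / ((1 - np.exp(-0.3)) / 0.3)
        assert ratio == pytest.approx(expected, rel=1e-7)
        assert ratio == pytest.approx(1.1015, abs=5e-4)

    def test_bounded_by_window_extrema(self, eight):
        value = twa(eight, "121", 0.3, origin=0.0)
        window = (eight.times >= 0.0) & (eight.times <= 0.3)
        trace = eight.column("121")[window]
        assert trace.min() <= value <= trace.max()

    def test_rejects_window_past_series_end(self, eight):
        with pytest.raises(ValueError):
            twa(eight, "111", 1.0, origin=0.0)

    def test_well_mixed_table_pair(self):
        # a single-zone trace whose 0.3-h TWA is anchored at 22.9 mg/m3 has
        # a 0.1-h TWA of 25.2 mg/m3
        params = FlowParameters(30.0, 1.0, 0.0)
        times = np.linspace(0.0, 0.35, 2101)
        trial = simulate_model1(params, EmissionEvent(mass=1.0), times)
        mass = 22.9 / twa(trial, "WHOLE_ROOM", 0.3)
        out = simulate_model1(params, EmissionEvent(mass=mass), times)
        assert twa(out, "WHOLE_ROOM", 0.3) == pytest.approx(22.9, abs=1e-6)
        assert twa(out, "WHOLE_ROOM", 0.1) == pytest.approx(25.2, abs=0.05)
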