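"""ROI extraction, calibration, concentration and decay-constant recovery."""

import numpy as np
import pytest

import bubbletrace as bt
from bubbletrace.quantify import ROI, CalibrationCurve, IntensitySeries


def synthetic_series(d, c1=1.0, background=0.0, n=20, dt=0.77):
    t = np.arange(n) * dt + 0.25
    return IntensitySeries(times_s=t, means=c1 * np.exp(-d * t) + background)


def fitted_curve(slope=2.0, intercept=0.0, background=0.5, sigma=0.01):
    conc = np.array([0.0, 0.002, 0.005, 0.01])
    curve = CalibrationCurve(
        concentrations=conc,
        mean_intensities=background + intercept + slope * conc,
        background=background,
        sigma=sigma,
    )
    bt.fit_linear(curve)
    return curve


class TestROI:
    def test_central_roi_excludes_walls(self, grid, geometry):
        roi = bt.central_lumen_roi(grid, geometry, lumen_fraction=0.5)
        y = grid.pixel_y_centers_mm()
        rows = np.arange(roi.row_start, roi.row_stop)
        assert np.all(np.abs(y[rows]) <= geometry.inner_radius_mm)
        # full lumen fraction still stays off the wall
        roi_full = bt.central_lumen_roi(grid, geometry, lumen_fraction=1.0)
        rows_full = np.arange(roi_full.row_start, roi_full.row_stop)
        assert np.all(np.abs(y[rows_full]) <= geometry.inner_radius_mm)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            ROI(5, 5, 0, 3)

    def test_roi_outside_image_rejected(self, decay_sequence):
        roi = ROI(0, 10_000, 0, 2)
        with pytest.raises(ValueError):
            bt.roi_mean_series(decay_sequence, roi)

    def test_uniform_frame_mean_is_exact(self):
        from bubbletrace.simulate import ImageFrame, ImageSequence

        frame = ImageFrame(intensity=np.full((8, 6), 3.25), timestamp_s=0.0)
        seq = ImageSequence(frames=(frame,))
        series = bt.roi_mean_series(seq, ROI(1, 5, 1, 5))
        assert series.means[0] == 3.25


class TestBackgroundSubtraction:
    def test_self_subtraction_is_zero(self):
        s = synthetic_series(0.1, background=0.4)
        sub = bt.subtract_background(s, 0.4)
        assert np.allclose(sub.means, s.means - 0.4)

    def test_zero_subtraction_is_identity(self):
        s = synthetic_series(0.1)
        sub = bt.subtract_background(s, 0.0)
        assert np.array_equal(sub.means, s.means)

    def test_bubble_free_frame_subtracts_to_noise(
        self, background_stats
    ):
        bg_mean, bg_sigma, reps = background_stats
        # each replicate's subtracted ROI mean sits within 3 sigma of zero
        assert np.all(np.abs(reps - bg_mean) <= 3 * bg_sigma * np.sqrt(2))


class TestCalibration:
    def test_requires_zero_level(self, geometry, size_dist, grid, rocking_curve, working_point):
        with pytest.raises(ValueError):
            bt.build_calibration(
                [0.002, 0.005, 0.01], geometry, size_dist, grid,
                rocking_curve, working_point,
            )

    def test_requires_three_levels(self, geometry, size_dist, grid, rocking_curve, working_point):
        with pytest.raises(ValueError):
            bt.build_calibration(
                [0.0, 0.005], geometry, size_dist, grid, rocking_curve, working_point,
            )

    def test_subtracted_strictly_increasing(self, calibration):
        assert np.all(np.diff(calibration.subtracted) > 0)

    def test_zero_level_subtracts_to_zero(self, calibration):
        assert calibration.subtracted[0] == pytest.approx(0.0, abs=1e-12)

    def test_fit_quality(self, calibration):
        assert calibration.r_squared >= 0.95
        assert calibration.slope > 0

    def test_collinear_points_have_zero_residuals(self):
        curve = fitted_curve(slope=3.0)
        assert np.allclose(curve.residuals, 0.0, atol=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_degenerate_concentrations_rejected(self):
        curve = CalibrationCurve(
            concentrations=np.array([0.005, 0.005, 0.005]),
            mean_intensities=np.array([1.0, 1.1, 1.2]),
            background=0.0,
            sigma=0.01,
        )
        with pytest.raises(ValueError):
            bt.fit_linear(curve)


class TestEstimateConcentration:
    def test_zero_intensity_maps_to_zero(self):
        curve = fitted_curve(intercept=0.0)
        assert bt.estimate_concentration(0.0, curve) == 0.0

    def test_round_trip_at_calibrated_level(self):
        curve = fitted_curve(slope=2.0)
        intensity = 2.0 * 0.005
        assert bt.estimate_concentration(intensity, curve) == pytest.approx(0.005)

    def test_unfitted_curve_rejected(self):
        curve = CalibrationCurve(
            concentrations=np.array([0.0, 0.005, 0.01]),
            mean_intensities=np.array([0.5, 0.51, 0.52]),
            background=0.5,
            sigma=0.01,
        )
        with pytest.raises(ValueError):
            bt.estimate_concentration(0.01, curve)

    def test_extrapolation_warns(self):
        curve = fitted_curve()
        with pytest.warns(UserWarning, match="extrapolat"):
            bt.estimate_concentration(1.0, curve)

    def test_simulated_round_trip_bias(self, calibration):
        # invert the fit at every calibrated level; recovery within 10 %
        for c, sub in zip(
            calibration.concentrations[1:], calibration.subtracted[1:]
        ):
            est = bt.estimate_concentration(float(sub), calibration)
            assert est == pytest.approx(c, rel=0.10)


class TestDecayConstant:
    def test_noiseless_exponential_exact(self):
        s = synthetic_series(0.056, background=0.3, n=30)
        est = bt.estimate_decay_constant(s, 0.3, background_sigma=0.0, n_boot=50)
        assert est.d_hat == pytest.approx(0.056, rel=1e-10)
        assert est.ci_low <= est.d_hat <= est.ci_high

    def test_deterministic_bootstrap(self):
        s = synthetic_series(0.08, background=0.1, n=25)
        a = bt.estimate_decay_constant(s, 0.1, n_boot=100, seed=4)
        b = bt.estimate_decay_constant(s, 0.1, n_boot=100, seed=4)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_too_few_frames_rejected(self):
        s = synthetic_series(0.056, n=5)
        with pytest.raises(ValueError):
            bt.estimate_decay_constant(s, 0.0)

    def test_series_at_background_rejected(self):
        s = IntensitySeries(
            times_s=np.arange(10.0), means=np.full(10, 0.3)
        )
        with pytest.raises(ValueError, match="background"):
            bt.estimate_decay_constant(s, 0.3, background_sigma=0.01)

    def test_noise_floor_drops_low_frames(self):
        # frames below 3 sigma of background are excluded from the fit
        s = synthetic_series(0.2, c1=1.0, background=0.0, n=40)
        est = bt.estimate_decay_constant(s, 0.0, background_sigma=0.01, n_boot=50)
        kept = s.means > 0.03
        assert est.n_frames_used == int(kept.sum())
        assert est.d_hat == pytest.approx(0.2, rel=1e-8)

    def test_recovery_from_simulated_run(
        self, decay_sequence, roi, background_stats
    ):
        bg_mean, bg_sigma, _ = background_stats
        series = bt.roi_mean_series(decay_sequence, roi)
        est = bt.estimate_decay_constant(
            series, bg_mean, background_sigma=bg_sigma, n_boot=200, seed=0
        )
        assert est.d_hat == pytest.approx(0.056, rel=0.10)


class TestDetectionLimit:
    def test_scales_linearly_with_sigma(self):
        c1 = bt.detection_limit(fitted_curve(sigma=0.01), 5.0)
        c2 = bt.detection_limit(fitted_curve(sigma=0.02), 5.0)
        assert c2 == pytest.approx(2 * c1)
        assert bt.detection_limit(fitted_curve(sigma=0.0), 5.0) == 0.0

    def test_zero_slope_rejected(self):
        curve = fitted_curve()
        curve.slope = 0.0
        with pytest.raises(ValueError):
            bt.detection_limit(curve, 5.0)

    def test_simulated_benchmark_limit_is_finite(self, calibration):
        limit = bt.detection_limit(calibration, 5.0)
        assert 0.0 < limit < 0.01


class TestAlignment:
    def test_alignment_at_crossing(self):
        a = synthetic_series(0.1, c1=1.0, n=30)
        b = synthetic_series(0.1, c1=0.7, n=30)
        aligned = bt.align_at_intensity([a, b], 0.5)
        # after alignment both series cross the level at t = 0
        for s in aligned:
            interp = np.interp(0.0, s.times_s, s.means)
            assert interp == pytest.approx(0.5, rel=0.01)

    def test_series_never_crossing_unshifted(self):
        s = synthetic_series(0.1, c1=1.0, n=10)
        (out,) = bt.align_at_intensity([s], 1e-9)
        assert np.array_equal(out.times_s, s.times_s)
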