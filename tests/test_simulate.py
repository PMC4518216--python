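"""Ray tracing physics and frame rendering."""

import numpy as np
import pytest

import bubbletrace as bt
from bubbletrace.simulate import Ray


def single_sphere_phantom(geometry, center, radius_um):
    return bt.Phantom(
        geometry=geometry,
        centers_mm=np.asarray([center], dtype=float),
        radii_um=np.asarray([radius_um], dtype=float),
        target_concentration=0.0,
        seed=0,
    )


class TestClosedForm:
    def test_central_ray_undeviated(self):
        assert bt.sphere_deflection_closed_form(8e-7, 5.0, 0.0) == 0.0

    def test_unit_geometry_factor(self):
        # b = r/sqrt(2) makes b / sqrt(r^2 - b^2) = 1, so the deflection
        # is exactly 2 * delta_contrast
        d = bt.sphere_deflection_closed_form(8e-7, 5.0, 5.0 / np.sqrt(2))
        assert d == pytest.approx(1.6, rel=1e-9)

    def test_monotone_in_impact_parameter(self):
        b = np.linspace(0.0, 0.95 * 5.0, 100)
        d = [bt.sphere_deflection_closed_form(8e-7, 5.0, bi) for bi in b]
        assert np.all(np.diff(d) > 0)

    def test_grazing_rejected(self):
        with pytest.raises(ValueError):
            bt.sphere_deflection_closed_form(8e-7, 5.0, 5.0)
        with pytest.raises(ValueError):
            bt.sphere_deflection_closed_form(8e-7, 5.0, -1.0)


class TestTraceRay:
    def test_bubble_free_central_ray(self, empty_phantom, geometry, materials):
        ray = bt.trace_ray(Ray(x_mm=0.25, y_mm=0.0), empty_phantom, materials)
        expected = np.exp(
            -(
                materials["water"].mu * geometry.inner_diameter_mm
                + materials["nylon12"].mu * 2 * geometry.wall_thickness_mm
            )
        )
        assert ray.weight == pytest.approx(expected, rel=1e-12)
        assert ray.deflection_urad == 0.0  # normal incidence everywhere

    def test_ray_missing_phantom_unchanged(self, empty_phantom, materials):
        ray = bt.trace_ray(Ray(x_mm=0.25, y_mm=10.0), empty_phantom, materials)
        assert ray.weight == 1.0
        assert ray.deflection_urad == 0.0

    def test_sphere_deflection_matches_closed_form(self, geometry, materials):
        # isolate the bubble by differencing against the bubble-free trace
        rng = np.random.default_rng(123)
        dd = materials["water"].delta - materials["gas_core"].delta
        empty = bt.Phantom(
            geometry=geometry,
            centers_mm=np.empty((0, 3)),
            radii_um=np.empty(0),
            target_concentration=0.0,
            seed=0,
        )
        for _ in range(40):
            r = rng.uniform(2.0, 12.0)
            b = rng.uniform(0.0, 0.9 * r)
            phi = rng.uniform(0, 2 * np.pi)
            cy, cz = rng.uniform(-1.0, 1.0), rng.uniform(-1.0, 1.0)
            x = 0.25 + b * np.sin(phi) / 1e3
            y = cy + b * np.cos(phi) / 1e3
            ph = single_sphere_phantom(geometry, [0.25, cy, cz], r)
            traced = bt.trace_ray(Ray(x_mm=x, y_mm=y), ph, materials)
            baseline = bt.trace_ray(Ray(x_mm=x, y_mm=y), empty, materials)
            got_y = traced.deflection_urad - baseline.deflection_urad
            full = bt.sphere_deflection_closed_form(dd, r, b)
            # the tracer records the diffraction-plane (y) component
            expected_y = -full * np.cos(phi)
            assert got_y == pytest.approx(expected_y, rel=0.01, abs=1e-6)

    def test_gas_chord_reduces_attenuation(self, geometry, materials):
        ph = single_sphere_phantom(geometry, [0.25, 0.0, 0.0], 10.0)
        with_bubble = bt.trace_ray(Ray(x_mm=0.25, y_mm=0.0), ph, materials)
        empty = bt.Phantom(
            geometry=geometry,
            centers_mm=np.empty((0, 3)),
            radii_um=np.empty(0),
            target_concentration=0.0,
            seed=0,
        )
        without = bt.trace_ray(Ray(x_mm=0.25, y_mm=0.0), empty, materials)
        # a gas chord replaces water: 20 um less water along the path
        ratio = with_bubble.weight / without.weight
        assert ratio == pytest.approx(np.exp(materials["water"].mu * 0.020), rel=1e-9)


class TestRenderFrame:
    def test_empty_beam_uniform_at_working_point(
        self, grid, rocking_curve, working_point
    ):
        frame = bt.render_frame(None, grid, rocking_curve, working_point)
        assert np.allclose(frame.intensity, 0.05, atol=1e-12)

    def test_deterministic_with_noise(
        self, bubble_frame, geometry, size_dist, grid, rocking_curve, working_point
    ):
        ph = bt.generate_phantom(geometry, size_dist, 0.005, seed=1)
        again = bt.render_frame(
            ph, grid, rocking_curve, working_point, photon_budget=1e5, seed=3
        )
        assert np.array_equal(again.intensity, bubble_frame.intensity)

    def test_energy_bookkeeping(self, geometry, size_dist, grid):
        # constant-reflectivity analyser and zero absorption: refraction
        # redistributes angle, not weight, so every pixel is exactly the
        # incident flux
        ph = bt.generate_phantom(geometry, size_dist, 0.003, seed=5)
        flat_curve = bt.RockingCurve(fwhm_urad=1e12)
        wp = bt.WorkingPoint(offset_urad=0.0, reflectivity_level=0.5)
        mats = {
            name: bt.Material(name=m.name, delta=m.delta, mu=0.0)
            for name, m in bt.default_materials().items()
        }
        frame = bt.render_frame(ph, grid, flat_curve, wp, materials=mats, seed=0)
        assert np.all(frame.intensity == 1.0)

    def test_bubbles_brighten_lumen(
        self, bubble_frame, background_stats, roi
    ):
        bg_mean, _, _ = background_stats
        assert bubble_frame.intensity[roi.slice()].mean() > bg_mean

    def test_intensities_nonnegative(self, bubble_frame):
        assert np.all(bubble_frame.intensity >= 0)

    def test_poisson_noise_variance(self, rocking_curve):
        # flat field: pixel variance should equal mean / photon budget
        grid = bt.DetectorGrid(fov_x_mm=3.6, fov_y_mm=4.6, rays_per_pixel=1)
        wp = bt.find_working_point(rocking_curve, 0.05)
        budget = 1e4
        frame = bt.render_frame(
            None, grid, rocking_curve, wp, photon_budget=budget, seed=8
        )
        assert frame.intensity.size >= 10_000
        var = frame.intensity.var()
        mean = frame.intensity.mean()
        assert var == pytest.approx(mean / budget, rel=0.05)


class TestRenderSequence:
    def test_single_frame_at_first_mid_exposure(
        self, geometry, size_dist, grid, rocking_curve, working_point
    ):
        dil = bt.DilutionModel(c1=0.002, decay_rate=0.1)
        seq = bt.render_sequence(
            geometry, size_dist, dil, bt.AcquisitionTiming(), 1,
            grid, rocking_curve, working_point, seed=0,
        )
        assert len(seq.frames) == 1
        assert seq.frames[0].timestamp_s == pytest.approx(0.25)
        expected_c = 0.002 * np.exp(-0.1 * 0.25)
        assert seq.frames[0].concentration == pytest.approx(expected_c, rel=0.02)

    def test_constant_concentration_statistically_identical(
        self, geometry, size_dist, grid, rocking_curve, working_point, roi
    ):
        dil = bt.DilutionModel(c1=0.004, decay_rate=0.0)
        seq = bt.render_sequence(
            geometry, size_dist, dil, bt.AcquisitionTiming(), 4,
            grid, rocking_curve, working_point, seed=21,
        )
        means = bt.roi_mean_series(seq, roi).means
        # fresh phantoms per frame: same mean up to Monte Carlo scatter
        assert means.std() / means.mean() < 0.02

    def test_decaying_run_decreases(self, decay_sequence, roi):
        series = bt.roi_mean_series(decay_sequence, roi)
        smooth = np.convolve(series.means, np.ones(5) / 5, mode="valid")
        assert smooth[0] > smooth[-1]
        assert np.mean(series.means[:5]) > np.mean(series.means[-5:])

    def test_zero_frames_rejected(
        self, geometry, size_dist, grid, rocking_curve, working_point
    ):
        dil = bt.DilutionModel(c1=0.002, decay_rate=0.1)
        with pytest.raises(ValueError):
            bt.render_sequence(
                geometry, size_dist, dil, bt.AcquisitionTiming(), 0,
                grid, rocking_curve, working_point, seed=0,
            )


class TestSequenceIO:
    def test_tiff_and_sidecar_round_trip(self, decay_sequence, tmp_path):
        tif = tmp_path / "seq.tif"
        csv = tmp_path / "seq.csv"
        decay_sequence.save(tif, csv)
        back = bt.ImageSequence.load(tif, csv)
        assert len(back.frames) == len(decay_sequence.frames)
        assert np.allclose(back.times_s, decay_sequence.times_s)
        assert np.allclose(
            back.concentrations, decay_sequence.concentrations, rtol=1e-6
        )
        # float32 storage round trip
        assert np.allclose(
            back.stack(), decay_sequence.stack().astype(np.float32), rtol=1e-6
        )
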