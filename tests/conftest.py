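"""Shared fixtures: one reduced-scale imaging setup reused across tests.

The session-scoped fixtures render at a 0.5 mm axial field of view and
32 rays per pixel so expensive frames are computed once; the physics is
identical to the full-scale default configuration.
"""

import numpy as np
import pytest

import bubbletrace as bt

PHOTON_BUDGET = 1.0e5


@pytest.fixture(scope="session")
def rocking_curve():
    return bt.RockingCurve(fwhm_urad=20.0)


@pytest.fixture(scope="session")
def working_point(rocking_curve):
    return bt.find_working_point(rocking_curve, 0.05)


@pytest.fixture(scope="session")
def geometry():
    return bt.VesselGeometry(inner_diameter_mm=4.0, wall_thickness_mm=1.0, length_mm=0.5)


@pytest.fixture(scope="session")
def size_dist():
    return bt.SizeDistribution()


@pytest.fixture(scope="session")
def grid():
    return bt.DetectorGrid(fov_x_mm=0.5, fov_y_mm=4.6, rays_per_pixel=32)


@pytest.fixture(scope="session")
def materials():
    return bt.default_materials(17.0)


@pytest.fixture(scope="session")
def roi(grid, geometry):
    return bt.central_lumen_roi(grid, geometry, lumen_fraction=0.5)


@pytest.fixture(scope="session")
def empty_phantom(geometry):
    return bt.Phantom(
        geometry=geometry,
        centers_mm=np.empty((0, 3)),
        radii_um=np.empty(0),
        target_concentration=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def background_stats(empty_phantom, grid, rocking_curve, working_point, roi):
    """(mean, sigma, per-replicate means) of the bubble-free ROI intensity."""
    reps = np.array(
        [
            bt.render_frame(
                empty_phantom,
                grid,
                rocking_curve,
                working_point,
                photon_budget=PHOTON_BUDGET,
                seed=900 + k,
            ).intensity[roi.slice()].mean()
            for k in range(5)
        ]
    )
    return float(reps.mean()), float(reps.std(ddof=1)), reps


@pytest.fixture(scope="session")
def bubble_frame(geometry, size_dist, grid, rocking_curve, working_point):
    """One noisy frame at volume concentration 0.005."""
    ph = bt.generate_phantom(geometry, size_dist, 0.005, seed=1)
    return bt.render_frame(
        ph, grid, rocking_curve, working_point, photon_budget=PHOTON_BUDGET, seed=3
    )


@pytest.fixture(scope="session")
def decay_sequence(geometry, size_dist, grid, rocking_curve, working_point):
    """A 40-frame dilution run with D = 0.056 1/s from C1 = 0.01."""
    dil = bt.DilutionModel(c1=0.01, decay_rate=0.056)
    return bt.render_sequence(
        geometry,
        size_dist,
        dil,
        bt.AcquisitionTiming(),
        40,
        grid,
        rocking_curve,
        working_point,
        photon_budget=PHOTON_BUDGET,
        seed=1000,
    )


@pytest.fixture(scope="session")
def calibration(geometry, size_dist, grid, rocking_curve, working_point):
    """Fitted six-level calibration benchmark with three replicates."""
    cal = bt.build_calibration(
        [0.0, 0.002, 0.004, 0.006, 0.008, 0.01],
        geometry,
        size_dist,
        grid,
        rocking_curve,
        working_point,
        photon_budget=PHOTON_BUDGET,
        n_replicates=3,
        seed=0,
    )
    bt.fit_linear(cal)
    return cal
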