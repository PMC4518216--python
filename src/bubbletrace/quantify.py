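"""Quantification pipeline: from dark-field frames to concentration and D.

The analysis mirrors a dilution-run experiment end to end:

1. average intensity over a rectangular ROI in the centre of the tube
   lumen for every frame of a sequence;
2. subtract the background (the same ROI imaged at zero bubble
   concentration) so zero intensity corresponds to zero concentration;
3. benchmark intensity against known simulated concentrations to build
   a calibration curve, fit a straight line through it and keep the
   residuals as a diagnostic of the mild nonlinearity;
4. invert the fit to estimate concentration from intensity, and fit
   the log of the subtracted intensity series against time to recover
   the dilution decay constant D with a bootstrap confidence interval;
5. convert the calibration noise level into a Rose-criterion detection
   limit, c_min = SNR_threshold * sigma / slope.

The ROI defaults to the central 50 % of the lumen width and always
excludes wall pixels, whose edge refraction carries no bubble signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .optics import RockingCurve, WorkingPoint
from .phantom import SizeDistribution, VesselGeometry, generate_phantom
from .simulate import DetectorGrid, ImageSequence, render_frame

__all__ = [
    "ROI",
    "IntensitySeries",
    "CalibrationCurve",
    "DecayEstimate",
    "central_lumen_roi",
    "roi_mean_series",
    "subtract_background",
    "build_calibration",
    "fit_linear",
    "estimate_concentration",
    "estimate_decay_constant",
    "detection_limit",
    "align_at_intensity",
    "plot_intensity_time",
    "plot_calibration",
]

ROSE_SNR = 5.0  # Rose criterion: SNR >= 5 to distinguish a detail


@dataclass(frozen=True)
class ROI:
    """Half-open pixel-index rectangle [row_start:row_stop, col_start:col_stop]."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_start >= self.row_stop or self.col_start >= self.col_stop:
            raise ValueError("ROI must be non-empty")
        if min(self.row_start, self.col_start) < 0:
            raise ValueError("ROI indices must be nonnegative")

    def validate_for(self, shape: tuple[int, int]) -> None:
        if self.row_stop > shape[0] or self.col_stop > shape[1]:
            raise ValueError(f"ROI {self} outside image of shape {shape}")

    def slice(self) -> tuple[slice, slice]:
        return (
            slice(self.row_start, self.row_stop),
            slice(self.col_start, self.col_stop),
        )


@dataclass(frozen=True)
class IntensitySeries:
    """Per-frame ROI mean intensities with timestamps."""

    times_s: np.ndarray
    means: np.ndarray
    stderrs: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.means):
            raise ValueError("times and means must have the same length")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class CalibrationCurve:
    """Simulated intensity-vs-concentration benchmark and its linear fit.

    ``sigma`` is the standard deviation of replicate zero-concentration
    ROI means — the noise level used for the Rose detection limit.
    """

    concentrations: np.ndarray
    mean_intensities: np.ndarray
    background: float
    sigma: float
    subtracted: np.ndarray = field(init=False)
    slope: float | None = None
    intercept: float | None = None
    intercept_stderr: float | None = None
    residuals: np.ndarray | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        order = np.argsort(self.concentrations)
        self.concentrations = np.asarray(self.concentrations, float)[order]
        self.mean_intensities = np.asarray(self.mean_intensities, float)[order]
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        self.subtracted = self.mean_intensities - self.background


@dataclass(frozen=True)
class DecayEstimate:
    """Recovered decay constant with a bootstrap confidence interval."""

    d_hat: float
    ci_low: float
    ci_high: float
    n_frames_used: int


def central_lumen_roi(
    grid: DetectorGrid,
    geometry: VesselGeometry,
    lumen_fraction: float = 0.5,
    col_margin: int = 0,
) -> ROI:
    """ROI covering the central ``lumen_fraction`` of the lumen width.

    Rows are selected by pixel-centre y-coordinate; wall pixels can
    never enter because the fraction is of the *inner* diameter.
    Columns span the full axial field of view minus ``col_margin``
    pixels per side.
    """
    if not 0.0 < lumen_fraction <= 1.0:
        raise ValueError("lumen_fraction must be in (0, 1]")
    half = lumen_fraction * geometry.inner_radius_mm
    y = grid.pixel_y_centers_mm()
    inside = np.flatnonzero(np.abs(y) <= half)
    if inside.size == 0:
        raise ValueError("no pixel rows inside the requested lumen fraction")
    ny, nx = grid.shape
    if col_margin * 2 >= nx:
        raise ValueError("col_margin leaves no columns")
    return ROI(int(inside[0]), int(inside[-1] + 1), col_margin, nx - col_margin)


def roi_mean_series(sequence: ImageSequence, roi: ROI) -> IntensitySeries:
    """Mean ROI intensity of every frame, timestamped from the sequence."""
    if not sequence.frames:
        raise ValueError("empty sequence")
    roi.validate_for(sequence.frames[0].intensity.shape)
    sl = roi.slice()
    means, errs = [], []
    for f in sequence.frames:
        patch = f.intensity[sl]
        means.append(float(patch.mean()))
        errs.append(float(patch.std(ddof=1) / np.sqrt(patch.size)))
    return IntensitySeries(
        times_s=sequence.times_s,
        means=np.array(means),
        stderrs=np.array(errs),
    )


def subtract_background(
    series: IntensitySeries, background: float
) -> IntensitySeries:
    """Shift a series by the zero-concentration background intensity."""
    return IntensitySeries(
        times_s=series.times_s,
        means=series.means - background,
        stderrs=series.stderrs,
        label=series.label,
    )


def build_calibration(
    concentrations,
    geometry: VesselGeometry,
    dist: SizeDistribution,
    grid: DetectorGrid,
    curve: RockingCurve,
    wp: WorkingPoint,
    photon_budget: float | None = None,
    n_replicates: int = 3,
    lumen_fraction: float = 0.5,
    seed: int = 0,
) -> CalibrationCurve:
    """Simulate the intensity-concentration benchmark.

    Renders ``n_replicates`` independent phantoms per concentration
    level (zero must be included: it defines the background and the
    noise level sigma) and records the ROI mean of each.
    """
    levels = np.asarray(sorted(set(float(c) for c in concentrations)))
    if levels.size < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    if 0.0 not in levels:
        raise ValueError("concentration 0 required to define the background")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates to estimate the noise level")
    roi = central_lumen_roi(grid, geometry, lumen_fraction)
    ss = np.random.SeedSequence(seed)
    means = np.empty(levels.size)
    zero_reps = None
    for i, c in enumerate(levels):
        reps = []
        for child in ss.spawn(n_replicates):
            pack_seed, render_seed = (int(s) for s in child.generate_state(2) >> 1)
            ph = generate_phantom(geometry, dist, float(c), seed=pack_seed)
            frame = render_frame(
                ph, grid, curve, wp, photon_budget=photon_budget, seed=render_seed
            )
            reps.append(float(frame.intensity[roi.slice()].mean()))
        means[i] = np.mean(reps)
        if c == 0.0:
            zero_reps = np.array(reps)
    return CalibrationCurve(
        concentrations=levels,
        mean_intensities=means,
        background=float(np.mean(zero_reps)),
        sigma=float(np.std(zero_reps, ddof=1)),
    )


def fit_linear(curve: CalibrationCurve):
    """Ordinary least squares of subtracted intensity on concentration.

    Stores slope, intercept, residuals and R^2 on the curve and returns
    ``(slope, intercept, residuals)``.  Residuals are kept signed; their
    structure is the diagnostic that the response is only approximately
    linear.
    """
    x, y = curve.concentrations, curve.subtracted
    if x.size < 3:
        raise ValueError("need at least 3 points for the linear fit")
    if np.unique(x).size < 2:
        raise ValueError("degenerate fit: all concentrations identical")
    res = stats.linregress(x, y)
    curve.slope = float(res.slope)
    curve.intercept = float(res.intercept)
    curve.intercept_stderr = float(res.intercept_stderr)
    curve.residuals = y - (res.slope * x + res.intercept)
    curve.r_squared = float(res.rvalue**2)
    return curve.slope, curve.intercept, curve.residuals


def estimate_concentration(intensity: float, curve: CalibrationCurve) -> float:
    """Invert the linear calibration: (I - intercept) / slope, clipped at 0.

    Warns when the requested intensity lies outside the calibrated
    range (extrapolation).
    """
    if curve.slope is None:
        raise ValueError("calibration curve has not been fitted; call fit_linear")
    lo, hi = float(curve.subtracted.min()), float(curve.subtracted.max())
    if not lo <= intensity <= hi:
        warnings.warn(
            f"intensity {intensity:.4g} outside calibrated range "
            f"[{lo:.4g}, {hi:.4g}]; extrapolating",
            stacklevel=2,
        )
    return max(0.0, (intensity - curve.intercept) / curve.slope)


def estimate_decay_constant(
    series: IntensitySeries,
    background: float,
    background_sigma: float = 0.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> DecayEstimate:
    """Recover the dilution decay constant from an ROI intensity series.

    The background is subtracted, frames below the noise floor
    (3 x ``background_sigma``, or any nonpositive value) are dropped —
    the log of near-background intensities is dominated by noise — and
    ``log(subtracted)`` is fitted against time by OLS; D is minus the
    slope.  The confidence interval is a seeded bootstrap over frames
    (percentile 2.5-97.5).
    """
    if len(series.means) < 8:
        raise ValueError("need at least 8 frames to estimate D")
    sub = series.means - background
    floor = 3.0 * background_sigma
    keep = sub > max(floor, 0.0)
    if keep.sum() == 0:
        raise ValueError("no signal above background")
    if keep.sum() < 3:
        raise ValueError("too few frames above the noise floor")
    t = series.times_s[keep]
    logy = np.log(sub[keep])
    if logy.max() - logy.min() < 1.0:
        warnings.warn(
            "series spans less than one e-folding above background; "
            "D estimate may be poorly constrained",
            stacklevel=2,
        )
    res = stats.linregress(t, logy)
    d_hat = -float(res.slope)

    rng = np.random.default_rng(seed)
    n = t.size
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.unique(t[idx]).size < 2:
            boots[i] = d_hat
            continue
        boots[i] = -stats.linregress(t[idx], logy[idx]).slope
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return DecayEstimate(
        d_hat=d_hat, ci_low=float(lo), ci_high=float(hi), n_frames_used=int(n)
    )


def detection_limit(curve: CalibrationCurve, snr_threshold: float = ROSE_SNR) -> float:
    """Smallest detectable concentration: snr_threshold * sigma / slope.

    Inverts the fitted calibration at the intensity where the
    subtracted signal first reaches ``snr_threshold`` times the
    zero-concentration noise level.
    """
    if curve.slope is None:
        raise ValueError("calibration curve has not been fitted; call fit_linear")
    if curve.slope == 0:
        raise ValueError("zero calibration slope: no sensitivity to concentration")
    return snr_threshold * curve.sigma / curve.slope


def align_at_intensity(
    series_list: list[IntensitySeries], level: float
) -> list[IntensitySeries]:
    """Shift each series so t=0 falls where its mean first crosses ``level``.

    Reproduces the display convention of overlaying dilution runs that
    started from slightly different initial concentrations: the origin
    is placed at a common intensity, found by linear interpolation
    between the bracketing frames.  Series never crossing the level are
    returned unshifted.
    """
    out = []
    for s in series_list:
        below = np.flatnonzero(s.means <= level)
        if below.size == 0 or below[0] == 0:
            out.append(s)
            continue
        k = below[0]
        t0, t1 = s.times_s[k - 1], s.times_s[k]
        y0, y1 = s.means[k - 1], s.means[k]
        t_cross = t0 + (level - y0) * (t1 - t0) / (y1 - y0)
        out.append(
            IntensitySeries(
                times_s=s.times_s - t_cross,
                means=s.means,
                stderrs=s.stderrs,
                label=s.label,
            )
        )
    return out


# --- presentation -------------------------------------------------------


def plot_intensity_time(series_list, path, background: float | None = None):
    """Overlay ROI intensity-vs-time curves for one or more dilution runs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in series_list:
        ax.plot(s.times_s, s.means, "o-", ms=3, label=s.label or None)
    if background is not None:
        ax.axhline(background, color="k", ls="--", lw=1, label="background")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ROI mean intensity (a.u.)")
    if any(s.label for s in series_list) or background is not None:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_calibration(curve: CalibrationCurve, path):
    """Calibration curve with linear fit and a residual panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    ax1.plot(curve.concentrations, curve.subtracted, "o", label="simulated")
    if curve.slope is not None:
        xs = np.linspace(0, curve.concentrations.max(), 50)
        ax1.plot(
            xs,
            curve.slope * xs + curve.intercept,
            "-",
            label=f"fit, $R^2$={curve.r_squared:.3f}",
        )
        ax2.plot(curve.concentrations, curve.residuals, "o")
    ax2.axhline(0.0, color="k", lw=1)
    ax1.set_ylabel("background-subtracted intensity (a.u.)")
    ax2.set_ylabel("residual (a.u.)")
    ax2.set_xlabel("microbubble volume concentration")
    ax1.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
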