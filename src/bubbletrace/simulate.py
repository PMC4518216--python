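"""Ray-optics Monte Carlo forward model of single-shot dark-field imaging.

A parallel, monochromatic beam (17 keV default) propagates along +z
through the vessel phantom.  Each ray accumulates

* attenuation ``exp(-sum_i mu_i * l_i)`` over its analytic chord
  lengths through the Nylon wall, the water lumen and any gas bubbles
  it crosses, and
* a refractive angular deviation at every interface.  For a sphere of
  index decrement contrast ``ddelta = delta_in - delta_out`` crossed at
  impact parameter ``b``, the entry+exit deflection has the closed form
  ``2*ddelta*b/sqrt(r^2 - b^2)``, directed radially (outward for
  positive contrast); a cylinder crossed perpendicular to its axis
  obeys the same expression in the transverse plane.  Gas bubbles have
  ``delta`` below water's, so each one acts as a weak converging x-ray
  lens deviating rays by ~1 microradian.

Only the deflection component in the diffraction plane (y) is kept:
a crystal analyser is a one-dimensional angular filter.  The detected
intensity per ray is ``weight * R(theta_wp - alpha_y)`` where ``R`` is
the rocking curve and ``theta_wp`` the tail working point; ultra-small-
angle scattering by many bubbles broadens the angular distribution and,
on the convex tail of the curve, *raises* the mean reflectivity — the
bright dark-field signal in the lumen.

Deflections never re-steer the intersection search: microradian
deviations over millimetres move a ray by far less than a pixel, so
straight-line chords are exact for bookkeeping purposes.  Attenuation
multiplies ray weights continuously (no stochastic absorption), so the
rays-per-pixel budget only controls refraction sampling noise.  Air
outside the tube is treated as vacuum (its mu of ~1e-4/mm is
negligible over the few-mm geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

from .flow import AcquisitionTiming, DilutionModel, concentration_at, frame_times
from .optics import Material, RockingCurve, WorkingPoint, optical_constants, reflectivity
from .phantom import Phantom, SizeDistribution, VesselGeometry, generate_phantom

__all__ = [
    "Ray",
    "DetectorGrid",
    "ImageFrame",
    "ImageSequence",
    "sphere_deflection_closed_form",
    "trace_ray",
    "render_frame",
    "render_sequence",
    "default_materials",
]

RAD_TO_URAD = 1e6
UM_PER_MM = 1e3

_SPHERE_CHUNK = 16384  # bound transient memory in the scatter-add gather


@dataclass
class Ray:
    """One ray of the parallel beam.

    ``x_mm, y_mm`` locate the ray on the entrance plane (it travels
    along +z), ``weight`` is the accumulated transmission in [0, 1] and
    ``deflection_urad`` the accumulated angular deviation in the
    diffraction plane (y), in microradian.
    """

    x_mm: float
    y_mm: float
    weight: float = 1.0
    deflection_urad: float = 0.0


@dataclass(frozen=True)
class DetectorGrid:
    """Binned detector geometry and the per-pixel ray budget.

    The raw sensor has 9 um pixels; 4x4 binning gives the 36 um
    effective pixels used for fast sequence acquisition.  The field of
    view is centred on the vessel axis in y and spans
    ``[0, fov_x_mm]`` along the vessel axis.  ``rays_per_pixel`` is
    rounded down to a square number (stratified jittered subgrid).
    """

    raw_pixel_um: float = 9.0
    binning: int = 4
    fov_x_mm: float = 0.5
    fov_y_mm: float = 4.6
    rays_per_pixel: int = 64

    def __post_init__(self) -> None:
        if self.raw_pixel_um <= 0 or self.binning < 1:
            raise ValueError("invalid pixel size or binning")
        if self.fov_x_mm <= 0 or self.fov_y_mm <= 0:
            raise ValueError("empty field of view")
        if self.rays_per_pixel < 1:
            raise ValueError("rays_per_pixel must be >= 1")

    @property
    def pixel_mm(self) -> float:
        """Effective (binned) pixel pitch in mm."""
        return self.raw_pixel_um * self.binning / UM_PER_MM

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the effective-pixel image."""
        ny = max(1, int(round(self.fov_y_mm / self.pixel_mm)))
        nx = max(1, int(round(self.fov_x_mm / self.pixel_mm)))
        return ny, nx

    @property
    def subgrid(self) -> int:
        """Subrays per pixel edge (rays_per_pixel rounded to a square)."""
        return max(1, int(np.sqrt(self.rays_per_pixel)))

    def pixel_y_centers_mm(self) -> np.ndarray:
        ny, _ = self.shape
        return (np.arange(ny) + 0.5) * self.pixel_mm - 0.5 * self.fov_y_mm


@dataclass(frozen=True)
class ImageFrame:
    """A single rendered frame (intensity per unit incident flux)."""

    intensity: np.ndarray
    timestamp_s: float = 0.0
    photon_budget: float | None = None
    concentration: float | None = None


@dataclass(frozen=True)
class ImageSequence:
    """Time-stamped frame stack plus per-frame ground truth."""

    frames: tuple[ImageFrame, ...]

    @property
    def times_s(self) -> np.ndarray:
        return np.array([f.timestamp_s for f in self.frames])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array(
            [np.nan if f.concentration is None else f.concentration for f in self.frames]
        )

    def stack(self) -> np.ndarray:
        return np.stack([f.intensity for f in self.frames])

    def save(self, tiff_path, sidecar_csv_path) -> None:
        """Write a 32-bit float multi-page TIFF plus a timing sidecar CSV."""
        tifffile.imwrite(
            str(tiff_path),
            self.stack().astype(np.float32),
            photometric="minisblack",
        )
        pd.DataFrame(
            {
                "frame": np.arange(len(self.frames)),
                "time_s": self.times_s,
                "concentration": self.concentrations,
            }
        ).to_csv(sidecar_csv_path, index=False)

    @classmethod
    def load(cls, tiff_path, sidecar_csv_path) -> "ImageSequence":
        stack = tifffile.imread(str(tiff_path))
        if stack.ndim == 2:
            stack = stack[None]
        meta = pd.read_csv(sidecar_csv_path)
        frames = tuple(
            ImageFrame(
                intensity=np.asarray(stack[k], dtype=float),
                timestamp_s=float(meta["time_s"].iloc[k]),
                concentration=(
                    None
                    if np.isnan(meta["concentration"].iloc[k])
                    else float(meta["concentration"].iloc[k])
                ),
            )
            for k in range(stack.shape[0])
        )
        return cls(frames=frames)


def default_materials(energy_kev: float = 17.0) -> dict[str, Material]:
    """Optical constants for the standard phantom materials."""
    return {
        name: optical_constants(name, energy_kev)
        for name in ("water", "nylon12", "gas_core")
    }


def sphere_deflection_closed_form(
    delta_contrast: float, radius_um: float, impact_parameter_um: float
) -> float:
    """Entry+exit refractive deflection of a ray crossing a sphere, in urad.

    ``2 * delta_contrast * b / sqrt(r^2 - b^2)``: the analytic two-surface
    result used as the independent oracle for the tracer.
    """
    b, r = impact_parameter_um, radius_um
    if not 0.0 <= b < r:
        raise ValueError("impact parameter must satisfy 0 <= b < radius")
    return 2.0 * delta_contrast * b / np.sqrt(r * r - b * b) * RAD_TO_URAD


def _cylinder_chord(radius_mm: float, y: np.ndarray) -> np.ndarray:
    """Chord length along z through a cylinder of given radius at height y."""
    h2 = radius_mm * radius_mm - y * y
    return 2.0 * np.sqrt(np.maximum(h2, 0.0))


def _cylinder_deflection_rad(
    delta_contrast: float, radius_mm: float, y: np.ndarray
) -> np.ndarray:
    """y-deflection (radians) from crossing a full cylinder at height y.

    Same two-surface closed form as the sphere, applied in the y-z
    plane; zero outside the cylinder.  Signed: positive contrast pushes
    rays away from the axis.
    """
    inside = np.abs(y) < radius_mm
    out = np.zeros_like(y)
    h = np.sqrt(np.maximum(radius_mm * radius_mm - y * y, 1e-30))
    out[inside] = 2.0 * delta_contrast * y[inside] / h[inside]
    return out


def _wall_and_lumen(
    x: np.ndarray,
    y: np.ndarray,
    geometry: VesselGeometry,
    materials: dict[str, Material],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wall chord, lumen chord and wall refraction for rays at (x, y).

    The hollow cylinder is decomposed into a full Nylon cylinder of the
    outer radius superposed with a water cylinder of the inner radius
    that replaces Nylon in the lumen; chords and deflections add
    linearly in the small-angle, straight-chord limit.
    """
    nylon, water = materials["nylon12"], materials["water"]
    in_segment = (x >= 0.0) & (x <= geometry.length_mm)
    outer = _cylinder_chord(geometry.outer_radius_mm, y) * in_segment
    inner = _cylinder_chord(geometry.inner_radius_mm, y) * in_segment
    wall = outer - inner
    defl = (
        _cylinder_deflection_rad(nylon.delta, geometry.outer_radius_mm, y)
        + _cylinder_deflection_rad(
            water.delta - nylon.delta, geometry.inner_radius_mm, y
        )
    ) * in_segment
    return wall, inner, defl


def trace_ray(
    ray: Ray, phantom: Phantom, materials: dict[str, Material] | None = None
) -> Ray:
    """Trace one ray through the phantom; returns the updated ray.

    A ray that misses the vessel entirely comes back unchanged.  Bubble
    crossings are found by comparing the transverse distance of the ray
    to each sphere center against the sphere radius (straight-line
    geometry); the weight picks up ``exp(-sum mu*l)`` and the
    deflection the signed y-component of each interface pair's closed
    form.
    """
    if materials is None:
        materials = default_materials()
    water, gas = materials["water"], materials["gas_core"]

    x = np.array([ray.x_mm])
    y = np.array([ray.y_mm])
    wall, lumen, defl_rad = _wall_and_lumen(x, y, phantom.geometry, materials)
    wall, lumen, defl_rad = wall[0], lumen[0], defl_rad[0]

    gas_chord = 0.0
    if phantom.n_spheres:
        c = phantom.centers_mm
        r = phantom.radii_um / UM_PER_MM
        dx = ray.x_mm - c[:, 0]
        dy = ray.y_mm - c[:, 1]
        b2 = dx * dx + dy * dy
        hit = b2 < r * r
        if np.any(hit):
            half = np.sqrt(r[hit] ** 2 - b2[hit])
            gas_chord = float(np.sum(2.0 * half))
            defl_rad += float(
                np.sum(2.0 * (gas.delta - water.delta) * dy[hit] / half)
            )

    weight = ray.weight * np.exp(
        -(
            materials["nylon12"].mu * wall
            + water.mu * max(lumen - gas_chord, 0.0)
            + gas.mu * gas_chord
        )
    )
    return replace(
        ray,
        weight=float(weight),
        deflection_urad=ray.deflection_urad + float(defl_rad) * RAD_TO_URAD,
    )


def _accumulate_spheres(
    phantom: Phantom,
    materials: dict[str, Material],
    xs: np.ndarray,
    ys: np.ndarray,
    sub_pitch_mm: float,
    x0_mm: float,
    y0_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter bubble chords/deflections onto the subray grid.

    Sphere-centric: each sphere only touches subrays whose stratified
    cells intersect its transverse footprint, so candidates are found
    by integer arithmetic on the subray grid and accumulated with
    ``np.add.at``.  Returns (gas_chord_mm, deflection_rad) arrays of
    the subray grid shape.
    """
    gas_chord = np.zeros_like(xs)
    defl = np.zeros_like(xs)
    if not phantom.n_spheres:
        return gas_chord, defl

    n_rows, n_cols = xs.shape
    ddelta = materials["gas_core"].delta - materials["water"].delta
    r_all = phantom.radii_um / UM_PER_MM
    k_span = int(np.ceil(2.0 * r_all.max() / sub_pitch_mm)) + 2

    flat_chord = gas_chord.ravel()
    flat_defl = defl.ravel()
    for lo in range(0, phantom.n_spheres, _SPHERE_CHUNK):
        c = phantom.centers_mm[lo : lo + _SPHERE_CHUNK]
        r = r_all[lo : lo + _SPHERE_CHUNK]
        base_col = np.floor((c[:, 0] - r - x0_mm) / sub_pitch_mm).astype(np.int64)
        base_row = np.floor((c[:, 1] - r - y0_mm) / sub_pitch_mm).astype(np.int64)
        offs = np.arange(k_span, dtype=np.int64)
        cols = base_col[:, None, None] + offs[None, None, :]
        rows = base_row[:, None, None] + offs[None, :, None]
        valid = (rows >= 0) & (rows < n_rows) & (cols >= 0) & (cols < n_cols)
        rows_c = np.clip(rows, 0, n_rows - 1)
        cols_c = np.clip(cols, 0, n_cols - 1)
        dx = xs[rows_c, cols_c] - c[:, None, None, 0]
        dy = ys[rows_c, cols_c] - c[:, None, None, 1]
        b2 = dx * dx + dy * dy
        r2 = (r**2)[:, None, None]
        hit = valid & (b2 < r2)
        if not np.any(hit):
            continue
        half = np.sqrt(r2 - b2, where=hit, out=np.zeros_like(b2))
        idx = (rows_c * n_cols + cols_c)[hit]
        np.add.at(flat_chord, idx, 2.0 * half[hit])
        np.add.at(flat_defl, idx, 2.0 * ddelta * dy[hit] / half[hit])
    return flat_chord.reshape(xs.shape), flat_defl.reshape(xs.shape)


def render_frame(
    phantom: Phantom | None,
    grid: DetectorGrid,
    curve: RockingCurve,
    wp: WorkingPoint,
    materials: dict[str, Material] | None = None,
    photon_budget: float | None = None,
    seed: int = 0,
    timestamp_s: float = 0.0,
) -> ImageFrame:
    """Render one dark-field frame of the phantom.

    Each effective pixel launches a stratified, jittered subgrid of
    rays; the pixel value is the mean over rays of
    ``weight * R(theta_wp - alpha_y)``, normalised to unit incident
    flux.  ``phantom=None`` renders the empty beam (every pixel at the
    working-point reflectivity).  With ``photon_budget`` set, Poisson
    noise is applied per pixel at that many incident photons per pixel.
    Deterministic for fixed seed.
    """
    if materials is None:
        materials = default_materials()
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape
    ns = grid.subgrid
    sub = grid.pixel_mm / ns
    n_rows, n_cols = ny * ns, nx * ns
    x0, y0 = 0.0, -0.5 * grid.fov_y_mm

    # stratified jitter: subray (i, j) stays inside its own subcell
    jit_y = rng.uniform(0.0, 1.0, (n_rows, n_cols))
    jit_x = rng.uniform(0.0, 1.0, (n_rows, n_cols))
    ys = y0 + (np.arange(n_rows)[:, None] + jit_y) * sub
    xs = x0 + (np.arange(n_cols)[None, :] + jit_x) * sub

    if phantom is None:
        intensity = np.full((ny, nx), float(reflectivity(curve, wp.offset_urad)))
    else:
        wall, lumen, defl_rad = _wall_and_lumen(xs, ys, phantom.geometry, materials)
        gas_chord, defl_sph = _accumulate_spheres(
            phantom, materials, xs, ys, sub, x0, y0
        )
        defl_rad = defl_rad + defl_sph
        weight = np.exp(
            -(
                materials["nylon12"].mu * wall
                + materials["water"].mu * np.maximum(lumen - gas_chord, 0.0)
                + materials["gas_core"].mu * gas_chord
            )
        )
        signal = weight * reflectivity(
            curve, wp.offset_urad - defl_rad * RAD_TO_URAD
        )
        intensity = signal.reshape(ny, ns, nx, ns).mean(axis=(1, 3))

    if photon_budget is not None:
        if photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        intensity = rng.poisson(intensity * photon_budget) / photon_budget

    return ImageFrame(
        intensity=intensity,
        timestamp_s=timestamp_s,
        photon_budget=photon_budget,
        concentration=None if phantom is None else phantom.realized_concentration,
    )


def render_sequence(
    geometry: VesselGeometry,
    dist: SizeDistribution,
    dilution: DilutionModel,
    timing: AcquisitionTiming,
    n_frames: int,
    grid: DetectorGrid,
    curve: RockingCurve,
    wp: WorkingPoint,
    materials: dict[str, Material] | None = None,
    photon_budget: float | None = None,
    seed: int = 0,
) -> ImageSequence:
    """Render a dilution run: one fresh phantom per frame at C(t_mid).

    Flow replaces the bubble population between frames, so frame ``k``
    draws an independent sphere pack at the mid-exposure concentration
    ``C(t_k)``.  Intra-exposure motion blur is not modelled.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    times = frame_times(timing, n_frames)
    children = np.random.SeedSequence(seed).spawn(n_frames)
    frames = []
    for k, (t, child) in enumerate(zip(times, children)):
        pack_seed, render_seed = (int(s) for s in child.generate_state(2) >> 1)
        conc = float(concentration_at(dilution, float(t)))
        ph = generate_phantom(geometry, dist, conc, seed=pack_seed)
        frames.append(
            render_frame(
                ph,
                grid,
                curve,
                wp,
                materials=materials,
                photon_budget=photon_budget,
                seed=render_seed,
                timestamp_s=float(t),
            )
        )
    return ImageSequence(frames=tuple(frames))
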