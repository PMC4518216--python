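"""Numerical vessel phantoms: polydisperse microbubble packs in a tube.

A phantom is a hollow Nylon-12 cylinder (the imaged vessel section,
4 mm internal diameter by default) whose water-filled lumen contains a
random, non-overlapping arrangement of gas microspheres at a target gas
volume fraction ("volume concentration").  Bubble radii follow a
truncated lognormal with a configurable median (4 um default, matching
polymer-shelled contrast agents) and geometric standard deviation.

Coordinate convention, used package-wide: the beam propagates along +z,
the vessel axis lies along x (perpendicular to the beam), and the
analyser's diffraction plane is y-z, so only angular deviations in y
are sensed.  Lengths are mm internally; bubble radii are um at the API
surface.

Packing is plain rejection sampling — centers uniform in the lumen,
candidates rejected on wall protrusion or overlap — which terminates
comfortably at the dilute volume fractions of interest (<= a few
percent).  Internally candidates are screened in vectorised batches
with a KD-tree, reproducing exactly the accept/reject decisions of a
one-at-a-time scan in candidate order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SizeDistribution",
    "VesselGeometry",
    "Phantom",
    "sample_radii",
    "generate_phantom",
    "lumen_volume",
]

MAX_PACKING_FRACTION = 0.05  # rejection packing is only guaranteed dilute

UM_PER_MM = 1e3


@dataclass(frozen=True)
class SizeDistribution:
    """Truncated lognormal bubble-radius distribution.

    Attributes
    ----------
    median_radius_um : float
        Median radius in um (4 um, typical of polymer-shelled agents).
    geometric_sd : float
        Geometric standard deviation (> 1; 1 means monodisperse).
    min_radius_um, max_radius_um : float
        Hard truncation bounds in um.
    """

    family: str = "lognormal"
    median_radius_um: float = 4.0
    geometric_sd: float = 1.7
    min_radius_um: float = 1.0
    max_radius_um: float = 12.0

    def __post_init__(self) -> None:
        if self.family != "lognormal":
            raise ValueError(f"unsupported size-distribution family {self.family!r}")
        if self.median_radius_um <= 0:
            raise ValueError("median_radius_um must be positive")
        if self.geometric_sd < 1.0:
            raise ValueError("geometric_sd must be >= 1")
        if self.min_radius_um >= self.max_radius_um:
            raise ValueError("truncation bounds require min_radius < max_radius")
        if self.min_radius_um <= 0:
            raise ValueError("min_radius_um must be positive")


@dataclass(frozen=True)
class VesselGeometry:
    """Cylindrical vessel segment: water lumen inside a Nylon-12 wall.

    The segment spans ``x in [0, length_mm]`` along the vessel axis.
    """

    inner_diameter_mm: float = 4.0
    wall_thickness_mm: float = 1.0
    length_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.inner_diameter_mm <= 0:
            raise ValueError("inner_diameter_mm must be positive")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall_thickness_mm must be positive")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")

    @property
    def inner_radius_mm(self) -> float:
        return 0.5 * self.inner_diameter_mm

    @property
    def outer_radius_mm(self) -> float:
        return self.inner_radius_mm + self.wall_thickness_mm


@dataclass(frozen=True)
class Phantom:
    """A realised sphere pack inside a vessel geometry.

    ``centers_mm`` is an (n, 3) array of (x, y, z) bubble centers and
    ``radii_um`` the matching radii.  ``realized_concentration`` is the
    summed gas volume over the lumen volume.
    """

    geometry: VesselGeometry
    centers_mm: np.ndarray
    radii_um: np.ndarray
    target_concentration: float
    seed: int
    distribution: SizeDistribution = field(default_factory=SizeDistribution)

    @property
    def n_spheres(self) -> int:
        return int(self.radii_um.size)

    @property
    def gas_volume_mm3(self) -> float:
        r_mm = self.radii_um / UM_PER_MM
        return float((4.0 / 3.0) * np.pi * np.sum(r_mm**3))

    @property
    def realized_concentration(self) -> float:
        return self.gas_volume_mm3 / lumen_volume(self.geometry)

    # --- plain-text round trip (regression fixtures) -------------------

    def to_csv(self) -> str:
        """Serialise to CSV with a ``#``-prefixed header block."""
        g, d = self.geometry, self.distribution
        header = [
            f"# inner_diameter_mm: {g.inner_diameter_mm!r}",
            f"# wall_thickness_mm: {g.wall_thickness_mm!r}",
            f"# length_mm: {g.length_mm!r}",
            f"# target_concentration: {self.target_concentration!r}",
            f"# seed: {self.seed}",
            f"# median_radius_um: {d.median_radius_um!r}",
            f"# geometric_sd: {d.geometric_sd!r}",
            f"# min_radius_um: {d.min_radius_um!r}",
            f"# max_radius_um: {d.max_radius_um!r}",
        ]
        body = pd.DataFrame(
            {
                "x_mm": self.centers_mm[:, 0],
                "y_mm": self.centers_mm[:, 1],
                "z_mm": self.centers_mm[:, 2],
                "radius_um": self.radii_um,
            }
        ).to_csv(index=False, float_format="%.9g")
        return "\n".join(header) + "\n" + body

    @classmethod
    def from_csv(cls, text: str) -> "Phantom":
        meta: dict[str, float] = {}
        lines = text.splitlines()
        n_head = 0
        for line in lines:
            if not line.startswith("#"):
                break
            n_head += 1
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = float(value)
        df = pd.read_csv(io.StringIO("\n".join(lines[n_head:])))
        return cls(
            geometry=VesselGeometry(
                inner_diameter_mm=meta["inner_diameter_mm"],
                wall_thickness_mm=meta["wall_thickness_mm"],
                length_mm=meta["length_mm"],
            ),
            centers_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            radii_um=df["radius_um"].to_numpy(float),
            target_concentration=meta["target_concentration"],
            seed=int(meta["seed"]),
            distribution=SizeDistribution(
                median_radius_um=meta["median_radius_um"],
                geometric_sd=meta["geometric_sd"],
                min_radius_um=meta["min_radius_um"],
                max_radius_um=meta["max_radius_um"],
            ),
        )


def lumen_volume(geometry: VesselGeometry) -> float:
    """Volume of the water lumen in mm^3: pi * r_in^2 * length."""
    return float(np.pi * geometry.inner_radius_mm**2 * geometry.length_mm)


def sample_radii(
    dist: SizeDistribution, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` bubble radii (um) from the truncated lognormal.

    Deterministic for a fixed integer seed.  Truncation is by rejection;
    in the degenerate ``geometric_sd -> 1`` limit every radius equals
    the median.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if n == 0:
        return np.empty(0, dtype=float)
    log_sigma = np.log(dist.geometric_sd)
    if log_sigma == 0.0:
        return np.full(n, dist.median_radius_um, dtype=float)
    out = np.empty(0, dtype=float)
    mu = np.log(dist.median_radius_um)
    while out.size < n:
        draw = rng.lognormal(mean=mu, sigma=log_sigma, size=2 * (n - out.size) + 16)
        keep = draw[(draw >= dist.min_radius_um) & (draw <= dist.max_radius_um)]
        out = np.concatenate([out, keep])
    return out[:n]


def _screen_batch(
    centers: np.ndarray,
    radii_mm: np.ndarray,
    acc_centers: np.ndarray,
    acc_radii_mm: np.ndarray,
) -> np.ndarray:
    """Sequential-rejection accept mask for one candidate batch.

    A candidate is rejected if it overlaps any previously accepted
    sphere or any *earlier accepted* candidate of the same batch —
    identical to scanning candidates one at a time.
    """
    n = len(radii_mm)
    accept = np.ones(n, dtype=bool)
    r_max_cand = radii_mm.max() if n else 0.0

    if len(acc_radii_mm):
        acc_tree = cKDTree(acc_centers)
        cand_tree = cKDTree(centers)
        pairs = cand_tree.sparse_distance_matrix(
            acc_tree, max_distance=r_max_cand + acc_radii_mm.max(), output_type="coo_matrix"
        )
        bad = pairs.data < radii_mm[pairs.row] + acc_radii_mm[pairs.col]
        accept[np.unique(pairs.row[bad])] = False

    cand_tree = cKDTree(centers)
    raw_pairs = cand_tree.query_pairs(2.0 * r_max_cand, output_type="ndarray")
    if raw_pairs.size:
        i, j = raw_pairs[:, 0], raw_pairs[:, 1]
        d = np.linalg.norm(centers[i] - centers[j], axis=1)
        touch = d < radii_mm[i] + radii_mm[j]
        i, j = i[touch], j[touch]
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        order = np.argsort(hi, kind="stable")
        for a, b in zip(lo[order], hi[order]):
            if accept[b] and accept[a]:
                accept[b] = False
    return accept


def generate_phantom(
    geometry: VesselGeometry,
    dist: SizeDistribution,
    concentration: float,
    seed: int,
) -> Phantom:
    """Pack non-overlapping gas spheres to a target volume concentration.

    Candidates are drawn uniformly in the lumen cylinder (uniform axial
    position, uniform over the cross-section disk) and rejected if they
    protrude into the wall or overlap an earlier sphere; accepted
    spheres accumulate until the gas volume fraction first reaches the
    target.  Deterministic for fixed seed and parameters.
    """
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    if concentration > MAX_PACKING_FRACTION:
        raise ValueError(
            f"concentration {concentration} above supported dilute packing "
            f"limit {MAX_PACKING_FRACTION}"
        )
    rng = np.random.default_rng(seed)
    r_in = geometry.inner_radius_mm
    target_vol = concentration * lumen_volume(geometry)

    acc_centers: list[np.ndarray] = []
    acc_radii: list[np.ndarray] = []
    realized_vol = 0.0

    # over-estimate of the mean bubble volume for batch sizing only
    mv = (
        (4.0 / 3.0)
        * np.pi
        * (dist.median_radius_um / UM_PER_MM) ** 3
        * np.exp(4.5 * np.log(dist.geometric_sd) ** 2)
    )

    while realized_vol < target_vol:
        n_batch = int(np.ceil((target_vol - realized_vol) / mv * 1.05)) + 64
        radii_um = sample_radii(dist, n_batch, rng)
        radii_mm = radii_um / UM_PER_MM
        x = rng.uniform(0.0, geometry.length_mm, n_batch)
        rho = r_in * np.sqrt(rng.uniform(0.0, 1.0, n_batch))
        phi = rng.uniform(0.0, 2.0 * np.pi, n_batch)
        centers = np.column_stack([x, rho * np.cos(phi), rho * np.sin(phi)])

        inside = rho <= r_in - radii_mm  # wall-protrusion rejection
        centers, radii_um, radii_mm = centers[inside], radii_um[inside], radii_mm[inside]
        if not len(radii_mm):
            continue

        prev_c = (
            np.concatenate(acc_centers) if acc_centers else np.empty((0, 3))
        )
        prev_r = (
            np.concatenate(acc_radii) if acc_radii else np.empty(0)
        ) / UM_PER_MM
        accept = _screen_batch(centers, radii_mm, prev_c, prev_r)
        centers, radii_um, radii_mm = centers[accept], radii_um[accept], radii_mm[accept]

        # accept in candidate order until the target volume is first reached
        vols = (4.0 / 3.0) * np.pi * radii_mm**3
        cum = realized_vol + np.cumsum(vols)
        n_take = int(np.searchsorted(cum, target_vol, side="left") + 1)
        n_take = min(n_take, len(vols))
        if n_take:
            acc_centers.append(centers[:n_take])
            acc_radii.append(radii_um[:n_take])
            realized_vol = float(cum[n_take - 1])

    return Phantom(
        geometry=geometry,
        centers_mm=np.concatenate(acc_centers) if acc_centers else np.empty((0, 3)),
        radii_um=np.concatenate(acc_radii) if acc_radii else np.empty(0),
        target_concentration=concentration,
        seed=seed,
        distribution=dist,
    )
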