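"""X-ray optical constants and the analyser-crystal rocking curve.

The refractive index of a material for hard x-rays is written
``n = 1 - delta + i*beta``: ``delta`` (the refractive-index decrement,
~1e-7 at 17 keV for water) drives refraction at interfaces, while the
imaginary part enters here as the linear attenuation coefficient
``mu`` (1/mm).  Constants for the phantom materials ship as a small
bundled table (``data/materials.csv``) computed from the classical
electron-density formula delta = r_e * lambda^2 * n_e / (2*pi) and
standard mass-attenuation tabulations; values are interpolated
log-linearly in energy between the tabulated points.

The analyser crystal converts microradian angular deviations into
intensity through its rocking curve — reflectivity as a function of
angular deviation from the Bragg peak.  The measured curve of a real
double-crystal setup is replaced by a parametric family (Gaussian by
default, pseudo-Voigt optionally).  Single-shot dark-field imaging
parks the analyser on the curve's tail, by default where reflectivity
has fallen to 5 % of its peak.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Material",
    "RockingCurve",
    "WorkingPoint",
    "SUPPORTED_MATERIALS",
    "optical_constants",
    "reflectivity",
    "find_working_point",
]

_GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Material:
    """Optical constants of one phantom material at one energy.

    Attributes
    ----------
    name : str
        Material label (e.g. ``"water"``).
    delta : float
        Refractive-index decrement (dimensionless).
    mu : float
        Linear attenuation coefficient in 1/mm.
    """

    name: str
    delta: float
    mu: float

    def __post_init__(self) -> None:
        if self.delta < 0 or self.mu < 0:
            raise ValueError(f"negative optical constants for {self.name!r}")


@dataclass(frozen=True)
class RockingCurve:
    """Parametric analyser reflectivity profile.

    Parameters
    ----------
    shape : {"gaussian", "pseudo_voigt"}
        Profile family.  The pseudo-Voigt mixes a Gaussian and a
        Lorentzian of equal FWHM with weight ``eta`` on the Lorentzian.
    fwhm_urad : float
        Full width at half maximum in microradian.
    peak_reflectivity : float
        Reflectivity at zero angular deviation, in (0, 1].
    eta : float
        Lorentzian fraction for the pseudo-Voigt shape (ignored for
        the Gaussian).
    """

    shape: str = "gaussian"
    fwhm_urad: float = 20.0
    peak_reflectivity: float = 1.0
    eta: float = 0.3

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "pseudo_voigt"):
            raise ValueError(f"unknown rocking-curve shape {self.shape!r}")
        if self.fwhm_urad <= 0:
            raise ValueError("fwhm_urad must be positive")
        if not 0.0 < self.peak_reflectivity <= 1.0:
            raise ValueError("peak_reflectivity must be in (0, 1]")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")

    @property
    def sigma_urad(self) -> float:
        """Gaussian standard deviation equivalent of the FWHM."""
        return self.fwhm_urad * _GAUSS_FWHM_TO_SIGMA


@dataclass(frozen=True)
class WorkingPoint:
    """Angular offset on the rocking-curve tail used for dark-field imaging.

    ``offset_urad`` is the signed angular deviation from the peak at
    which the analyser is parked; reflectivity there equals
    ``reflectivity_level * peak_reflectivity``.
    """

    offset_urad: float
    reflectivity_level: float = 0.05
    side: str = "positive"

    def __post_init__(self) -> None:
        if not 0.0 < self.reflectivity_level < 1.0:
            raise ValueError("reflectivity_level must be in (0, 1)")
        if self.side not in ("positive", "negative"):
            raise ValueError("side must be 'positive' or 'negative'")


def _load_table() -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Parse the bundled materials CSV into per-material energy grids."""
    path = importlib.resources.files("bubbletrace.data") / "materials.csv"
    raw = np.genfromtxt(
        str(path), delimiter=",", names=True, dtype=None, encoding="utf-8"
    )
    table: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for name in np.unique(raw["material"]):
        rows = raw[raw["material"] == name]
        order = np.argsort(rows["energy_kev"])
        table[str(name)] = (
            rows["energy_kev"][order].astype(float),
            rows["delta"][order].astype(float),
            rows["mu_per_mm"][order].astype(float),
        )
    return table


_TABLE = _load_table()
SUPPORTED_MATERIALS = tuple(sorted(_TABLE))


def _loglog_interp(x: float, xs: np.ndarray, ys: np.ndarray) -> float:
    """Log-log linear interpolation; exact for power laws like delta ~ E^-2."""
    if np.all(ys == 0.0):
        return 0.0
    return float(np.exp(np.interp(np.log(x), np.log(xs), np.log(ys))))


def optical_constants(material_name: str, energy_kev: float = 17.0) -> Material:
    """Look up delta and mu for a phantom material at the given energy.

    Parameters
    ----------
    material_name : str
        One of ``SUPPORTED_MATERIALS`` (water, nylon12, air, gas_core,
        polymer_shell).  The gas core uses vacuum constants: its delta
        and mu are negligible against the surrounding liquid.
    energy_kev : float
        Photon energy in keV, within the tabulated 15-20 keV band.

    Returns
    -------
    Material
        Constants interpolated log-linearly between tabulated energies.
    """
    if material_name not in _TABLE:
        raise KeyError(
            f"unknown material {material_name!r}; supported: "
            + ", ".join(SUPPORTED_MATERIALS)
        )
    if energy_kev <= 0:
        raise ValueError("energy_kev must be positive")
    energies, deltas, mus = _TABLE[material_name]
    if not energies[0] <= energy_kev <= energies[-1]:
        raise ValueError(
            f"energy {energy_kev} keV outside tabulated range "
            f"[{energies[0]}, {energies[-1]}] keV"
        )
    return Material(
        name=material_name,
        delta=_loglog_interp(energy_kev, energies, deltas),
        mu=_loglog_interp(energy_kev, energies, mus),
    )


def reflectivity(curve: RockingCurve, deviation_urad) -> np.ndarray | float:
    """Analyser reflectivity at the given angular deviation(s) from the peak.

    Vectorised over ``deviation_urad``; defined for all real deviations,
    symmetric about zero and maximal at zero.
    """
    dev = np.asarray(deviation_urad, dtype=float)
    sigma = curve.sigma_urad
    gauss = np.exp(-0.5 * (dev / sigma) ** 2)
    if curve.shape == "gaussian":
        profile = gauss
    else:
        hwhm = 0.5 * curve.fwhm_urad
        lorentz = 1.0 / (1.0 + (dev / hwhm) ** 2)
        profile = curve.eta * lorentz + (1.0 - curve.eta) * gauss
    out = curve.peak_reflectivity * profile
    return float(out) if np.isscalar(deviation_urad) else out


def find_working_point(
    curve: RockingCurve, level: float = 0.05, side: str = "positive"
) -> WorkingPoint:
    """Locate the tail offset where reflectivity equals ``level`` x peak.

    Root-found on the requested side of the (symmetric, monotone-tailed)
    curve.  ``level`` must lie strictly between 0 and 1: the peak itself
    is not a tail point and the profile never reaches zero.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be strictly between 0 and 1")
    target = level * curve.peak_reflectivity

    def f(x: float) -> float:
        return float(reflectivity(curve, x)) - target

    # Bracket: expand until the profile has fallen below the target.
    hi = curve.fwhm_urad
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6 * curve.fwhm_urad:  # pragma: no cover - defensive
            raise RuntimeError("failed to bracket working point")
    offset = brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14)
    if side == "negative":
        offset = -offset
    return WorkingPoint(offset_urad=offset, reflectivity_level=level, side=side)
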