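"""Run configuration: one YAML file drives the whole pipeline.

Defaults reproduce the reference acquisition: 17 keV beam, 4 mm
internal-diameter Nylon-12 tube, 9 um detector pixels with 4x4
binning, 0.5 s exposure + 0.27 s readout, analyser parked at 5 %
reflectivity, bubble median radius 4 um.  Every key carries its unit
in its name.  Unknown keys are rejected with the offending path, and
a config echo (plus its hash) accompanies every artifact a run writes.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .flow import AcquisitionTiming, DilutionModel
from .optics import RockingCurve, WorkingPoint, find_working_point
from .phantom import SizeDistribution, VesselGeometry
from .simulate import DetectorGrid

__all__ = ["RunConfig", "load_config", "save_config", "config_hash", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "energy_kev": 17.0,
    "rocking_curve": {
        "shape": "gaussian",
        "fwhm_urad": 20.0,
        "peak_reflectivity": 1.0,
        "eta": 0.3,
    },
    "working_point": {"level": 0.05, "side": "positive"},
    "vessel": {
        "inner_diameter_mm": 4.0,
        "wall_thickness_mm": 1.0,
        "length_mm": 0.5,
    },
    "bubbles": {
        "median_radius_um": 4.0,
        "geometric_sd": 1.7,
        "min_radius_um": 1.0,
        "max_radius_um": 12.0,
    },
    "detector": {
        "raw_pixel_um": 9.0,
        "binning": 4,
        "fov_x_mm": 0.5,
        "fov_y_mm": 4.6,
        "rays_per_pixel": 64,
        "photon_budget": 1.0e5,
    },
    "timing": {"exposure_s": 0.5, "readout_s": 0.27},
    "dilution": {
        "c1": 0.01,
        "decay_rate_per_s": 0.056,
        "flow_ml_min": None,
        "pump_side_volume_ml": 2.3,
        "far_side_volume_ml": 2.8,
        "output_ratio": None,
    },
    "sequence": {"n_frames": 40},
    "quantify": {
        "lumen_fraction": 0.5,
        "snr_threshold": 5.0,
        "n_boot": 1000,
        "calibration_levels": [0.0, 0.002, 0.004, 0.006, 0.008, 0.01],
        "calibration_replicates": 3,
    },
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    """Defaults overlaid with user values; unknown keys are an error."""
    out = copy.deepcopy(defaults)
    for key, value in (user or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(
                f"unknown config key {here!r}; known keys at this level: "
                + ", ".join(sorted(defaults))
            )
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"config section {here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration tree (see ``DEFAULTS`` for the schema)."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __post_init__(self) -> None:
        # constructing the domain objects runs their invariant checks
        for build in (
            self.rocking_curve,
            self.working_point,
            self.vessel,
            self.bubbles,
            self.detector,
            self.timing,
            self.dilution,
        ):
            build()
        if self.data["sequence"]["n_frames"] < 1:
            raise ValueError("sequence.n_frames must be >= 1")

    # --- domain-object builders ---------------------------------------

    def rocking_curve(self) -> RockingCurve:
        rc = self.data["rocking_curve"]
        try:
            return RockingCurve(
                shape=rc["shape"],
                fwhm_urad=float(rc["fwhm_urad"]),
                peak_reflectivity=float(rc["peak_reflectivity"]),
                eta=float(rc["eta"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"rocking_curve: {exc}") from exc

    def working_point(self) -> WorkingPoint:
        wp = self.data["working_point"]
        try:
            return find_working_point(
                self.rocking_curve(), float(wp["level"]), wp["side"]
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"working_point: {exc}") from exc

    def vessel(self) -> VesselGeometry:
        v = self.data["vessel"]
        try:
            return VesselGeometry(
                inner_diameter_mm=float(v["inner_diameter_mm"]),
                wall_thickness_mm=float(v["wall_thickness_mm"]),
                length_mm=float(v["length_mm"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"vessel: {exc}") from exc

    def bubbles(self) -> SizeDistribution:
        b = self.data["bubbles"]
        try:
            return SizeDistribution(
                median_radius_um=float(b["median_radius_um"]),
                geometric_sd=float(b["geometric_sd"]),
                min_radius_um=float(b["min_radius_um"]),
                max_radius_um=float(b["max_radius_um"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"bubbles: {exc}") from exc

    def detector(self) -> DetectorGrid:
        d = self.data["detector"]
        try:
            return DetectorGrid(
                raw_pixel_um=float(d["raw_pixel_um"]),
                binning=int(d["binning"]),
                fov_x_mm=float(d["fov_x_mm"]),
                fov_y_mm=float(d["fov_y_mm"]),
                rays_per_pixel=int(d["rays_per_pixel"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"detector: {exc}") from exc

    def timing(self) -> AcquisitionTiming:
        t = self.data["timing"]
        try:
            return AcquisitionTiming(
                exposure_s=float(t["exposure_s"]), readout_s=float(t["readout_s"])
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"timing.exposure_s/readout_s: {exc}") from exc

    def dilution(self) -> DilutionModel:
        d = self.data["dilution"]
        try:
            if d["decay_rate_per_s"] is not None:
                return DilutionModel(
                    c1=float(d["c1"]), decay_rate=float(d["decay_rate_per_s"])
                )
            if d["flow_ml_min"] is None or d["output_ratio"] is None:
                raise ValueError(
                    "either decay_rate_per_s or both flow_ml_min and "
                    "output_ratio must be set"
                )
            return DilutionModel.from_loop(
                c1=float(d["c1"]),
                flow_rate_ml_s=float(d["flow_ml_min"]) / 60.0,
                pump_side_volume_ml=float(d["pump_side_volume_ml"]),
                far_side_volume_ml=float(d["far_side_volume_ml"]),
                output_ratio=float(d["output_ratio"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"dilution: {exc}") from exc

    def photon_budget(self) -> float | None:
        pb = self.data["detector"]["photon_budget"]
        return None if pb is None else float(pb)

    @property
    def seed(self) -> int:
        return int(self.data["seed"])


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; an empty/missing body means defaults."""
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    user = yaml.safe_load(p.read_text()) or {}
    if not isinstance(user, dict):
        raise TypeError("config file must contain a YAML mapping")
    return RunConfig(data=_merge(DEFAULTS, user))


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.data, sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying the exact configuration."""
    canon = yaml.safe_dump(config.data, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
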