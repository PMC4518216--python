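"""Well-mixed loop dilution kinetics and acquisition timing.

The flow phantom pumps a microbubble suspension around a closed loop;
when the inlet/outlet valves open, bubble-free liquid is drawn in and
the circulating concentration decays approximately exponentially,

    C(t) = C1 * exp(-D * t),

with decay constant ``D`` (1/s) set by the pump rate and valve
restriction.  ``D`` is the primary parameter here — runs are specified
by it directly (e.g. 0.056 1/s).  A well-mixed single-compartment
estimate D = R*Q/(V_p + V_l) is provided as a documented convenience
for users who only know the loop parameters; it is an assumption of
this package, not a calibrated device model.

Frames are timestamped at mid-exposure so each intensity sample pairs
with the concentration halfway through its integration window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DilutionModel",
    "AcquisitionTiming",
    "concentration_at",
    "decay_constant",
    "frame_period",
    "frame_times",
]


@dataclass(frozen=True)
class DilutionModel:
    """Exponential dilution of the circulating bubble concentration.

    Attributes
    ----------
    c1 : float
        Initial volume concentration (gas volume fraction, dimensionless).
    decay_rate : float
        Decay constant D in 1/s.
    """

    c1: float
    decay_rate: float

    def __post_init__(self) -> None:
        if self.c1 < 0:
            raise ValueError("c1 must be nonnegative")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be nonnegative")

    @classmethod
    def from_loop(
        cls,
        c1: float,
        flow_rate_ml_s: float,
        pump_side_volume_ml: float = 2.3,
        far_side_volume_ml: float = 2.8,
        output_ratio: float = 0.2,
    ) -> "DilutionModel":
        """Build a model from loop parameters via the well-mixed formula."""
        return cls(
            c1=c1,
            decay_rate=decay_constant(
                flow_rate_ml_s,
                pump_side_volume_ml,
                far_side_volume_ml,
                output_ratio,
            ),
        )


@dataclass(frozen=True)
class AcquisitionTiming:
    """Detector exposure/readout cadence (defaults: 0.5 s + 0.27 s)."""

    exposure_s: float = 0.5
    readout_s: float = 0.27

    def __post_init__(self) -> None:
        if self.exposure_s < 0 or self.readout_s < 0:
            raise ValueError("exposure and readout must be nonnegative")


def concentration_at(model: DilutionModel, t) -> np.ndarray | float:
    """Concentration C1*exp(-D*t) at time(s) ``t`` >= 0 (seconds)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    out = model.c1 * np.exp(-model.decay_rate * t_arr)
    return float(out) if np.isscalar(t) else out


def decay_constant(
    flow_rate_ml_s: float,
    pump_side_volume_ml: float,
    far_side_volume_ml: float,
    output_ratio: float,
) -> float:
    """Well-mixed single-compartment decay constant R*Q/(V_p + V_l) in 1/s.

    Fresh liquid enters at rate ``output_ratio * flow_rate`` and mixes
    instantly into the full loop volume.  Documented assumption: the
    real device's two tubing volumes either side of the junction may
    depart from perfect mixing; supply D directly when it is known.
    """
    if min(flow_rate_ml_s, pump_side_volume_ml, far_side_volume_ml) < 0:
        raise ValueError("flow rate and volumes must be nonnegative")
    if not 0.0 <= output_ratio <= 1.0:
        raise ValueError("output_ratio must be in [0, 1]")
    total = pump_side_volume_ml + far_side_volume_ml
    if total == 0:
        raise ValueError("loop volume must be positive")
    return output_ratio * flow_rate_ml_s / total


def frame_period(timing: AcquisitionTiming) -> float:
    """Seconds from one frame start to the next: exposure + readout."""
    return timing.exposure_s + timing.readout_s


def frame_times(
    timing: AcquisitionTiming, n_frames: int, t0: float = 0.0
) -> np.ndarray:
    """Mid-exposure timestamps of ``n_frames`` consecutive frames."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    k = np.arange(n_frames, dtype=float)
    return t0 + k * frame_period(timing) + 0.5 * timing.exposure_s
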