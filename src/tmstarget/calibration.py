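"""Device-output calibration: Standard Motor Threshold units to dI/dt.

The stimulator's output is expressed in Standard Motor Threshold (SMT)
units: 1 SMT is the setting that induces 135 V/m at a point 2 cm along
the coil's central axis below the scalp.  Given the reference field
E'_2cm produced by the coil model at unit current I0 and angular
frequency omega0 (time-harmonic drive, so dI/dt = omega0 I0), the output
per SMT unit is

    dI/dt per SMT = E_target * omega0 * I0 / E'_2cm.

With the device-sheet analog E'_2cm = 0.066 V/m this gives 64.26 A/us.
The winding geometry of the treatment coil is proprietary; the default
figure-eight model is therefore calibrated so that its computed E'_2cm
matches the configured ``reference_output``, which closes the loop:
driving the calibrated coil at 1 SMT reproduces the 135 V/m target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coil import CoilModel, Placement, default_coil
from .efield import SphereConductor, depth_profile
from .targeting import ScalpPoint

__all__ = [
    "CalibrationSpec",
    "CalibrationResult",
    "standard_placement",
    "e_ref_at_depth",
    "calibrate_coil",
    "smt_to_didt",
    "subject_didt",
]


@dataclass(frozen=True)
class CalibrationSpec:
    e_target: float = 135.0  # V/m at calibration depth for 1 SMT
    depth: float = 20.0  # mm below the scalp along the coil axis
    i0: float = 1.0  # A
    omega0: float = 2 * np.pi * 5000.0  # rad/s
    e_ref: float = 0.066  # V/m at (i0, omega0)

    def __post_init__(self):
        if self.e_target < 0:
            raise ValueError("e_target must be non-negative")
        if min(self.depth, self.i0, self.omega0, self.e_ref) <= 0:
            raise ValueError("depth, i0, omega0 and e_ref must be positive")


@dataclass(frozen=True)
class CalibrationResult:
    didt_per_smt: float  # A/s
    provenance: CalibrationSpec

    @property
    def didt_per_smt_a_per_us(self) -> float:
        return self.didt_per_smt * 1e-6


def standard_placement(sphere: SphereConductor, hair_offset: float = 4.0) -> Placement:
    """Calibration pose: coil on the vertex, axis radial, default orientation."""
    top = np.array([0.0, 0.0, sphere.radius])
    return Placement(
        scalp_point=ScalpPoint(position=top, outward_normal=np.array([0.0, 0.0, 1.0])),
        orientation_deg=45.0,
        hair_offset=hair_offset,
    )


def e_ref_at_depth(
    coil: CoilModel,
    sphere: SphereConductor,
    spec: CalibrationSpec = CalibrationSpec(),
    placement: Placement | None = None,
) -> float:
    """|E| (V/m) at the calibration depth under time-harmonic drive
    dI/dt = omega0 * I0."""
    placement = placement or standard_placement(sphere)
    return float(
        depth_profile(coil, placement, sphere, spec.omega0 * spec.i0, np.array([spec.depth]))[0]
    )


def calibrate_coil(
    coil: CoilModel,
    sphere: SphereConductor,
    spec: CalibrationSpec = CalibrationSpec(),
) -> CoilModel:
    """Rescale the coil's dipole weights so its computed reference field at
    the calibration depth equals ``coil.reference_output``."""
    raw = e_ref_at_depth(coil.with_scale(1.0), sphere, spec)
    if raw <= 0:
        raise ValueError("raw reference field is zero; cannot calibrate")
    return coil.with_scale(coil.reference_output / raw)


def calibrated_default_coil(
    sphere: SphereConductor | None = None, n_dipoles: int = 60
) -> CoilModel:
    sphere = sphere or SphereConductor()
    return calibrate_coil(default_coil(n_dipoles=n_dipoles), sphere)


def smt_to_didt(spec: CalibrationSpec = CalibrationSpec()) -> CalibrationResult:
    """dI/dt (A/s) corresponding to 1 SMT of device output."""
    if spec.e_ref == 0:
        raise ValueError("e_ref must be nonzero")
    didt = spec.e_target * spec.omega0 * spec.i0 / spec.e_ref
    return CalibrationResult(didt_per_smt=didt, provenance=spec)


def subject_didt(subject, calibration: CalibrationResult, treatment: bool = True) -> float:
    """dI/dt (A/s) for one subject.

    Treatment simulations are run at the treatment intensity (1.2 x SMT);
    motor-hotspot simulations at the motor threshold itself (1.0 x SMT).
    """
    intensity = subject.treatment_intensity if treatment else subject.smt
    if intensity < 0:
        raise ValueError("stimulation intensity must be non-negative")
    return intensity * calibration.didt_per_smt
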