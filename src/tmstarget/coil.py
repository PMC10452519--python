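"""Figure-eight coil model discretized to magnetic dipoles.

The treatment coil is represented as two coplanar circular wings of
opposite polarity, each discretized into a layer of small magnetic
dipoles whose weights sum to the wing's magnetic moment per unit
current (turns x area).  The real device's ferromagnetic core is not
modeled geometrically; its effect on output is absorbed into a single
calibration scale factor tied to the device's specified reference field
(``reference_output``, the field at 2 cm depth in the standard spherical
head at I0 = 1 A, omega0 = 2 pi x 5 kHz).

Local coil frame: wings centred at +/- separation/2 along local x, coil
plane z = 0, wing normals +/- z.  Placement maps local z to the outward
scalp normal and rotates about it so that the primary-current axis
(local y) makes ``orientation_deg`` with the local toward-midline
direction; 45 degrees is the standard clinical placement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import toward_midline, unit
from .targeting import ScalpPoint

__all__ = ["CoilGeometry", "CoilModel", "Placement", "discretize_coil", "default_coil"]

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class CoilGeometry:
    loop_radius: float = 35.0  # mm
    loop_separation: float = 40.0  # mm, distance between wing centres
    turns: int = 1

    def validate(self) -> None:
        if self.loop_radius <= 0 or self.loop_separation < 0 or self.turns < 1:
            raise ValueError("degenerate coil geometry")


@dataclass
class CoilModel:
    """Dipole-discretized figure-eight coil.

    ``positions`` are local-frame dipole positions in mm; ``moments`` are
    dipole moment vectors per unit coil current in A m^2 / A (i.e. m^2),
    already including the calibration ``scale``.
    """

    geometry: CoilGeometry
    positions: np.ndarray  # (n, 3) mm, local frame
    moments: np.ndarray  # (n, 3) m^2 per unit current
    scale: float = 1.0
    reference_output: float = 0.066  # V/m at 2 cm depth, I0=1 A, omega0=2pi*5 kHz

    @property
    def n_dipoles(self) -> int:
        return len(self.positions)

    def with_scale(self, scale: float) -> "CoilModel":
        if scale <= 0:
            raise ValueError("scale must be positive")
        return replace(
            self,
            positions=self.positions.copy(),
            moments=self.moments * (scale / self.scale),
            scale=scale,
        )

    def wing_moment(self, sign: int) -> np.ndarray:
        """Net moment (m^2 per unit current) of the +z (sign=+1) or -z wing."""
        sel = np.sign(self.moments[:, 2]) == sign
        return self.moments[sel].sum(axis=0)


def _gauss_disc(n_dipoles: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature of the uniform dipole sheet over a disc.

    Gauss-Legendre nodes in radius crossed with a midpoint rule in angle;
    returns points (n,3) in the disc plane (mm) and area weights (mm^2)
    summing to pi radius^2 exactly.  A current loop is equivalent to a
    uniform magnetic-dipole sheet over any spanning surface, so this
    converges rapidly for field points a few millimetres off the plane.
    """
    n_r = max(1, int(round(np.sqrt(n_dipoles / 2.4))))
    n_th = max(3, int(np.ceil(n_dipoles / n_r)))
    x, w = np.polynomial.legendre.leggauss(n_r)
    r = radius * (x + 1.0) / 2.0
    wr = w * radius / 2.0
    th = 2 * np.pi * (np.arange(n_th) + 0.5) / n_th
    rr, tt = np.meshgrid(r, th)
    ww = np.meshgrid(wr * r, th)[0] * (2 * np.pi / n_th)
    pts = np.column_stack(
        [(rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel(), np.zeros(rr.size)]
    )
    return pts, ww.ravel()


def discretize_coil(
    geometry: CoilGeometry = CoilGeometry(),
    n_dipoles: int = 60,
    reference_output: float = 0.066,
) -> CoilModel:
    """Discretize each wing into about ``n_dipoles`` magnetic dipoles.

    Each wing is a uniform dipole sheet over its disc (equivalent to the
    winding's circulating current) sampled on a Gauss-Legendre-in-radius
    grid; weights carry turns x area so the wing's total moment per unit
    current equals turns x area exactly.  The two wings have opposite
    polarity (+z wing at +x).
    """
    geometry.validate()
    if n_dipoles < 2:
        raise ValueError("need at least 2 dipoles per wing")
    pts, w_mm2 = _gauss_disc(n_dipoles, geometry.loop_radius)
    w = geometry.turns * w_mm2 * MM**2  # mm^2 -> m^2
    half_sep = geometry.loop_separation / 2.0
    n = len(pts)
    pos = np.vstack([pts + [half_sep, 0, 0], pts + [-half_sep, 0, 0]])
    mom = np.zeros_like(pos)
    mom[:n, 2] = w
    mom[n:, 2] = -w
    return CoilModel(
        geometry=geometry, positions=pos, moments=mom,
        reference_output=reference_output,
    )


def default_coil(n_dipoles: int = 60) -> CoilModel:
    return discretize_coil(CoilGeometry(), n_dipoles=n_dipoles)


@dataclass
class Placement:
    """A coil pose on the scalp.

    The coil plane is tangent at ``scalp_point`` offset outward by
    ``hair_offset`` mm; ``orientation_deg`` rotates the coil about the
    outward normal, measured from the toward-midline direction to the
    primary-current axis (counterclockwise seen from outside).
    """

    scalp_point: ScalpPoint
    orientation_deg: float = 45.0
    hair_offset: float = 4.0

    @property
    def coil_center(self) -> np.ndarray:
        return self.scalp_point.position + self.hair_offset * self.scalp_point.outward_normal

    def frame(self) -> np.ndarray:
        """3x3 matrix with rows = world directions of the local x, y, z axes."""
        n = self.scalp_point.outward_normal
        ref = toward_midline(self.scalp_point.position, n)
        ang = np.deg2rad(self.orientation_deg)
        # Rodrigues rotation of ref about n by ang
        y = (
            ref * np.cos(ang)
            + np.cross(n, ref) * np.sin(ang)
            + n * (n @ ref) * (1 - np.cos(ang))
        )
        y = unit(y)
        x = np.cross(y, n)
        return np.vstack([x, y, n])

    def to_dict(self) -> dict:
        return {
            "position": self.scalp_point.position.tolist(),
            "normal": self.scalp_point.outward_normal.tolist(),
            "orientation_deg": float(self.orientation_deg),
            "hair_offset_mm": float(self.hair_offset),
        }


def placed_dipoles(coil: CoilModel, placement: Placement) -> tuple[np.ndarray, np.ndarray]:
    """World-frame dipole positions (mm) and moment vectors (m^2 per unit
    current) for ``coil`` under ``placement``."""
    F = placement.frame()  # rows are world axes
    pos = placement.coil_center + coil.positions @ F
    mom = coil.moments @ F
    return pos, mom
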