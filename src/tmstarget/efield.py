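"""Quasi-static E-field of a coil outside a homogeneous spherical conductor.

In the quasi-static regime the induced field splits into a primary part,
E_p = -dA/dt from the coil's magnetic vector potential, and a secondary
part, E_s = -grad(phi), where the interior harmonic potential phi
enforces zero normal current at the surface.  For a spherical conductor
both parts combine into an exact closed form per magnetic dipole: by
electromagnetic reciprocity the total field at r inside the sphere due
to a dipole with moment-per-current w at r0 outside is the transpose of
the magnetometer lead field of Sarvas' formula,

    E(r) = -dI/dt * mu0/(4 pi F^2) [ F (r x w) - (r x r0) (gradF . w) ],

with F = a (r0 a + r0^2 - r.r0), a = r0 - r.  Consequences that the
implementation inherits exactly: E vanishes at the sphere centre, E is
everywhere tangential, and E is independent of the sphere radius and
conductivity (homogeneous conductor).

An independent boundary-element oracle (single-layer surface charge on a
triangulated sphere, collocation with the closed-surface solid-angle
identity) is provided for cross-validation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .coil import MM, CoilModel, Placement, placed_dipoles

__all__ = [
    "SphereConductor",
    "TissueConductivities",
    "FieldResult",
    "efield_total",
    "efield_primary",
    "efield_oracle_bem",
    "depth_profile",
    "normal_component",
    "field_on_grid",
]

MU0_4PI = 1e-7  # H/m / (4 pi)


@dataclass(frozen=True)
class SphereConductor:
    radius: float = 85.0  # mm
    conductivity: float = 0.33  # S/m; does not affect the interior E-field

    def __post_init__(self):
        if self.radius <= 0 or self.conductivity <= 0:
            raise ValueError("radius and conductivity must be positive")


@dataclass(frozen=True)
class TissueConductivities:
    """Multi-tissue conductivities (S/m), carried as configuration for
    layered-model extensions; the homogeneous solver does not use them."""

    skin: float = 0.465
    skull: float = 0.010
    csf: float = 1.654
    gray: float = 0.275
    white: float = 0.126
    eyes: float = 0.5

    def __post_init__(self):
        if any(v <= 0 for v in self.__dict__.values()):
            raise ValueError("conductivities must be positive")


@dataclass
class FieldResult:
    sample_points: np.ndarray  # (n, 3) mm
    e_vectors: np.ndarray  # (n, 3) V/m
    didt: float  # A/s
    placement: Placement | None = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.e_vectors, axis=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            np.hstack([self.sample_points, self.e_vectors]),
            columns=["x_mm", "y_mm", "z_mm", "Ex", "Ey", "Ez"],
        )


def _check_placement(coil: CoilModel, placement: Placement, sphere: SphereConductor):
    pos, mom = placed_dipoles(coil, placement)
    if np.linalg.norm(pos, axis=1).min() <= sphere.radius:
        raise ValueError("coil dipoles must lie strictly outside the sphere")
    return pos, mom


def _check_points(points: np.ndarray, sphere: SphereConductor) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if np.linalg.norm(pts, axis=1).max() >= sphere.radius:
        raise ValueError("all sample points must lie strictly inside the sphere")
    return pts


def _e_closed_form(points_m, dip_pos_m, dip_mom, didt):
    """Vectorized Sarvas-reciprocity sum over dipoles; SI units in.

    Broadcasts dipoles x points in chunks sized to bound peak memory.
    """
    n_dip = len(dip_pos_m)
    chunk = max(256, int(4.0e5 / max(n_dip, 1)))
    r0 = np.asarray(dip_pos_m)  # (D,3)
    m = np.asarray(dip_mom)  # (D,3)
    r0n = np.linalg.norm(r0, axis=1)  # (D,)
    E = np.empty_like(points_m)
    for start in range(0, len(points_m), chunk):
        r = points_m[start : start + chunk]  # (P,3)
        a = r0[:, None, :] - r[None, :, :]  # (D,P,3)
        an = np.linalg.norm(a, axis=2)  # (D,P)
        rdotr0 = r @ r0.T  # (P,D)
        F = an * (r0n[:, None] * an + r0n[:, None] ** 2 - rdotr0.T)
        adotr0 = np.einsum("dpk,dk->dp", a, r0)
        c1 = an**2 / r0n[:, None] + adotr0 / an + 2 * an + 2 * r0n[:, None]
        c2 = an + 2 * r0n[:, None] + adotr0 / an
        # gradF . m without materializing gradF: c1 (r0.m) - c2 (r.m)
        gFm = c1 * (np.einsum("dk,dk->d", r0, m))[:, None] - c2 * (r @ m.T).T
        rxm = np.cross(r[None, :, :], m[:, None, :])  # (D,P,3)
        rxr0 = np.cross(r[None, :, :], r0[:, None, :])
        acc = ((F[:, :, None] * rxm - rxr0 * gFm[:, :, None]) / F[:, :, None] ** 2).sum(axis=0)
        E[start : start + chunk] = -didt * MU0_4PI * acc
    return E


def efield_total(
    coil: CoilModel,
    placement: Placement,
    sphere: SphereConductor,
    points: np.ndarray,
    didt: float,
) -> FieldResult:
    """Total (primary + secondary) E-field at interior ``points`` (mm), V/m.

    Exact analytic solution for the homogeneous sphere; linear in
    ``didt`` and independent of the conductivity value.
    """
    pos, mom = _check_placement(coil, placement, sphere)
    pts = _check_points(points, sphere)
    E = _e_closed_form(pts * MM, pos * MM, mom, didt)
    return FieldResult(sample_points=pts, e_vectors=E, didt=didt, placement=placement)


def efield_primary(
    coil: CoilModel, placement: Placement, points: np.ndarray, didt: float
) -> np.ndarray:
    """Primary field -dA/dt alone (V/m), valid anywhere off the dipoles."""
    pos, mom = placed_dipoles(coil, placement)
    pts = np.atleast_2d(np.asarray(points, dtype=float)) * MM
    return _e_primary(pts, pos * MM, mom, didt)


def _e_primary(points_m, dip_pos_m, dip_mom, didt):
    d = points_m[None, :, :] - dip_pos_m[:, None, :]  # (D,P,3)
    dn = np.linalg.norm(d, axis=2)
    E = (np.cross(dip_mom[:, None, :], d) / dn[:, :, None] ** 3).sum(axis=0)
    return -MU0_4PI * didt * E


def efield_oracle_bem(
    coil: CoilModel,
    placement: Placement,
    sphere: SphereConductor,
    points: np.ndarray,
    didt: float,
    subdivisions: int = 4,
) -> FieldResult:
    """Independent numerical solution via a single-layer surface charge.

    The charge density rho on the triangulated sphere solves the
    collocation system (I/2 - K) rho = n . E_p with the adjoint
    double-layer operator K; the diagonal uses the closed-surface row-sum
    identity sum_j K_ij = 1/2, and the constant nullspace is deflated by
    enforcing zero total charge.  Used only for cross-validation.
    """
    pos, mom = _check_placement(coil, placement, sphere)
    pts = _check_points(points, sphere)

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=sphere.radius * MM)
    cent = mesh.triangles_center
    areas = mesh.area_faces
    nrm = mesh.face_normals
    n = len(cent)

    rhs = np.einsum("ij,ij->i", _e_primary(cent, pos * MM, mom, didt), nrm)
    K = np.empty((n, n))
    block = max(1, int(2.0e7 / n))
    for s in range(0, n, block):
        diff = cent[s : s + block, None, :] - cent[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        dist[dist == 0] = 1.0
        K[s : s + block] = (
            np.einsum("ik,ijk->ij", nrm[s : s + block], diff)
            / (4 * np.pi * dist**3)
            * areas[None, :]
        )
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, 0.5 - K.sum(axis=1))
    A = 0.5 * np.eye(n) - K + np.outer(np.ones(n), areas / areas.sum())
    rho = np.linalg.solve(A, rhs)

    pts_m = pts * MM
    Es = np.empty_like(pts_m)
    block = max(1, int(2.0e7 / n))
    for s in range(0, len(pts_m), block):
        d = pts_m[s : s + block, None, :] - cent[None, :, :]
        dn = np.linalg.norm(d, axis=2)
        Es[s : s + block] = (
            np.einsum("j,pjk->pk", rho * areas, d / dn[:, :, None] ** 3) / (4 * np.pi)
        )
    E = _e_primary(pts_m, pos * MM, mom, didt) + Es
    return FieldResult(sample_points=pts, e_vectors=E, didt=didt, placement=placement)


def depth_profile(
    coil: CoilModel,
    placement: Placement,
    sphere: SphereConductor,
    didt: float,
    depths: np.ndarray,
) -> np.ndarray:
    """|E| (V/m) along the inward coil axis at ``depths`` mm below the scalp."""
    depths = np.asarray(depths, dtype=float)
    if np.any(depths <= 0) or np.any(depths >= 2 * sphere.radius):
        raise ValueError("depths must lie in (0, 2R)")
    n = placement.scalp_point.outward_normal
    pts = placement.scalp_point.position[None, :] - depths[:, None] * n[None, :]
    return efield_total(coil, placement, sphere, pts, didt).magnitude


def normal_component(field: FieldResult, normals: np.ndarray) -> np.ndarray:
    """Signed E . n_hat at each sample point (outward-positive)."""
    normals = np.atleast_2d(np.asarray(normals, dtype=float))
    if normals.shape != field.e_vectors.shape:
        raise ValueError("point and normal counts must match")
    nn = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return np.einsum("ij,ij->i", field.e_vectors, nn)


def field_on_grid(
    coil: CoilModel,
    placement: Placement,
    sphere: SphereConductor,
    grid,
    didt: float,
) -> np.ndarray:
    """|E| volume over a GmGrid: values at member voxel centres, 0 elsewhere."""
    vol = np.zeros(grid.data.shape)
    pts = grid.voxel_centers(member_only=True)
    res = efield_total(coil, placement, sphere, pts, didt)
    vol[grid.data] = res.magnitude
    return vol
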