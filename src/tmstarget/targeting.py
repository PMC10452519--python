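"""Scalp- and anatomy-based coil targeting constructions.

Implements the four ways of choosing where the coil goes:

* the 5 cm rule — a fixed geodesic advance anterior of the motor hotspot
  in the parasagittal plane;
* F3 of the International 10-20 EEG system, built by the constructive
  arc chain on the actual scalp surface;
* the anatomical DLPFC brain target (DBT) built from corpus-callosum
  geometry and projected to the scalp (DST);
* the L-DLPFC gray-matter voxel mask whose median field is the dose
  metric (the E-field-optimized placement is in ``optimizer``).

Conventions: RAS frame, left hemisphere x < 0; coronal/axial mask planes
are perpendicular to the head-frame y/z axes; voxels belong to a mask if
their centre satisfies all predicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import arc_angle, geodesic_midpoint, sphere_geodesic, unit
from .head import GmGrid, HeadModel

__all__ = [
    "ScalpPoint",
    "MaskSpec",
    "RoiMask",
    "DbtResult",
    "five_cm_target",
    "ten_twenty_positions",
    "dbt_construct",
    "scalp_project",
    "build_dlpfc_mask",
]


@dataclass
class ScalpPoint:
    """A point on the scalp with its outward unit normal."""

    position: np.ndarray
    outward_normal: np.ndarray
    degenerate_tie: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.outward_normal = unit(self.outward_normal)


def _on_scalp(head: HeadModel, position: np.ndarray, tol: float = 0.1) -> bool:
    return abs(np.linalg.norm(position) - head.scalp_radius) <= tol


def _measurement_frame(head: HeadModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal scalp-measurement frame (right, nasion, vertex directions).

    Scalp-measurement constructions (10-20 chain, 5 cm rule) run in this
    frame, which may be slightly rotated relative to the anatomy."""
    lm = head.landmarks
    return unit(lm.rpa), unit(lm.nasion), unit(lm.vertex)


def scalp_point(head: HeadModel, position: np.ndarray) -> ScalpPoint:
    """ScalpPoint at ``position`` (must lie on the scalp sphere)."""
    if not _on_scalp(head, position):
        raise ValueError("point does not lie on the scalp surface")
    return ScalpPoint(position=position, outward_normal=unit(position))


def five_cm_target(
    head: HeadModel,
    hotspot: ScalpPoint | None = None,
    distance: float = 50.0,
    chord: bool = False,
) -> ScalpPoint:
    """Scalp point ``distance`` mm anterior of the motor hotspot.

    The advance follows the parasagittal section (constant x) of the
    scalp.  By default the distance is measured as a geodesic arc along
    the scalp; with ``chord=True`` it is the straight-line chord in the
    parasagittal plane.
    """
    if hotspot is None:
        hotspot = scalp_point(head, head.landmarks.motor_hotspot)
    if distance < 0:
        raise ValueError("distance must be >= 0")
    p = hotspot.position
    R = head.scalp_radius
    e1, e2, e3 = _measurement_frame(head)
    x = p @ e1
    rho = np.sqrt(max(R**2 - x**2, 0.0))
    if rho < 1e-6:
        raise ValueError("parasagittal section through the hotspot is degenerate")
    # in-plane polar angle; anterior advance decreases the angle toward nasion
    alpha = np.arctan2(p @ e3, p @ e2)
    if chord:
        half = distance / (2 * rho)
        if half > 1:
            raise ValueError("chord longer than the parasagittal section diameter")
        dalpha = 2 * np.arcsin(half)
    else:
        dalpha = distance / rho
    a = alpha - dalpha
    q = x * e1 + rho * np.cos(a) * e2 + rho * np.sin(a) * e3
    return ScalpPoint(position=q, outward_normal=unit(q))


def ten_twenty_positions(head: HeadModel) -> dict[str, ScalpPoint]:
    """Named 10-20 scalp positions from the constructive arc chain.

    Cz sits at the crossing of the 50% nasion-inion and 50% ear-to-ear
    arcs; Fz/Pz at 30%/70% and Fpz/Oz at 10%/90% of the nasion-inion arc;
    Fp1/Fp2 and F7/F8 at 5% and 15% of the circumferential ring through
    Fpz and Oz, measured from Fpz (left negative x); F3 (F4) is the
    geodesic midpoint of the F7-Fz (F8-Fz) arc.
    """
    lm = head.landmarks
    for name in ("nasion", "inion", "lpa", "rpa", "vertex"):
        if getattr(lm, name) is None:
            raise ValueError(f"landmark {name} missing")
    R = head.scalp_radius
    e1, e2, e3 = _measurement_frame(head)

    def sagittal(frac):  # along nasion->inion over the vertex
        ang = frac * np.pi
        return R * np.cos(ang) * e2 + R * np.sin(ang) * e3

    pts: dict[str, np.ndarray] = {
        "Nz": lm.nasion, "Iz": lm.inion, "Cz": sagittal(0.5),
        "Fpz": sagittal(0.1), "Fz": sagittal(0.3),
        "Pz": sagittal(0.7), "Oz": sagittal(0.9),
    }
    # circumferential ring through Fpz and Oz
    z0 = R * np.sin(0.1 * np.pi)
    rho0 = np.sqrt(R**2 - z0**2)
    for name, frac, sign in (
        ("Fp1", 0.05, +1), ("Fp2", 0.05, -1),
        ("F7", 0.15, +1), ("F8", 0.15, -1),
        ("T7", 0.25, +1), ("T8", 0.25, -1),
    ):
        psi = np.pi / 2 + sign * 2 * np.pi * frac  # from nasion, left is psi > pi/2
        pts[name] = rho0 * np.cos(psi) * e1 + rho0 * np.sin(psi) * e2 + z0 * e3
    pts["F3"] = geodesic_midpoint(pts["F7"], pts["Fz"])
    pts["F4"] = geodesic_midpoint(pts["F8"], pts["Fz"])
    pts["P3"] = geodesic_midpoint(pts["T7"], pts["Pz"])
    pts["P4"] = geodesic_midpoint(pts["T8"], pts["Pz"])
    return {k: ScalpPoint(position=v, outward_normal=unit(v)) for k, v in pts.items()}


@dataclass
class DbtResult:
    """Anatomically constructed DLPFC brain target: the centre of a
    20 mm cubic ROI aligned with the slab frame."""

    center: np.ndarray
    slab_normal: np.ndarray
    slab_center_coord: float
    half_thickness: float
    clamped: bool


def dbt_construct(head: HeadModel, slab_thickness: float = 20.0) -> DbtResult:
    """Build the DLPFC brain target from corpus-callosum geometry.

    Steps: (1) the inferior corpus-callosum plane through the inferior
    margins of the rostrum and splenium; (2) a coronal-oblique slab of
    ``slab_thickness`` perpendicular to that plane, centred 10 mm
    anterior of the genu; (3) the deep superior-frontal-sulcus point,
    constrained to the slab along the slab normal.  If the point falls
    outside the slab it is moved to the nearest in-slab coordinate and
    the result is flagged.
    """
    an = head.anatomy
    d = an.cc_splenium_inferior - an.cc_rostrum_inferior
    xhat = np.array([1.0, 0.0, 0.0])
    n_plane = unit(np.cross(xhat, d))
    if n_plane[2] < 0:
        n_plane = -n_plane
    # slab normal: in the inferior plane, perpendicular to x, anterior
    m = unit(np.cross(n_plane, xhat))
    if m[1] < 0:
        m = -m
    half = slab_thickness / 2.0
    center_coord = float(an.cc_genu_anterior @ m) + 10.0
    s = float(an.sfs_deep_point @ m)
    clamped = not (center_coord - half <= s <= center_coord + half)
    s_in = float(np.clip(s, center_coord - half, center_coord + half))
    center = an.sfs_deep_point + (s_in - s) * m
    return DbtResult(
        center=center, slab_normal=m, slab_center_coord=center_coord,
        half_thickness=half, clamped=clamped,
    )


def scalp_project(brain_point: np.ndarray, head: HeadModel, method: str = "analytic") -> ScalpPoint:
    """Project a brain point to the closest scalp point (shortest straight path).

    On the spherical scalp this is the radial projection.  ``method="mesh"``
    instead takes the nearest triangulation vertex (used as a brute-force
    cross-check).  A point at the sphere centre has no unique projection;
    the tie is broken deterministically (smallest vertex index) and flagged.
    """
    p = np.asarray(brain_point, dtype=float)
    R = head.scalp_radius
    r = np.linalg.norm(p)
    if r >= R:
        raise ValueError("point must lie strictly inside the scalp")
    if r < 1e-9:
        v = head.scalp_surface.vertices[0]
        return ScalpPoint(position=np.array(v), outward_normal=unit(v), degenerate_tie=True)
    if method == "mesh":
        verts = head.scalp_surface.vertices
        i = int(np.argmin(np.linalg.norm(verts - p, axis=1)))
        v = np.array(verts[i])
        return ScalpPoint(position=v, outward_normal=unit(v))
    q = R * p / r
    return ScalpPoint(position=q, outward_normal=unit(q))


@dataclass
class MaskSpec:
    """Fractional plane positions of the L-DLPFC mask.

    The posterior coronal bound sits ``post_fraction`` of the frontal-to-
    temporal-pole distance (dFP-TP) anterior of the temporal pole tip; the
    anterior bound ``ant_fraction`` of dFP-TP posterior of the frontal
    pole tip; the inferior axial bound ``inf_fraction`` of the brain
    bottom-to-top distance (dBB-TB) above the lowest brain point.
    """

    post_fraction: float = 0.20
    ant_fraction: float = 0.40
    inf_fraction: float = 0.50

    def validate(self) -> None:
        if not (0 <= self.post_fraction and 0 <= self.ant_fraction
                and self.post_fraction + self.ant_fraction < 1):
            raise ValueError("fractions must leave a nonempty band between the poles")
        if not (0 <= self.inf_fraction < 1):
            raise ValueError("inf_fraction must be in [0, 1)")


@dataclass
class RoiMask:
    data: np.ndarray
    affine: np.ndarray
    voxel_size: float

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_centers(self) -> np.ndarray:
        idx = np.argwhere(self.data)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    @property
    def centroid(self) -> np.ndarray:
        if self.n_voxels == 0:
            raise ValueError("empty mask")
        return self.voxel_centers.mean(axis=0)

    @property
    def volume(self) -> float:
        return self.n_voxels * float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def equivalent_radius(self) -> float:
        """Radius of the sphere with the same volume as the mask."""
        return float((3.0 * self.volume / (4.0 * np.pi)) ** (1.0 / 3.0))

    def save_nifti(self, path: str) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, path)


def build_dlpfc_mask(head: HeadModel, spec: MaskSpec | None = None) -> RoiMask:
    """Binary L-DLPFC mask over the gray-matter grid.

    Keeps left-hemisphere (x < 0) gray-matter voxels whose centres lie
    between the two coronal planes derived from the frontal/temporal pole
    distance and above the axial plane derived from the brain height.
    """
    spec = spec or MaskSpec()
    spec.validate()
    an = head.anatomy
    gm: GmGrid = head.gm_grid

    fp_y = float(an.frontal_pole[1])
    tp_y = float(an.temporal_pole_left[1])
    d_fptp = fp_y - tp_y
    if d_fptp <= 0:
        raise ValueError("frontal pole must be anterior of the temporal pole")
    y_post = tp_y + spec.post_fraction * d_fptp
    y_ant = fp_y - spec.ant_fraction * d_fptp

    z_bot = float(an.brain_inferior_extreme[2])
    z_top = float(an.brain_superior_extreme[2])
    z_inf = z_bot + spec.inf_fraction * (z_top - z_bot)

    centers = gm.voxel_centers(member_only=False).reshape(*gm.data.shape, 3)
    keep = (
        gm.data
        & (centers[..., 0] < 0)
        & (centers[..., 1] >= y_post)
        & (centers[..., 1] <= y_ant)
        & (centers[..., 2] >= z_inf)
    )
    if not keep.any():
        raise ValueError("L-DLPFC mask is empty for this head/spec")
    return RoiMask(data=keep, affine=gm.affine.copy(), voxel_size=gm.voxel_size)
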