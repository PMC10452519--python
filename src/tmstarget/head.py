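"""Synthetic head models and cohorts.

The study population is an adolescent depression cohort treated with
high-frequency rTMS over the left dorsolateral prefrontal cortex
(L-DLPFC).  Real participants are represented here by parameterized
spherical head models: a scalp sphere with EEG-style landmarks, a motor
hotspot, corpus-callosum-style anatomical landmark points, and a
gray-matter shell voxelized on a regular RAS grid.  Per-subject motor
thresholds (in Standard Motor Threshold units, treatment delivered at
120% SMT) and depression-score changes (CDRS-R) are generated with a
configurable linear dependence on the delivered E-field dose.

Geometry is self-similar across head sizes, so inter-subject variability
that in real heads comes from skull/brain shape is emulated by three
explicit jitters: tangential jitter of the motor hotspot, independent
jitter of each anatomical landmark, and a small rigid rotation of the
scalp-landmark frame (nasion/inion/ears/vertex) relative to the
anatomy.  The frame rotation is what decouples scalp-measurement-based
targeting (5 cm rule, F3) from the anatomy-defined target and mask,
mirroring the scalp-measurement-to-anatomy variability of real heads;
its default magnitude is chosen so the between-subject dispersion of the
scalp-method doses is large relative to the anatomy-guided method, the
dispersion pattern reported for real adolescent cohorts.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import stats

from .geometry import make_sphere_mesh, rotate_about_axis, tangent_basis, unit

__all__ = [
    "GmGrid",
    "LandmarkSet",
    "AnatomyDescriptor",
    "HeadModel",
    "SubjectRecord",
    "CohortSpec",
    "make_head",
    "make_cohort",
    "assign_clinical_outcome",
    "noise_sd_for_target_r",
    "simulate_dose_response_cohort",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "save_head_surface",
    "save_gm_grid_nifti",
]

# Default direction of the left "hand knob" motor hotspot on the scalp
# (left hemisphere, slightly posterior and superior), before jitter.
HAND_KNOB_DIRECTION = unit(np.array([-0.42, -0.25, 0.873]))

# Anatomy landmark positions as fractions of the scalp radius R (corpus
# callosum points, superior frontal sulcus proxy) or of the brain radius
# R_b = R - cortex_offset (poles and extremes).  Chosen so that the
# anatomically constructed DLPFC scalp target lands in the left frontal
# scalp region and scales with head size.
_ANATOMY_FRACTIONS_R = {
    "cc_rostrum_inferior": (0.0, 0.24, -0.02),
    "cc_splenium_inferior": (0.0, -0.32, -0.02),
    "cc_genu_anterior": (0.0, 0.35, 0.02),
    "sfs_deep_point": (-0.26, 0.46, 0.27),
}
_ANATOMY_FRACTIONS_RB = {
    "frontal_pole": (0.0, 1.0, 0.0),
    "temporal_pole_left": (-0.55, 0.62, -0.35),
    # inferior reference for the mask's axial cut: most inferior point of
    # the temporal lobe (not the brain bottom), per the mask construction
    "brain_inferior_extreme": (-0.4, 0.1, -0.5),
    "brain_superior_extreme": (0.0, 0.0, 1.0),
}


@dataclass
class GmGrid:
    """Binary gray-matter membership on a regular voxel grid.

    ``affine`` maps voxel indices (i, j, k, 1) to RAS millimetres; voxel
    centres are at integer indices.
    """

    data: np.ndarray
    affine: np.ndarray
    voxel_size: float

    def voxel_centers(self, member_only: bool = True) -> np.ndarray:
        idx = np.argwhere(self.data) if member_only else np.argwhere(np.ones_like(self.data))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class LandmarkSet:
    nasion: np.ndarray
    inion: np.ndarray
    lpa: np.ndarray
    rpa: np.ndarray
    vertex: np.ndarray
    motor_hotspot: np.ndarray
    nasion_inion_arc: float
    tragus_tragus_arc: float
    circumference: float


@dataclass
class AnatomyDescriptor:
    cc_rostrum_inferior: np.ndarray
    cc_splenium_inferior: np.ndarray
    cc_genu_anterior: np.ndarray
    sfs_deep_point: np.ndarray
    frontal_pole: np.ndarray
    temporal_pole_left: np.ndarray
    brain_inferior_extreme: np.ndarray
    brain_superior_extreme: np.ndarray

    def points(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


@dataclass
class HeadModel:
    scalp_radius: float
    scalp_surface: trimesh.Trimesh
    cortex_offset: float
    gm_thickness: float
    gm_grid: GmGrid
    landmarks: LandmarkSet
    anatomy: AnatomyDescriptor
    conductivity: float = 0.33  # S/m, homogeneous volume conductor

    @property
    def brain_radius(self) -> float:
        """Outer radius of the gray-matter shell."""
        return self.scalp_radius - self.cortex_offset


@dataclass
class JitterSpec:
    hotspot_sd: float = 0.0
    anatomy_sd: float = 0.0
    rotation_deg_sd: float = 0.0


@dataclass
class SubjectRecord:
    subject_id: int
    head: HeadModel
    smt: float
    cdrs_baseline: float
    cdrs_change: float | None = None
    completed: bool = True
    dropout: bool = False

    @property
    def treatment_intensity(self) -> float:
        """Treatment dose in SMT units (120% of motor threshold)."""
        return 1.2 * self.smt


@dataclass
class CohortSpec:
    """Generation parameters for a synthetic cohort.

    Defaults emulate a small adolescent rTMS cohort: ten subjects, scalp
    radius 85 +/- 3.5 mm, motor threshold 1.0 +/- 0.13 SMT (both truncated
    normal), and a negative linear dose-response of the CDRS-R change on
    the delivered median E-field.  The jitter magnitudes are calibrated to
    the between-subject dispersion reported for real adolescent cohorts:
    anatomy-guided dose CV ~13% (motor-threshold spread), ROI-size CV ~4%
    (anatomy point jitter), and a scalp-method dose CV several times
    larger (measurement-frame rotation).  The default outcome noise SD of
    3.6 CDRS points corresponds to a population dose-response correlation
    near -0.77 at the ~22 V/m between-subject dose SD the default cohort
    produces (see ``noise_sd_for_target_r``).
    """

    n_subjects: int = 10
    radius_mean: float = 85.0
    radius_sd: float = 3.5
    smt_mean: float = 1.0
    smt_sd: float = 0.13
    hotspot_jitter_sd: float = 5.0
    anatomy_jitter_sd: float = 1.0
    rotation_jitter_deg: float = 15.0
    dose_response_slope: float = -0.2  # CDRS points per V/m
    dose_response_intercept: float = 0.0
    dose_response_noise_sd: float = 3.6
    cdrs_baseline_mean: float = 55.0
    cdrs_baseline_sd: float = 8.0
    include_dropout: bool = False
    dropout_smt: float = 1.54
    voxel_size: float = 2.0
    mesh_edge_mm: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        for name in (
            "radius_sd", "smt_sd", "hotspot_jitter_sd", "anatomy_jitter_sd",
            "rotation_jitter_deg", "dose_response_noise_sd", "cdrs_baseline_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        return cls(**json.loads(text))


def _truncnorm_rvs(mean, sd, lower, upper, rng, size=None):
    if sd == 0:
        return mean if size is None else np.full(size, float(mean))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_head(
    radius: float,
    mesh_density: float = 6.0,
    jitter_spec: JitterSpec | None = None,
    seed: int = 0,
    cortex_offset: float = 13.0,
    gm_thickness: float = 15.0,
    voxel_size: float = 2.0,
    hotspot_direction: np.ndarray = HAND_KNOB_DIRECTION,
) -> HeadModel:
    """Build one synthetic head model.

    Parameters
    ----------
    radius:
        Scalp sphere radius in mm; must lie in [70, 100].
    mesh_density:
        Target scalp triangle edge length in mm.
    jitter_spec:
        Per-subject variability: tangential hotspot jitter (mm SD),
        anatomy point jitter (mm SD) and rigid anatomy rotation (deg SD).
    seed:
        Seeds all jitter draws; the same seed reproduces the head
        bit-identically.
    cortex_offset, gm_thickness:
        Scalp-to-gray-matter depth and gray-matter shell thickness (mm).
        The default 13 mm offset stands in for scalp + skull + CSF.
    voxel_size:
        Gray-matter grid resolution in mm.
    """
    if not (70.0 <= radius <= 100.0):
        raise ValueError("radius must be in [70, 100] mm")
    if mesh_density <= 0 or voxel_size <= 0:
        raise ValueError("mesh_density and voxel_size must be positive")
    if cortex_offset <= 0 or gm_thickness <= 0 or cortex_offset + gm_thickness >= radius:
        raise ValueError("invalid cortical shell parameters")

    jit = jitter_spec or JitterSpec()
    rng = np.random.default_rng(seed)

    mesh = make_sphere_mesh(radius, mesh_density)

    # --- landmarks on the generating sphere (RAS, origin at centre);
    # the whole measurement frame may be rotated slightly w.r.t. anatomy
    nasion = np.array([0.0, radius, 0.0])
    inion = np.array([0.0, -radius, 0.0])
    lpa = np.array([-radius, 0.0, 0.0])
    rpa = np.array([radius, 0.0, 0.0])
    vertex = np.array([0.0, 0.0, radius])
    if jit.rotation_deg_sd > 0:
        axis = unit(rng.normal(size=3))
        ang = np.deg2rad(rng.normal(0.0, jit.rotation_deg_sd))
        nasion, inion, lpa, rpa, vertex = (
            rotate_about_axis(p, axis, ang) for p in (nasion, inion, lpa, rpa, vertex)
        )

    hotspot_dir = unit(np.asarray(hotspot_direction, dtype=float))
    if jit.hotspot_sd > 0:
        t1, t2 = tangent_basis(hotspot_dir)
        off = rng.normal(0.0, jit.hotspot_sd, size=2)
        hotspot_dir = unit(radius * hotspot_dir + off[0] * t1 + off[1] * t2)
    motor_hotspot = radius * hotspot_dir
    if motor_hotspot[0] >= 0:
        raise RuntimeError("motor hotspot left the left hemisphere; reduce jitter")

    landmarks = LandmarkSet(
        nasion=nasion, inion=inion, lpa=lpa, rpa=rpa, vertex=vertex,
        motor_hotspot=motor_hotspot,
        nasion_inion_arc=np.pi * radius,
        tragus_tragus_arc=np.pi * radius,
        circumference=2 * np.pi * radius,
    )

    # --- anatomy landmark points
    r_b = radius - cortex_offset
    pts = {k: radius * np.array(v) for k, v in _ANATOMY_FRACTIONS_R.items()}
    pts.update({k: r_b * np.array(v) for k, v in _ANATOMY_FRACTIONS_RB.items()})
    if jit.anatomy_sd > 0:
        pts = {k: v + rng.normal(0.0, jit.anatomy_sd, size=3) for k, v in pts.items()}
    anatomy = AnatomyDescriptor(**pts)

    # --- gray-matter shell on a regular voxel grid
    outer, inner = r_b, radius - cortex_offset - gm_thickness
    half = int(np.floor(outer / voxel_size))
    coords = np.arange(-half, half + 1) * voxel_size
    gx, gy, gz = np.meshgrid(coords, coords, coords, indexing="ij")
    rr = np.sqrt(gx**2 + gy**2 + gz**2)
    data = (rr <= outer) & (rr >= inner)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
    affine[:3, 3] = -half * voxel_size
    gm = GmGrid(data=data, affine=affine, voxel_size=voxel_size)

    return HeadModel(
        scalp_radius=radius,
        scalp_surface=mesh,
        cortex_offset=cortex_offset,
        gm_thickness=gm_thickness,
        gm_grid=gm,
        landmarks=landmarks,
        anatomy=anatomy,
    )


def make_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a cohort of synthetic subjects from ``spec``.

    Radii and motor thresholds come from normal distributions truncated at
    +/-3 SD and at physical lower bounds (radius >= 70 mm, SMT >= 0.3).
    CDRS-R baselines are truncated below at the study inclusion threshold
    of 40.  If ``include_dropout`` is set, the last subject's motor
    threshold is forced to ``dropout_smt`` and the subject is flagged as a
    non-completer, mimicking a dropout driven by intolerably high
    treatment intensity.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    radii = _truncnorm_rvs(
        spec.radius_mean, spec.radius_sd,
        max(70.0, spec.radius_mean - 3 * spec.radius_sd),
        min(100.0, spec.radius_mean + 3 * spec.radius_sd),
        rng, size=spec.n_subjects,
    )
    smts = _truncnorm_rvs(
        spec.smt_mean, spec.smt_sd,
        max(0.3, spec.smt_mean - 3 * spec.smt_sd),
        spec.smt_mean + 3 * spec.smt_sd,
        rng, size=spec.n_subjects,
    )
    baselines = _truncnorm_rvs(
        spec.cdrs_baseline_mean, spec.cdrs_baseline_sd,
        40.0, spec.cdrs_baseline_mean + 3 * spec.cdrs_baseline_sd,
        rng, size=spec.n_subjects,
    )

    jit = JitterSpec(
        hotspot_sd=spec.hotspot_jitter_sd,
        anatomy_sd=spec.anatomy_jitter_sd,
        rotation_deg_sd=spec.rotation_jitter_deg,
    )
    subjects = []
    head_seeds = rng.integers(0, 2**31 - 1, size=spec.n_subjects)
    for i in range(spec.n_subjects):
        head = make_head(
            float(radii[i]), mesh_density=spec.mesh_edge_mm, jitter_spec=jit,
            seed=int(head_seeds[i]), voxel_size=spec.voxel_size,
        )
        subjects.append(
            SubjectRecord(
                subject_id=i, head=head, smt=float(smts[i]),
                cdrs_baseline=float(baselines[i]),
            )
        )
    if spec.include_dropout:
        subjects[-1].smt = spec.dropout_smt
        subjects[-1].completed = False
        subjects[-1].dropout = True
    return subjects


def assign_clinical_outcome(
    subject: SubjectRecord,
    median_efield: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> float:
    """Assign a CDRS-R change from the delivered dose.

    change = intercept + slope * E + N(0, noise_sd); a negative change is
    symptom improvement, so the default slope is negative.
    """
    if median_efield < 0:
        raise ValueError("median_efield must be >= 0")
    noise = rng.normal(0.0, spec.dose_response_noise_sd) if spec.dose_response_noise_sd > 0 else 0.0
    change = spec.dose_response_intercept + spec.dose_response_slope * median_efield + noise
    subject.cdrs_change = float(change)
    return subject.cdrs_change


def noise_sd_for_target_r(slope: float, dose_sd: float, target_r: float) -> float:
    """Noise SD making the population dose-response Pearson r equal ``target_r``.

    For change = a + b*E + eps, r = b*sd_E / sqrt(b^2 sd_E^2 + sd_eps^2),
    hence sd_eps = |b| sd_E sqrt(1/r^2 - 1).
    """
    if not (0 < abs(target_r) < 1):
        raise ValueError("target_r must be in (0, 1) in magnitude")
    return abs(slope) * dose_sd * np.sqrt(1.0 / target_r**2 - 1.0)


def simulate_dose_response_cohort(
    n: int,
    dose_mean: float,
    dose_sd: float,
    target_r: float,
    slope: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (doses, CDRS changes) for ``n`` completers at a programmed
    population correlation ``target_r`` (sign taken from ``slope``)."""
    doses = rng.normal(dose_mean, dose_sd, size=n)
    noise_sd = noise_sd_for_target_r(slope, dose_sd, target_r)
    changes = slope * doses + rng.normal(0.0, noise_sd, size=n)
    return doses, changes


# ---------------------------------------------------------------------------
# I/O

_COHORT_COLUMNS = [
    "subject_id", "scalp_radius_mm", "smt", "treatment_intensity_smt",
    "cdrs_baseline", "cdrs_change", "completed",
]


def cohort_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "scalp_radius_mm": s.head.scalp_radius,
            "smt": s.smt,
            "treatment_intensity_smt": s.treatment_intensity,
            "cdrs_baseline": s.cdrs_baseline,
            "cdrs_change": np.nan if s.cdrs_change is None else s.cdrs_change,
            "completed": s.completed,
        }
        for s in subjects
    ]
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def write_cohort_csv(subjects: list[SubjectRecord], path_or_buf) -> None:
    cohort_to_frame(subjects).to_csv(path_or_buf, index=False, float_format="%.6f")


def read_cohort_csv(path_or_buf) -> pd.DataFrame:
    if isinstance(path_or_buf, str) or hasattr(path_or_buf, "read"):
        return pd.read_csv(path_or_buf)
    return pd.read_csv(io.StringIO(str(path_or_buf)))


def save_head_surface(head: HeadModel, path: str) -> None:
    """Write the scalp triangulation as an OBJ mesh."""
    head.scalp_surface.export(path)


def save_gm_grid_nifti(grid: GmGrid, path: str) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(grid.data.astype(np.uint8), grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
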