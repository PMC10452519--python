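"""End-to-end four-method comparison on a synthetic cohort.

For each subject: build the head, construct the L-DLPFC mask, derive the
four coil placements (5 cm rule, F3, anatomical DST — each at the
standard 45-degree orientation — and the E-field-optimized placement),
simulate the field at the subject's treatment dI/dt, extract the median
mask dose and the field-maximum location, assign the clinical outcome
from the delivered (DST) dose, and finally run the statistical battery.
Reruns with the same configuration are bit-identical; outputs are listed
in a manifest with content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationResult,
    CalibrationSpec,
    calibrate_coil,
    e_ref_at_depth,
    smt_to_didt,
    subject_didt,
)
from .coil import Placement, default_coil
from .efield import SphereConductor, efield_total, field_on_grid, normal_component
from .head import CohortSpec, SubjectRecord, assign_clinical_outcome, make_cohort
from .optimizer import OptimizationResult, field_maximum_location, optimize_placement
from .stats import METHODS, StatsReport, median_roi_dose, run_stats_battery
from .targeting import (
    MaskSpec,
    RoiMask,
    ScalpPoint,
    build_dlpfc_mask,
    dbt_construct,
    five_cm_target,
    scalp_project,
    scalp_point,
    ten_twenty_positions,
)

logger = logging.getLogger("tmstarget")

__all__ = ["RunConfig", "SubjectResult", "CohortResult", "run_comparison", "write_outputs"]


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    mask: MaskSpec = field(default_factory=MaskSpec)
    n_dipoles: int = 60
    hair_offset: float = 4.0
    search_extent: float = 30.0
    paper_scale: bool = False  # 1 mm / 4 deg search instead of 5 mm / 30 deg
    spacing: float | None = None
    angle_step: float | None = None
    compute_motor: bool = True
    compute_normal: bool = True
    methods: tuple = tuple(METHODS)

    def grid_params(self) -> tuple[float, float]:
        if self.spacing is not None and self.angle_step is not None:
            return self.spacing, self.angle_step
        return (1.0, 4.0) if self.paper_scale else (5.0, 30.0)


@dataclass
class SubjectResult:
    subject: SubjectRecord
    mask: RoiMask
    placements: dict[str, Placement]
    doses: dict[str, float]
    max_distances: dict[str, float]
    optimization: OptimizationResult
    motor_max: float | None = None
    normal_dose: float | None = None


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    dose_table: pd.DataFrame
    stats: StatsReport | None
    calibration: CalibrationResult
    config: RunConfig

    @property
    def n_enrolled(self) -> int:
        return len(self.subjects)

    @property
    def n_field_analysis(self) -> int:
        return int((~self.dose_table["dropout"]).sum())

    @property
    def n_correlation(self) -> int:
        return int(self.dose_table["completed"].sum())


def _standard_placements(head, hair_offset: float) -> dict[str, Placement]:
    hotspot = scalp_point(head, head.landmarks.motor_hotspot)
    p5 = five_cm_target(head, hotspot)
    f3 = ten_twenty_positions(head)["F3"]
    dst = scalp_project(dbt_construct(head).center, head)
    return {
        "5cm": Placement(scalp_point=p5, hair_offset=hair_offset),
        "F3": Placement(scalp_point=f3, hair_offset=hair_offset),
        "DST": Placement(scalp_point=dst, hair_offset=hair_offset),
        "hotspot": Placement(scalp_point=hotspot, hair_offset=hair_offset),
    }


def run_comparison(config: RunConfig | None = None) -> CohortResult:
    """Run the full four-method comparison; see the module docstring."""
    config = config or RunConfig()
    t0 = time.time()
    spacing, angle_step = config.grid_params()
    logger.info("cohort spec: %s", config.cohort)

    cal_sphere = SphereConductor(radius=85.0)
    coil = calibrate_coil(default_coil(n_dipoles=config.n_dipoles), cal_sphere, config.calibration)
    e_ref = e_ref_at_depth(coil, cal_sphere, config.calibration)
    cal = smt_to_didt(dataclasses.replace(config.calibration, e_ref=e_ref))
    logger.info("calibrated dI/dt per SMT: %.4g A/us", cal.didt_per_smt_a_per_us)

    subjects = make_cohort(config.cohort)
    outcome_rng = np.random.default_rng(np.random.SeedSequence([config.cohort.seed, 7]))

    results: list[SubjectResult] = []
    for rec in subjects:
        ts = time.time()
        head = rec.head
        sphere = SphereConductor(radius=head.scalp_radius)
        mask = build_dlpfc_mask(head, config.mask)
        placements = _standard_placements(head, config.hair_offset)
        didt_treat = subject_didt(rec, cal, treatment=True)

        opt = optimize_placement(
            head, mask, coil, sphere, didt_treat,
            extent=config.search_extent, spacing=spacing, angle_step=angle_step,
            hair_offset=config.hair_offset,
        )
        placements["OPT"] = opt.best

        doses, max_dist = {}, {}
        centroid = mask.centroid
        for name in config.methods:
            vol = field_on_grid(coil, placements[name], sphere, head.gm_grid, didt_treat)
            doses[name] = median_roi_dose(vol, mask)
            peak, _ = field_maximum_location(vol, head.gm_grid)
            max_dist[name] = float(np.linalg.norm(peak - centroid))

        motor_max = None
        if config.compute_motor:
            vol = field_on_grid(
                coil, placements["hotspot"], sphere, head.gm_grid,
                subject_didt(rec, cal, treatment=False),
            )
            motor_max = float(vol.max())

        normal_dose = None
        if config.compute_normal:
            pts = mask.voxel_centers
            res = efield_total(coil, placements["DST"], sphere, pts, didt_treat)
            normal_dose = float(np.median(normal_component(res, pts)))  # radial outward normals

        assign_clinical_outcome(rec, doses["DST"], config.cohort, outcome_rng)
        results.append(
            SubjectResult(
                subject=rec, mask=mask, placements=placements, doses=doses,
                max_distances=max_dist, optimization=opt,
                motor_max=motor_max, normal_dose=normal_dose,
            )
        )
        logger.info("subject %d done in %.1f s", rec.subject_id, time.time() - ts)

    rows = []
    for r in results:
        rows.append(
            {
                "subject_id": r.subject.subject_id,
                **{m: r.doses[m] for m in config.methods},
                **{f"maxdist_{m}": r.max_distances[m] for m in config.methods},
                "smt": r.subject.smt,
                "treatment_intensity": r.subject.treatment_intensity,
                "cdrs_change": r.subject.cdrs_change,
                "completed": r.subject.completed,
                "dropout": getattr(r.subject, "dropout", False),
                "motor_max": r.motor_max,
                "normal_dose": r.normal_dose,
            }
        )
    table = pd.DataFrame(rows)

    analysis = table[~table["dropout"]]
    completers = table[table["completed"]]
    stats_report = None
    if len(analysis) >= 2:
        dose_response = None
        if len(completers) >= 3:
            dose_response = (
                completers["DST"].to_numpy(), completers["cdrs_change"].to_numpy()
            )
        # On the spherical conductor the total field is exactly tangential,
        # so the outward normal component (and hence its dose-response
        # correlation) is degenerate whenever the cortical normals are
        # radial; report it only when it carries variance.
        normal_response = None
        if config.compute_normal and len(completers) >= 3:
            nd = completers["normal_dose"].to_numpy(dtype=float)
            if np.std(nd) > 0:
                normal_response = (nd, completers["cdrs_change"].to_numpy())
            else:
                logger.info("normal-component dose has zero variance; correlation skipped")
        motor_summary = None
        if config.compute_motor:
            mm = analysis["motor_max"].to_numpy(dtype=float)
            motor_summary = (float(mm.mean()), float(mm.std(ddof=1)), len(mm),
                             config.calibration.e_target)
        stats_report = run_stats_battery(
            analysis, methods=list(config.methods),
            dose_response=dose_response, normal_response=normal_response,
            motor_summary=motor_summary,
        )
    logger.info("cohort done in %.1f s", time.time() - t0)
    return CohortResult(
        subjects=results, dose_table=table, stats=stats_report,
        calibration=cal, config=config,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: CohortResult, out_dir: str | Path) -> dict:
    """Write the dose table, stats report, placements and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.dose_table.to_csv(out / "doses.csv", index=False, float_format="%.6f")
    if result.stats is not None:
        (out / "stats.json").write_text(json.dumps(result.stats.to_dict(), indent=2))
    placements = {
        str(r.subject.subject_id): {m: p.to_dict() for m, p in r.placements.items()}
        for r in result.subjects
    }
    (out / "placements.json").write_text(json.dumps(placements, indent=2))
    manifest = {
        "seed": result.config.cohort.seed,
        "didt_per_smt_a_per_us": result.calibration.didt_per_smt_a_per_us,
        "n_enrolled": result.n_enrolled,
        "n_field_analysis": result.n_field_analysis,
        "n_correlation": result.n_correlation,
        "files": {
            p.name: _sha256(p) for p in sorted(out.glob("*")) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
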