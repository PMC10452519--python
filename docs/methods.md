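# Methods

## Problem and model

The package compares four strategies for placing a TMS figure-eight
coil over the left dorsolateral prefrontal cortex (L-DLPFC) by the
electric field each strategy delivers to an anatomically defined target
mask. All dosimetry runs on a homogeneous spherical volume conductor —
the same idealization used for device calibration — with synthetic
subjects standing in for participant MRIs.

### Volume conductor and field solution

In the quasi-static regime the induced field is
`E = -∂A/∂t - ∇φ`: a primary term from the coil's vector potential and
a secondary term from charge accumulating where conductivity changes
(here, only the scalp boundary). Each coil wing is a uniform
magnetic-dipole sheet (exactly equivalent to its circulating current),
sampled by a Gauss–Legendre-in-radius quadrature; 60 dipoles per wing
reproduce the reference field to ~0.05% and successive refinements
change it by well under 0.5%.

For a magnetic dipole outside a homogeneous sphere the total interior
field has an exact closed form: by electromagnetic reciprocity it is
the transpose of the Sarvas magnetometer lead field. We evaluate that
closed form directly rather than a truncated spherical-harmonic
expansion — it is the infinite-order limit of such an expansion, needs
no truncation parameter, and is cheap enough for exhaustive placement
searches. The solution inherits, exactly: zero field at the sphere
centre, a purely tangential field, linearity in dI/dt, and independence
from the conductivity value and sphere radius. These properties are
asserted in tests, and the solution is cross-validated against an
independent boundary-element oracle: a single-layer surface charge
solved by collocation on an icosphere (diagonal via the closed-surface
solid-angle identity, constant nullspace deflated by a zero-total-charge
constraint). At 5120 faces the two solutions agree to <1% relative L2
over 1000 interior points; the oracle is used only for validation.

A consequence of the spherical geometry worth noting: with radial
cortical normals the *normal component* E·n̂ vanishes identically, so
the normal-component dose-response correlation is degenerate and the
pipeline reports it only when it carries variance. The multi-tissue
conductivity set (skin/skull/CSF/gray/white/eyes) is stored as
configuration for future layered models but unused by the homogeneous
solver.

### Device calibration (SMT units)

The stimulator's output unit is the Standard Motor Threshold: 1 SMT
induces 135 V/m at 2 cm depth along the coil axis. Driving the coil
model time-harmonically at I₀ = 1 A, ω₀ = 2π·5 kHz (so dI/dt = ω₀I₀)
yields a reference field E'_2cm, and

    dI/dt per SMT = 135 V/m · ω₀ I₀ / E'_2cm.

The real treatment coil has a proprietary ferromagnetic-core winding;
the package's air-core figure-eight (wings of radius 35 mm, centres
40 mm apart, coplanar, opposite polarity — configurable assumptions) is
therefore rescaled once so its computed E'_2cm equals the device-analog
reference 0.066 V/m. With the printed, rounded reference the conversion
gives 64.26 A/µs versus the device sheet's 64.67 A/µs computed from
unrounded inputs; agreement within 1% is treated as closure, while the
internal round trip (calibrate, convert, re-simulate) closes to <0.1%
by construction. Treatment simulations run at 120% of the subject's
motor threshold; motor-hotspot simulations at 100%.

### Targeting constructions

* **5 cm rule** — geodesic advance of 50 mm anterior of the motor
  hotspot within the parasagittal section of the scalp (a straight-chord
  variant is available behind a flag; the geodesic is the documented
  default, since tape measurements follow the scalp).
* **10-20 / F3** — the constructive chain on the scalp surface: Cz at
  the crossing of the 50% nasion-inion and ear-to-ear arcs, Fz/Fpz/Oz at
  30%/10%/90% of the sagittal arc, a circumferential ring through Fpz
  and Oz with F7 at 15% of the ring, and F3 as the geodesic midpoint of
  the F7–Fz arc. This head-size-scaling construction stands in for the
  measurement-regression variant, which could be added behind the same
  interface.
* **Anatomical target (DBT→DST)** — the inferior corpus-callosum plane
  through the rostrum/splenium inferior margins; a 20 mm coronal-oblique
  slab perpendicular to it, centred 10 mm anterior of the genu; the deep
  superior-frontal-sulcus point constrained to the slab (clamped and
  flagged if outside). The cube centre is projected along the shortest
  straight path to the scalp — radial for a sphere, with a mesh
  brute-force cross-check; the projection of the sphere centre is the
  one degenerate tie, broken deterministically and flagged. Projection
  happens after slab clamping (averaged-then-projected).
* **L-DLPFC mask** — left-hemisphere gray-matter voxels (voxel-centre
  convention) between two coronal planes at 20%/40% of the frontal-to-
  temporal-pole distance and above the axial plane at 50% of the
  temporal-lobe-bottom to brain-top distance. Planes are perpendicular
  to the head-frame axes, matching the template-space definition of the
  mask. On default heads the mask's equivalent radius is ~12.5 mm,
  checked against a 9–15 mm plausibility band around the ~11.4 mm ROI
  radius reported for registered template masks.
* **Optimized placement** — exhaustive search on a geodesic disc of
  scalp positions (default extent 30 mm; the study's search extent is
  not documented, so it is configurable) crossed with coil orientations,
  maximizing the mean |E| over gray-matter voxels within 20 mm of the
  scalp-projected mask centroid. For the symmetric coil the |E|
  objective is invariant under 180° flips, so only a half circle of
  orientations is enumerated by default (verified, results unchanged).
  Orientation is measured from the tangent-plane direction toward the
  sagittal midline to the coil's primary-current axis; 45° is the
  standard clinical pose; hair offset 4 mm.

## Synthetic cohort

Each subject is a sphere of radius ~N(85, 3.5²) mm truncated at ±3 SD
(adolescent head sizes are not tabulated in the source study; the range
is configurable and labeled an assumption), with a gray-matter shell
from 13 mm (scalp+skull+CSF stand-in) to 28 mm depth voxelized at 2 mm,
landmarks at canonical positions, and anatomy points at fixed fractions
of head size. Between-subject variability enters through four explicit,
seeded jitters, calibrated to the dispersion statistics reported for a
real adolescent cohort and then frozen:

| parameter | default | anchor |
| --- | --- | --- |
| motor threshold SD | 0.13 SMT | anatomy-guided dose CV ≈ 13% |
| anatomy point jitter | 1 mm | ROI radius 11.4 ± 0.48 mm (CV ≈ 4%) |
| scalp-measurement frame rotation | 15° SD | scalp-method dose CV ≫ anatomy-guided CV |
| hotspot tangential jitter | 5 mm | physiological hotspot variability |

The frame rotation rotates the cardinal scalp landmarks
(nasion/inion/ears/vertex) — hence everything built from scalp
measurements — relative to the anatomy and its mask. It is the model's
proxy for the head-shape (cranial-index) and measurement variability
that in real cohorts makes the F3 method accurate on average but
imprecise across individuals. A perfect sphere understates this
mechanism: the reported scalp-method CV of ~40% is not reachable with
plausible jitters (we obtain ~27%), but the variance *ordering* — F3
most variable, anatomy-guided and optimized methods least — is
reproduced, and only orderings are asserted. Clinical outcome is linear
in the delivered (anatomical-target) dose,
`ΔCDRS = a + b·E + ε`, with defaults (b = −0.2 CDRS/(V/m),
σ_ε = 3.6) placing the population dose-response correlation near −0.77
via `r = b·σ_E / √(b²σ_E² + σ_ε²)`. One subject can be flagged as a
high-threshold (1.54 SMT) dropout; the pipeline then excludes them from
the field analysis and non-completers from the correlation, mirroring
the study's exclusion path.

What passing cohort tests show — and what they do not: the synthetic
cohorts exercise the full code path (targeting, dosimetry, extraction,
statistics) under the dispersion structure the study reports, so they
validate the machinery and the qualitative findings (ordering,
concordance, variance pattern, field-maximum geography). They do not
reproduce gyral focality, tissue heterogeneity, or the absolute group
numbers of the real cohort, which depend on participant MRIs.

## Numerical and design choices

* Units: mm for geometry, V/m for fields, A/s for dI/dt (printed as
  A/µs where the field does); conversions centralized at the solver
  boundary.
* Geodesics use exact great-circle formulas (the scalp is an analytic
  sphere); a Dijkstra edge-path fallback exists for general meshes.
* Field-to-voxel transfer: the solver evaluates at voxel centres
  directly; trilinear interpolation is provided for volumes on foreign
  grids.
* Wilcoxon signed-rank: zero differences dropped, exact null for n ≤ 25
  without ties, normal approximation with continuity correction
  otherwise; Holm step-down for the six pairwise comparisons; all tests
  two-sided.
* Dose-response analyses use completers only, at treatment intensity.
* Optimizer ties broken by enumeration order (rings outward,
  orientations ascending); field-maximum ties by smallest linear voxel
  index, flagged.
* Determinism: every stochastic step draws from a generator seeded from
  the cohort seed; reruns are bit-identical and outputs carry a hashed
  manifest.

### Problem sizes

Defaults target desk-scale runs: 2 mm voxel grids and 60 dipoles per
wing for single-subject work; cohort studies in the test suite use 3 mm
grids, 24 dipoles per wing, and the reduced 5 mm / 30° search grid
(the study-scale 1 mm / 4° grid runs through the same code path via
`paper_scale`). The boundary-element oracle uses a 5120-face icosphere
for the headline validation and coarser meshes elsewhere.

## Known limitations

Spherical heads have no cortical folding, so field maxima sit directly
under the coil and the normal-component metric degenerates; tissue is
homogeneous (the layered-sphere extension is an explicit non-goal
hook); conductivity is age-independent; the coil winding is an air-core
assumption calibrated to the device's reference output rather than a
geometric model of the ferromagnetic core. Because the synthetic
gray-matter shell starts only 13 mm below the scalp, the maximum |E|
over gray matter at motor threshold (~150–200 V/m) exceeds the 135 V/m
reference defined at 20 mm depth; the pipeline's motor-cortex t check
reflects this geometry, unlike in real heads where the hand knob sits
near the reference depth.
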