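# tmstarget

Coil-placement targeting and electric-field dosimetry for repetitive
transcranial magnetic stimulation (rTMS) of the left dorsolateral
prefrontal cortex (L-DLPFC), on parameterized spherical head models.

rTMS of the L-DLPFC is a treatment for depression, including
treatment-resistant depression in adolescents. In the clinic the coil is
placed by one of several rules — the **5 cm rule** (5 cm anterior of the
motor hotspot along the parasagittal scalp), the **Beam F3 / EEG 10-20**
position, an **MRI-derived anatomical scalp target** (the DLPFC brain
target constructed from corpus-callosum geometry, projected to the
scalp), or a **computational optimum** that maximizes the induced
E-field in the target. Because the induced field falls off quickly with
distance from the coil, these rules deliver very different doses, and
scalp-measurement rules scale poorly across the wide head-size range of
adolescents. This package implements all four strategies and the
dosimetry needed to compare them, for researchers studying TMS dose
delivery and targeting accuracy.

## What's inside

- `tmstarget.head` — synthetic subjects: spherical scalp with EEG
  landmarks, motor hotspot, corpus-callosum-style anatomy, a voxelized
  gray-matter shell, motor thresholds in Standard Motor Threshold (SMT)
  units and dose-dependent clinical outcomes (CDRS-R change).
- `tmstarget.targeting` — the 5 cm rule, the constructive 10-20 chain
  (Cz, Fz, F7, F3, ...), the anatomical DLPFC brain/scalp target, and
  the L-DLPFC gray-matter mask built from fractional pole distances.
- `tmstarget.efield` — quasi-static E-field of a dipole-discretized
  figure-eight coil in a homogeneous spherical conductor. The total
  field (primary `-dA/dt` plus the secondary field of the surface
  charge) is evaluated with the exact closed form obtained by
  reciprocity from the Sarvas magnetometer lead field:

      E(r) = -dI/dt · μ₀/(4πF²) [ F (r × w) − (r × r₀)(∇F · w) ],

  with `F = a(r₀a + r₀² − r·r₀)`, `a = r₀ − r`, for each dipole of
  moment-per-current `w` at `r₀`. An independent boundary-element
  solution (single-layer surface charge) serves as a numerical oracle.
- `tmstarget.calibration` — SMT-unit calibration: 1 SMT is the output
  inducing 135 V/m at 2 cm depth, so
  `dI/dt per SMT = E_target · ω₀ I₀ / E'_2cm`; with the device-analog
  reference `E'_2cm = 0.066 V/m` this gives 64.26 A/µs.
- `tmstarget.optimizer` — exhaustive search over scalp positions
  (geodesic disc) × orientations, maximizing the mean |E| within 20 mm
  of the scalp-projected mask centre.
- `tmstarget.stats` — median mask dose, Friedman test, pairwise
  Wilcoxon with Holm adjustment, Bartlett variance test, dose-response
  Pearson correlation, one-sample t from summary statistics.
- `tmstarget.pipeline` / CLI `tmstarget` — the end-to-end four-method
  comparison with a hashed output manifest.

## Worked example

```bash
python examples/02_calibrate_device.py
```

prints

```
printed-inputs conversion (E_ref = 0.066 V/m):
  dI/dt per SMT = 64.26 A/us (device sheet prints 64.67 from unrounded inputs)
computed reference field at 2 cm: 0.0660 V/m (calibrated to 0.066)
dI/dt per SMT from computed reference: 64.26 A/us
  |E| at   10 mm depth:  225.27 V/m
  |E| at   20 mm depth:  135.00 V/m  <- 1 SMT definition (135 V/m)
  |E| at   30 mm depth:   77.72 V/m
  |E| at   40 mm depth:   43.98 V/m
```

The first line converts the motor-threshold definition into a coil
current rate using the printed reference field; the depth profile shows
the calibrated coil reproducing exactly 135 V/m at the 2 cm reference
depth when driven at 1 SMT — the closed calibration loop.

`examples/01_build_head_and_targets.py` builds a head and shows the
targeting geometry (on the default 85 mm head the 5 cm rule lands
51 mm, F3 19 mm, from the anatomical scalp target);
`examples/03_field_solver_validation.py` cross-checks the closed-form
solver against the boundary-element oracle (0.4% relative L2 at a
coarse mesh); `examples/04_optimize_placement.py` runs the placement
search (~11% dose gain over the anatomical placement on the default
head); `examples/05_cohort_comparison.py` runs a small cohort through
the full comparison and the statistical battery.

The same stages are available as shell commands:

```bash
tmstarget calibrate
tmstarget run-all --out results/ --seed 1
```

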