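"""Build a synthetic head and compare where the targeting rules point.

Generates one 85 mm head with default jitters off, derives the motor
hotspot, the 5 cm-rule target, the 10-20 F3 position and the anatomical
DLPFC scalp target (DST), and prints their scalp geodesic separations.
The separations show why the scalp rules miss: the 5 cm rule lands far
posterior of the anatomical target, F3 much closer.
"""

import numpy as np

import tmstarget as tt
from tmstarget.geometry import sphere_geodesic

head = tt.make_head(85.0, seed=0)
R = head.scalp_radius

hotspot = head.landmarks.motor_hotspot
p5 = tt.five_cm_target(head)
f3 = tt.ten_twenty_positions(head)["F3"]
dbt = tt.dbt_construct(head)
dst = tt.scalp_project(dbt.center, head)
mask = tt.build_dlpfc_mask(head)

print(f"scalp radius               : {R:.1f} mm")
print(f"nasion-inion arc           : {head.landmarks.nasion_inion_arc:.1f} mm")
print(f"motor hotspot              : {np.round(hotspot, 1)}")
print(f"5 cm target                : {np.round(p5.position, 1)}")
print(f"F3 (10-20 chain)           : {np.round(f3.position, 1)}")
print(f"DLPFC brain target (DBT)   : {np.round(dbt.center, 1)}")
print(f"DLPFC scalp target (DST)   : {np.round(dst.position, 1)}")
print(f"L-DLPFC mask               : {mask.n_voxels} voxels, "
      f"equivalent radius {mask.equivalent_radius:.1f} mm")
print()
g = lambda a, b: sphere_geodesic(a, b, R)
print(f"geodesic 5cm -> DST        : {g(p5.position, dst.position):5.1f} mm")
print(f"geodesic F3  -> DST        : {g(f3.position, dst.position):5.1f} mm")
print("(the scalp-measurement rules sit farther from the anatomical target"
      " than the MRI-style construction; distances scale with head size)")
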