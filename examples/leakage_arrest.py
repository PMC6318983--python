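"""Leakage versus arrest at a hole in the image signal.

A plane with a circular hole cuts the volume in half.  A large balloon
inflates from below and attaches to the plane around the hole; over the
hole, the unsupported membrane bulges.  Whether it squeezes through
("leak") or stalls ("arrest") depends on the product of hole radius and
pressure — a surface-tension-like threshold.  The script runs one case on
each side of the frontier and reports the outcome.
"""

import numpy as np

from surfelseg import Params, SurfelSystem, plane_with_hole, sphere_seed
from surfelseg.integrator import step

def bulge_crosses(r_hole, f_pressure, max_steps=1300):
    img = plane_with_hole((100, 100, 100), r_hole=r_hole)
    system = SurfelSystem.from_surfels(
        sphere_seed((49.5, 49.5, 27), 22, 3.0),
        Params(d0=3.0, f_pressure=f_pressure, rng_seed=6),
    )
    for _ in range(max_steps):
        step(system, img)
        pos = system.positions
        rho = np.hypot(pos[:, 0] - 49.5, pos[:, 1] - 49.5)
        if np.any((pos[:, 2] > 62) & (rho < r_hole + 5)):
            return True, system.step_count
        if system.n_locked == len(system):
            break
    return False, system.step_count

for r_hole, fp in ((9.0, 0.01), (9.0, 0.025)):
    crossed, steps = bulge_crosses(r_hole, fp)
    verdict = "LEAKED through the hole" if crossed else "ARRESTED at the hole"
    print(f"r_hole={r_hole} px, f_pressure={fp}: {verdict} "
          f"(r x p = {r_hole*fp:.3f}, decided by step {steps})")
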