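"""Non-spherical seeding from planar ROIs, then coarse-to-fine refinement.

For elongated objects a sphere is a poor starting shape.  A *skeleton* seed
interpolates a few hand-drawn planar outlines into a generalized cylinder
of surfels.  Here three circular ROIs around a sphere shell initialise the
segmentation, a first run converges at d0 = 4, and the run is then resumed
at d0 = 2.5 (all surfels reactivated) to refine the attachment — the
workflow for recovering fine detail after a coarse first pass.
"""

import numpy as np

from surfelseg import (
    OrientedCloud, Params, SurfelSystem, rms_to_sphere, run,
    skeleton_seed, sphere_shell,
)

center, radius = (49.5, 49.5, 49.5), 22.0
img = sphere_shell((100, 100, 100), center, radius)

def circle(r, n=48):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([49.5 + r * np.cos(t), 49.5 + r * np.sin(t)])

# rough outlines around the target at three z slices (deliberately too wide)
rois = [(30.0, circle(18)), (49.5, circle(26)), (69.0, circle(18))]

params = Params(d0=4.0, f_pressure=-0.005, rng_seed=8)  # gentle deflation
system = SurfelSystem.from_surfels(skeleton_seed(rois, params.d0), params)
print(f"skeleton seed: {len(system)} surfels from {len(rois)} ROIs")

system, _ = run(system, img, max_steps=2500, log_every=0)
cloud = OrientedCloud.from_system(system)
print(f"coarse pass (d0=4):   {len(system)} surfels, "
      f"RMS to target {rms_to_sphere(cloud, center, radius):.2f} px")

system.params = Params(d0=2.5, f_pressure=-0.005, rng_seed=8)
system, _ = run(system, img, max_steps=2500, reset=True, log_every=0)
cloud = OrientedCloud.from_system(system)
print(f"refined pass (d0=2.5): {len(system)} surfels, "
      f"RMS to target {rms_to_sphere(cloud, center, radius):.2f} px")
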