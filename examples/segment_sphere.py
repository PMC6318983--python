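"""Segment a noiseless sphere shell from an interior spherical seed.

A 100^3 volume holds a bright spherical membrane (radius 30 px).  A small
seed balloon (radius 10) placed at the centre inflates under a positive
pressure until every surfel attaches to the shell and locks.  The printed
numbers: the RMS distance of the final cloud to the true sphere (sub-pixel
when the segmentation succeeded), and the enclosed volume / surface area
from the oriented cloud against their analytic values.
"""

import numpy as np

from surfelseg import (
    OrientedCloud, Params, SurfelSystem, export_ply, measure,
    rms_to_sphere, run, sphere_seed, sphere_shell,
)

center, radius = (49.5, 49.5, 49.5), 30.0
img = sphere_shell(size=(100, 100, 100), center=center, radius=radius)

params = Params(d0=3.0, f_pressure=0.01, rng_seed=1)
system = SurfelSystem.from_surfels(sphere_seed(center, 10, params.d0), params)
print(f"seeded {len(system)} surfels, inflating ...")

system, reports = run(system, img, max_steps=3500, log_every=500)
cloud = OrientedCloud.from_system(system)
m = measure(cloud, params.d0)

print(f"finished after {system.step_count} steps: "
      f"{len(system)} surfels, {system.n_locked} locked")
print(f"RMS distance to target sphere: {rms_to_sphere(cloud, center, radius):.2f} px")
print(f"volume:  {m.volume:,.0f} voxel^3  (4/3 pi R^3 = {4/3*np.pi*radius**3:,.0f})")
print(f"surface: {m.surface_area:,.0f} voxel^2  (4 pi R^2 = {4*np.pi*radius**2:,.0f})")
export_ply(cloud, "sphere_segmentation.ply")
print("oriented point cloud written to sphere_segmentation.ply")
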