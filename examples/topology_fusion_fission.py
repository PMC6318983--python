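"""Topology changes arise from the particle rules, not explicit surgery.

Fusion: a seed inside a torus tube inflates, grows around the ring, and the
two ends of the "C" merge — one connected surface.  Fission: a seed
enclosing two separate spheres deflates, necks down between them, and
pinches into two surfaces.  The printed component counts are computed from
the fixed-radius neighbour graph of the final clouds.
"""

from surfelseg import (
    OrientedCloud, Params, SurfelSystem, connected_components, run,
    sphere_seed, torus, two_spheres,
)

d0 = 3.0
link = 1.75 * d0  # sphere-of-influence radius used as graph link length

img = torus((100, 100, 100), (49.5, 49.5, 49.5), r_major=25, r_minor=10)
system = SurfelSystem.from_surfels(
    sphere_seed((74.5, 49.5, 49.5), 5, d0),  # inside the tube
    Params(d0=d0, f_pressure=0.01, rng_seed=2),
)
system, _ = run(system, img, max_steps=4500, log_every=1000)
n_comp = connected_components(OrientedCloud.from_system(system), link)
print(f"fusion:  {len(system)} surfels in {n_comp} connected component(s) "
      "(the inflating surface closed the ring)")

img = two_spheres((100, 100, 100), ((30, 49.5, 49.5), (70, 49.5, 49.5)), (15, 15))
system = SurfelSystem.from_surfels(
    sphere_seed((49.5, 49.5, 49.5), 42, d0),  # enclosing both targets
    Params(d0=d0, f_pressure=-0.01, rng_seed=3),
)
system, _ = run(system, img, max_steps=3500, log_every=1000)
n_comp = connected_components(OrientedCloud.from_system(system), link)
print(f"fission: {len(system)} surfels in {n_comp} connected component(s) "
      "(the deflating surface pinched off between the spheres)")
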