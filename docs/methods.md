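# Methods

`surfelseg` segments objects in 3D intensity volumes with a deformable
surface made of *surfels* — oriented particles, each a position
**p**ᵢ (continuous voxel coordinates) and a unit normal **n**ᵢ.  The model
is a strongly coarse-grained membrane: particles keep a preferred spacing,
favour local co-planarity, are attracted to nearby intensity maxima, and
are created and removed so the surface can grow, shrink and change
topology freely.  The output is an oriented point cloud per object.

## Dynamics

The integration is explicit Euler with purely viscous response: forces are
displacements per step in units of `d0`,

    p(t+1) = p(t) + d0 · [ Σⱼ (F_dist + F_plane) + F_pressure + F_signal ]
    n(t+1) = normalize( n(t) + Σⱼ T_tilt )

so a constant force of 0.01 with `d0 = 15` px moves a surfel 0.15 px per
step — 100 steps for 15 px.  There is no inertia and no adaptive time
stepping.

### Pair interactions

Neighbours are all surfels within the *sphere of influence* `α·d0`
(`α = 1.75`); the same count doubles as the local density estimate.  With
`d = ‖pⱼ−pᵢ‖`, `u = (pⱼ−pᵢ)/d` and `x = d/d0`:

- **Preferred distance** `F_dist = k_dist · f(x) · u`, with the
  unit-stiffness profile `f(x) = x−1` for `x<1` (harmonic repulsion) and
  `f(x) = (x−1)·exp(−(x−1)²/w²)`, `w = 0.3`, for `x≥1` — an attractive
  bond that vanishes at equilibrium and breaks smoothly as the pair
  stretches.  The width `w = 0.3` keeps the residual second-ring
  attraction of a closed surface (neighbours near `√3·d0`) negligible;
  with a wider bond a free closed surface slowly ingests itself.
- **Co-planarity** `F_plane = k_plane · (u·(nᵢ+nⱼ)) · nᵢ`, which pushes a
  surfel back into the common tangent plane of its neighbourhood.
- **Normal alignment** `T_tilt = −k_tilt · (nᵢ·u) · u`, which removes the
  component of the normal lying along the inter-surfel direction.  The
  sign matters: the opposite choice *grows* that component, tipping
  normals into the surface and dismantling the sheet.  Linearising around
  a flat sheet shows only the negative sign is restoring, and this is the
  orientation that actually produces the co-planarity the interaction is
  meant to enforce.

Surfels of **different objects** exchange only the repulsive branch of
`F_dist`: distinct surfaces exclude each other and never merge.  The same
reduction applies to same-object pairs with **anti-parallel normals**
(`nᵢ·nⱼ < 0`): such contacts are opposite faces of the sheet meeting
face-to-face (e.g. the two sides of a collapsing neck), not in-plane
neighbours; bonding or torquing across them glues and crumples the
membrane instead of letting it pinch off.  Anti-parallel contacts still
count for density, so overlapping sheets trigger crowding removal — this
is what lets a deflating surface split cleanly.

### Stability of the explicit update

Because displacement equals `d0 ×` force, each stiffness contributes its
value directly to the eigenvalues of the update map; stability of a mode
with effective stiffness `λ` requires `|1 − λ| < 1`.  Summed over ~6–12
neighbours this caps the usable stiffnesses well below 1:
`k_dist = 0.1`, `k_plane = 0.03`, `k_tilt = 0.2` were fixed by relaxation
experiments (a perturbed spherical seed must decay to < 10⁻² px/step
rather than oscillate or diverge) and leave roughly a factor-2 margin.
As an additional safeguard the per-step displacement is hard-capped at
`0.3·d0`; ordinary forces sit 10–30× below the cap, which only clips
transient spikes inside topological reconnection zones.

### Image interaction

Each surfel samples the volume by trilinear interpolation along its normal
at 0.5 px steps over `[−band, +band]` (`band = d0` by default).  The
signed offset `s*` of the profile maximum decides the data attachment:

- no maximum in the band (flat profile, or entirely outside the volume):
  only the balloon pressure `F_pressure = f_pressure·n` acts;
- `|s*| ≤ 0.5` px: the surfel is attached — signal *and* pressure vanish;
- otherwise `F_signal = sign(s*)·f_signal·n` adds to the pressure.

Ties on a plateau resolve to the sample nearest the surfel, so a surfel
inside a thick ridge counts as attached instead of being dragged to the
plateau edge.  For anisotropic voxels the sampling direction is the
physical-space unit normal converted back to voxel coordinates, making the
band isotropic in physical units.  `f_signal = 0.05` exceeds the largest
recommended |pressure| (0.04) — attachment must win against the pressure
plus the transient push of particle creation, or fast-growing fronts punch
through thin (2 px) membrane signals.

Surfels that drift more than `2·d0` outside the volume are removed: there
is nothing to attach to out there and the pressure would otherwise inflate
stray membrane (for instance an inverted fragment left over from a
topology change) without bound.

## Population adaptation

Once per step, every *active, mature* surfel (age > `balance_period`)
checks its same-object neighbour count within `α·d0`:

| condition            | action              |
|----------------------|---------------------|
| count > `n_remove` (13)   | remove itself (overcrowded) |
| `n_isolated` (3) ≤ count ≤ `n_create` (7) | spawn one surfel at the lowest-density position |
| count < `n_isolated` | remove itself (spurious debris) |

An ideal hexagonal packing at spacing `d0` has 12 neighbours within
`1.75·d0`; the limits bracket that value asymmetrically so the converged
population settles near the ideal packing (the surface-area estimate
depends on it, see Measurements).  Events are collected in a full scan
(ascending row order) and applied atomically, so one step's decisions
cannot cascade; the single seeded RNG makes runs bit-reproducible.

The spawn position is `CREATE_OFFSET·d0 = 0.5·d0` from the parent along
the summed neighbour repulsion (weights `1 − d/(α·d0)`) projected on the
parent's tangent plane, plus a 0.01·d0 jitter; a perfectly symmetric
neighbourhood falls back to a seeded random tangent.  The offset stays
below the membrane-signal thickness on purpose: children are born inside
the attached band and are walked into the density gap by the repulsion,
rather than being teleported a full `d0` ahead — which can leapfrog a thin
wall whenever the parent's normal happens to be wall-tangent.  Proposals
closer than `0.3·d0` to existing surface are skipped.

Two throttles keep regeneration from outrunning removal in degenerate
zones.  After spawning, the parent itself cools down for `balance_period`
steps — otherwise a surfel pinned at a low count rebuilds surface every
single step and an over-stretched neck can never snap.  And creation
requires local orientational coherence (mean `nᵢ·nⱼ` over neighbours
≥ 0.7): a healthy membrane patch is locally aligned, while crumpled or
colliding zones mix opposite faces and must be allowed to dissolve through
the removal rules instead of regrowing out of disordered debris.

## Convergence and locking

Each surfel carries an anchor (position and normal at the start of its
current window).  After `conv_window = 50` steps, net motion below
`conv_disp_tol·d0 = 0.01·d0` px and net rotation below
`conv_rot_tol = 0.01` rad mark it *converged*; otherwise it reverts to
active and the anchor resets.  Net displacement (not a per-step path sum)
is deliberate: an attached surfel sits in a tiny zero-mean limit cycle of
the discrete update (the signal force flips sign across the maximum, ~0.03
px amplitude) and would never pass a path-length test, yet its position is
stationary for every practical purpose.

A converged surfel whose same-object neighbours are all converged or
locked becomes **locked**: its position and normal are frozen for the rest
of the run, though it still exerts forces on active neighbours — growing
fronts respect finished surface, and a finished object can be locked while
a second object is segmented against it.  Locking is irreversible within a
run; `run(..., reset=True)` reactivates everything, which is also the
coarse-to-fine workflow (converge at large `d0`, lower `d0`, resume).

## Seeding

- **Sphere**: Fibonacci-lattice tessellation with
  `n = round(4πR² / ((√3/2)·d0²))` points (one hexagonal tile per surfel),
  normals radially outward.  Radii below `1.5·d0` are warned against: at
  that curvature neighbouring normals differ by order-one angles, the tilt
  torque scrambles the orientation field and the front may fail to attach.
- **Skeleton**: planar ROIs at ≥ 2 z-slices, resampled by arc length to a
  common count, matched ring-to-ring (with a cyclic-shift alignment that
  minimises twist), linearly interpolated at ~`d0` axial spacing and
  capped with flat hexagonal-grid disks; normals outward.
- **Cloud**: any oriented point set, e.g. the converged output of the
  previous time frame when tracking a slowly moving object.

Seeds are born mature (age past the balance period) so density adaptation
can act immediately.  Multiple seeds sharing an object id merge on contact
(one object initialised from several spheres); distinct ids stay mutually
exclusive.

## Synthetic phantoms

All benchmarks run on generated volumes: a sphere shell, a mid-plane slab
with a central circular hole, a torus shell, and two disjoint sphere
shells.  All render *membrane-like* signal — a binary shell of ~2 voxel
thickness and intensity 1 — because the attachment force seeks maxima, and
optionally add seeded zero-mean Gaussian noise.  They emulate the contrast
geometry of fluorescently labelled membranes, not the optics: there is no
PSF, no anisotropic blur, no intensity falloff with depth, no
autofluorescent background structure.  Passing the benchmarks therefore
demonstrates the mechanics of the particle system (attachment, density
control, topology handling, noise robustness of the collective dynamics),
not photometric robustness on any particular microscope.

## Measurements

Each surfel is assigned the area of an ideal hexagonal tile,
`a = (√3/2)·d0²`.  Surface area is `Σ aᵢ` and the enclosed volume follows
from the divergence theorem, `V = (1/3)·Σ aᵢ·(pᵢ·nᵢ)`, origin-independent
for closed surfaces with outward normals (a negative result flags inverted
normals or an open surface and is returned as an absolute value with a
warning).  The tile approximation tracks the true values to within the
population's density error — the converged packing sits slightly denser
than ideal, so area and volume read ~5–10% high on the sphere benchmark.
A local (Voronoi) area estimate would remove this bias but is out of
scope.  With anisotropic voxel spacing, volumes scale by `sx·sy·sz` and
areas by its 2/3 power (exact only for isotropic spacing — a documented
approximation).

Benchmark scores: RMS of surfel distances to a target sphere, and the
number of connected components of the fixed-radius (α·d0) same-object
neighbour graph.

## Benchmark problem sizes

The characterisation experiments run on 100³ voxel phantoms at `d0 = 3`
px: noiseless and noisy (σ = 1) sphere segmentation from an interior seed,
torus fusion, two-sphere fission, simultaneous two-object segmentation,
and the hole-leakage frontier.  The leakage experiment inflates a large
balloon (seed R = 22, centred 23 px below the plane) so the membrane
attaches around the hole before the bulge is tested — the arrest/leak
decision is then a rim-supported, Young–Laplace-like threshold, and the
minimal crossing pressure is located by bisection on a 0.0025-step
pressure grid in [0.005, 0.035] (crossing is monotone in pressure).

## Known limitations

- Seeds near the resolution limit (sphere radius < ~1.5·d0) can fail
  catastrophically rather than gracefully (normal-field scrambling; see
  Seeding).
- Inflation under pressure runs ~25% below the free-particle rate
  `d0·f_pressure` per step: the stretching membrane carries bond tension
  that density adaptation relieves only with a lag.
- Signal thinner than ~2 px, or two membranes closer than ~`d0`, cannot be
  resolved; the maximum search has no sub-band contrast model (a flatness
  tolerance of 10⁻⁶ is the only intensity threshold).
- Topology changes shed debris transiently; the coherence gate, isolation
  clearance and out-of-volume removal clean it up, but a fragment inverted
  by a violent collapse can persist inside the volume until it drifts out.
- The per-surfel area tile and the anisotropic area scaling are
  approximations (see Measurements).
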