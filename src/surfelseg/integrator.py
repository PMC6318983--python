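"""Explicit Euler integration of the surfel system.

Each iteration: rebuild the spatial index, evaluate pair forces, adapt the
population to the local density, evaluate image forces, and update positions
and normals:

    p(t+1) = p(t) + d0 * [ sum_j (F_dist + F_plane) + F_pressure + F_signal ]
    n(t+1) = normalize( n(t) + sum_j T_tilt )

The dynamics are purely viscous (no inertia): a force of magnitude f moves a
surfel by ``d0 * f`` pixels per step, so forces read directly as
displacement per step in units of d0.

Convergence is two-staged: a surfel that moves and rotates below tolerance
for a full window becomes *converged*; a converged surfel whose same-object
neighbours have all converged is *locked* — frozen for the rest of the run,
though it still exerts forces on active neighbours (so growing fronts
respect already-finished surface, e.g. when one object is locked while
another is still being segmented against it).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core import Params, SurfelState, SurfelSystem, validate_params
from .forces import image_forces_bulk, pair_forces_bulk
from .image import Image3D
from .neighbors import build_index
from .population import AdaptationEvent, adapt_population

__all__ = ["StepReport", "step", "update_convergence", "run", "PopulationCollapse"]

logger = logging.getLogger(__name__)

#: hard cap on the per-step displacement, in units of d0.  Normal operation
#: stays far below it (forces are ~0.01-0.1); it only clips transient force
#: spikes in crowded reconnection zones so they cannot catapult surfels.
MAX_STEP_DISP = 0.3

#: surfels farther than this outside the volume (units of d0) are removed.
#: Outside the imaged volume there is no signal to attach to, only the
#: pressure, so anything that drifts out — e.g. an inverted membrane
#: fragment left over from a topology change, which the pressure inflates
#: indefinitely — would otherwise grow without bound.
CLEAR_MARGIN = 2.0


class PopulationCollapse(RuntimeError):
    """All surfels were removed; the seed or f_pressure needs revisiting."""


@dataclasses.dataclass
class StepReport:
    """Summary of one integration step."""

    step_index: int
    n_active: int
    n_converged: int
    n_locked: int
    max_displacement: float
    events: list[AdaptationEvent]

    @property
    def n_total(self) -> int:
        return self.n_active + self.n_converged + self.n_locked


def step(system: SurfelSystem, img: Image3D) -> StepReport:
    """Advance the system by one iteration and return a report."""
    p = system.params
    if len(system) == 0:
        raise PopulationCollapse(
            "no surfels left; try a different f_pressure or seed"
        )

    _clear_out_of_volume(system, img)
    n0 = len(system)
    if n0 == 0:
        raise PopulationCollapse(
            "all surfels left the imaged volume; try a different "
            "f_pressure or seed"
        )
    _ensure_anchors(system)
    index = build_index(system)
    I, J, d, u = index.pairs_within(p.d_threshold)
    same = system.object_ids[I] == system.object_ids[J]
    locked = system.states == SurfelState.LOCKED

    # density counts: same-object neighbours within the sphere of influence
    counts = np.bincount(I[same], minlength=n0)

    # pair forces on non-locked receivers (locked surfels still emit forces)
    recv = ~locked[I]
    F_pair = np.zeros((n0, 3))
    T_pair = np.zeros((n0, 3))
    if recv.any():
        Ir, dr, ur = I[recv], d[recv], u[recv]
        Fp, Tp = pair_forces_bulk(
            dr, ur, system.normals[Ir], system.normals[J[recv]], same[recv], p
        )
        for c in range(3):
            F_pair[:, c] = np.bincount(Ir, weights=Fp[:, c], minlength=n0)
            T_pair[:, c] = np.bincount(Ir, weights=Tp[:, c], minlength=n0)

    # population adaptation (atomic), realigning the per-row force arrays
    events, keep, n_created = adapt_population(
        system, counts, pairs=(I[same], J[same])
    )
    if len(system) == 0:
        raise PopulationCollapse(
            "population collapsed during adaptation; try a different "
            "f_pressure or seed"
        )
    F_pair = np.vstack([F_pair[keep], np.zeros((n_created, 3))])
    T_pair = np.vstack([T_pair[keep], np.zeros((n_created, 3))])
    tail = len(system) - n_created
    system._anchor_pos = np.vstack(
        [system._anchor_pos[keep], system.positions[tail:]]
    )
    system._anchor_nrm = np.vstack(
        [system._anchor_nrm[keep], system.normals[tail:]]
    )
    # re-derive same-object pairs over surviving rows for the locking test
    kept_rows = np.nonzero(keep)[0]
    remap = -np.ones(n0, dtype=np.int64)
    remap[kept_rows] = np.arange(len(kept_rows))
    pair_ok = same & (remap[I] >= 0) & (remap[J] >= 0)
    system._last_pairs = (remap[I[pair_ok]], remap[J[pair_ok]])

    # image force and update for non-locked surfels
    locked = system.states == SurfelState.LOCKED
    mobile = ~locked
    F_img = np.zeros((len(system), 3))
    if mobile.any():
        F_img[mobile], _ = image_forces_bulk(
            img, system.positions[mobile], system.normals[mobile], p
        )

    old_pos = system.positions.copy()
    old_nrm = system.normals.copy()
    total = F_pair + F_img
    move = p.d0 * total
    mnorm = np.linalg.norm(move, axis=1)
    cap = MAX_STEP_DISP * p.d0
    spike = mnorm > cap
    if spike.any():
        move[spike] *= (cap / mnorm[spike])[:, None]
    new_pos = system.positions + move
    new_nrm = system.normals + T_pair
    if not (np.all(np.isfinite(new_pos)) & np.all(np.isfinite(new_nrm))):
        bad = np.nonzero(
            ~np.all(np.isfinite(new_pos), axis=1)
            | ~np.all(np.isfinite(new_nrm), axis=1)
        )[0]
        raise RuntimeError(
            f"non-finite update for surfel id(s) {system.ids[bad].tolist()} "
            f"at step {system.step_count}: force blow-up"
        )
    norms = np.linalg.norm(new_nrm, axis=1)
    degen = norms < 1e-12
    if degen.any():  # torque cancelled the normal; keep the old orientation
        new_nrm[degen] = old_nrm[degen]
        norms[degen] = np.linalg.norm(new_nrm[degen], axis=1)
    new_nrm /= norms[:, None]

    system.positions = np.where(mobile[:, None], new_pos, old_pos)
    system.normals = np.where(mobile[:, None], new_nrm, old_nrm)

    disp = np.linalg.norm(system.positions - old_pos, axis=1)
    dots = np.clip(np.einsum("ij,ij->i", system.normals, old_nrm), -1.0, 1.0)
    rot = np.arccos(dots)
    system._last_disp = disp
    system._last_rot = rot

    system.ages += 1
    system.step_count += 1
    update_convergence(system)

    return StepReport(
        step_index=system.step_count,
        n_active=system.n_active,
        n_converged=system.n_converged,
        n_locked=system.n_locked,
        max_displacement=float(disp.max()) if len(disp) else 0.0,
        events=events,
    )


def _clear_out_of_volume(system: SurfelSystem, img: Image3D) -> None:
    """Drop surfels beyond ``CLEAR_MARGIN * d0`` outside the volume."""
    if len(system) == 0:
        return
    m = CLEAR_MARGIN * system.params.d0
    nx, ny, nz = img.shape_xyz
    hi = np.array([nx - 1, ny - 1, nz - 1], dtype=float)
    out = np.any(
        (system.positions < -m) | (system.positions > hi + m), axis=1
    )
    if not out.any():
        return
    keep = ~out
    anchors = getattr(system, "_anchor_pos", None)
    if anchors is not None and len(anchors) == len(system):
        system._anchor_pos = system._anchor_pos[keep]
        system._anchor_nrm = system._anchor_nrm[keep]
    cooldown = getattr(system, "_spawn_cooldown", None)
    if cooldown is not None and len(cooldown) == len(system):
        system._spawn_cooldown = cooldown[keep]
    system.remove_rows(out)
    system._last_pairs = None


def _ensure_anchors(system: SurfelSystem) -> None:
    """Initialise the per-surfel convergence anchors when missing."""
    a = getattr(system, "_anchor_pos", None)
    if a is None or len(a) != len(system):
        system._anchor_pos = system.positions.copy()
        system._anchor_nrm = system.normals.copy()


def update_convergence(system: SurfelSystem) -> None:
    """Update still-counters, converged flags and the locked set.

    Every surfel carries an *anchor* (position and normal captured at the
    start of its current window) and a counter of steps since then.  When
    the counter reaches ``conv_window``, the net motion relative to the
    anchor decides the state: below ``conv_disp_tol * d0`` px and
    ``conv_rot_tol`` rad -> converged, else active; the anchor then resets.
    Net motion (rather than a per-step path sum) is used so surfels trapped
    in tiny zero-mean limit cycles of the discrete update still converge.

    A converged surfel locks when every same-object neighbour is converged
    or locked; locking is irreversible within a run.
    """
    p = system.params
    _ensure_anchors(system)
    locked = system.states == SurfelState.LOCKED
    system.still_counters = np.where(
        locked, system.still_counters, system.still_counters + 1
    )
    due = (system.still_counters >= p.conv_window) & ~locked
    if due.any():
        net_d = np.linalg.norm(
            system.positions[due] - system._anchor_pos[due], axis=1
        )
        dots = np.clip(
            np.einsum(
                "ij,ij->i", system.normals[due], system._anchor_nrm[due]
            ),
            -1.0,
            1.0,
        )
        net_r = np.arccos(dots)
        ok = (net_d < p.conv_disp_tol * p.d0) & (net_r < p.conv_rot_tol)
        states = system.states.copy()
        states[due] = np.where(ok, SurfelState.CONVERGED, SurfelState.ACTIVE)
        system.states = states
        system._anchor_pos[due] = system.positions[due]
        system._anchor_nrm[due] = system.normals[due]
        system.still_counters[due] = 0

    pairs = system._last_pairs
    if pairs is None:
        return
    I, J = pairs
    settled = system.states >= SurfelState.CONVERGED
    has_unsettled_nb = np.zeros(len(system), dtype=bool)
    if len(I):
        np.logical_or.at(has_unsettled_nb, I, ~settled[J])
    lockable = (system.states == SurfelState.CONVERGED) & ~has_unsettled_nb
    system.states[lockable] = SurfelState.LOCKED


def run(
    system: SurfelSystem,
    img: Image3D,
    max_steps: int | None = None,
    reset: bool = False,
    log_every: int = 100,
) -> tuple[SurfelSystem, list[StepReport]]:
    """Iterate :func:`step` until every surfel is locked or the cap is hit.

    With ``reset=True`` all surfels revert to active first (still-counters
    cleared, ages set mature) — the resume workflow: change ``system.params``
    (e.g. lower ``d0`` to refine) and continue from the converged cloud.  A
    system that is already fully locked returns immediately with no force
    evaluation.
    """
    validate_params(system.params)
    if len(system) == 0:
        raise PopulationCollapse("cannot run an empty system: seed it first")
    if max_steps is None:
        max_steps = system.params.max_steps
    if reset:
        system.states = np.full(len(system), SurfelState.ACTIVE, dtype=np.int8)
        system.still_counters = np.zeros(len(system), dtype=np.int64)
        system.ages = np.full(
            len(system), system.params.balance_period + 1, dtype=np.int64
        )
        system._last_pairs = None
        system._anchor_pos = None

    reports: list[StepReport] = []
    for _ in range(max_steps):
        if len(system) and system.n_locked == len(system):
            break
        rep = step(system, img)
        reports.append(rep)
        if log_every and rep.step_index % log_every == 0:
            logger.info(
                "step %d: %d active / %d converged / %d locked, max disp %.4f px",
                rep.step_index,
                rep.n_active,
                rep.n_converged,
                rep.n_locked,
                rep.max_displacement,
            )
    return system, reports
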