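"""Density-driven surfel number adaptation.

The surface keeps its particle density near the equilibrium packing by three
local rules, evaluated once per integration step from the neighbour count
within the sphere of influence (``alpha * d0``, same-object neighbours only):

1. count > ``n_remove``            -> the surfel removes itself (overcrowded);
2. ``n_isolated`` <= count <= ``n_create`` -> one new surfel is created at the
   position of lowest local density;
3. count < ``n_isolated``          -> the surfel is removed (too isolated to
   seed new surface; clears spurious fragments).

Newly created surfels are protected by a *balance period*: for
``balance_period`` steps after creation a surfel can neither die nor spawn,
which damps creation/removal oscillations.  The balance period throttles the
parent side as well: after spawning, a surfel cannot spawn again for
``balance_period`` steps.  Without the parent cooldown, a surfel stuck at a
low count regenerates surface every single step, which keeps over-stretched
membrane necks alive indefinitely instead of letting them snap and be
cleared as isolated debris.  Events are gathered over a full scan in
ascending row order and applied atomically afterwards, so within-step
cascades are impossible and runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .core import Params, Surfel, SurfelState, SurfelSystem

__all__ = ["AdaptationEvent", "EventKind", "lowest_density_position", "adapt_population"]

#: minimum allowed distance of a newly created surfel to any existing
#: same-object surfel, in units of d0; closer proposals are skipped.
MIN_CREATE_SEP = 0.3

#: distance of a newly created surfel from its parent, in units of d0.
#: Kept well below 1 so that creation can never leapfrog a thin image
#: structure the parent is attached to (a membrane signal is only ~2 px
#: thick); the pair repulsion then walks the child into the density gap.
CREATE_OFFSET = 0.5

#: magnitude of the positional jitter applied to new surfels, units of d0.
CREATE_JITTER = 0.01

#: minimum mean normal alignment (n_i . n_j over same-object neighbours)
#: required to spawn.  A healthy membrane patch has locally aligned normals
#: (mean near 1); a collapsing or crumpled zone mixes opposite faces (mean
#: near or below 0).  Gating creation on coherence lets over-compressed or
#: torn regions dissolve through the removal rules instead of endlessly
#: regenerating surface out of disordered debris.
COHERENCE_MIN = 0.7


class EventKind(str, enum.Enum):
    CREATED = "created"
    REMOVED_CROWDED = "removed_crowded"
    REMOVED_ISOLATED = "removed_isolated"


@dataclasses.dataclass
class AdaptationEvent:
    """One creation/removal decision.

    ``surfel_id`` is the id of the new surfel for creations (with
    ``parent_id`` set to the spawning surfel) and the id of the removed
    surfel otherwise.  ``new_position`` is filled for creations only.
    """

    kind: EventKind
    surfel_id: int
    new_position: np.ndarray | None = None
    parent_id: int | None = None


def _repulsion_direction(
    pos: np.ndarray,
    normal: np.ndarray,
    neighbor_pos: np.ndarray,
    d_threshold: float,
) -> np.ndarray:
    """Summed neighbour repulsion projected on the tangent plane (unnormalised).

    Each neighbour within the sphere of influence repels with weight
    ``1 - d / d_threshold`` (as if it pushed the surfel away); the sum points
    toward the locally least crowded direction.
    """
    diff = neighbor_pos - pos[None, :]
    d = np.linalg.norm(diff, axis=1)
    ok = d > 1e-12
    diff, d = diff[ok], d[ok]
    w = np.maximum(1.0 - d / d_threshold, 0.0)
    r = -(w[:, None] * (diff / d[:, None])).sum(axis=0)
    return r - (r @ normal) * normal


def _random_tangent(normal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        t = v - (v @ normal) * normal
        n = np.linalg.norm(t)
        if n > 1e-9:
            return t / n


def lowest_density_position(
    s: Surfel, neighbors: list[Surfel], p: Params, rng: np.random.Generator
) -> np.ndarray:
    """Estimate where to create a new surfel near ``s``.

    The summed repulsion exerted by the neighbours, projected onto the
    tangent plane of ``s``, points toward the lowest surfel density; the new
    position is ``CREATE_OFFSET * d0`` along it, plus a small jitter
    (0.01 d0) so exact coincidences cannot occur.  A perfectly symmetric
    neighbourhood falls back to a random tangent direction drawn from the
    system RNG.  The offset stays below the parent spacing so that creation
    cannot jump across a thin attached image structure.
    """
    if not neighbors:
        raise ValueError("neighbors must be non-empty")
    npos = np.array([nb.position for nb in neighbors], dtype=float)
    r = _repulsion_direction(s.position, s.normal, npos, p.d_threshold)
    norm = np.linalg.norm(r)
    rhat = r / norm if norm > 1e-9 else _random_tangent(s.normal, rng)
    jitter = rng.standard_normal(3)
    jitter *= CREATE_JITTER * p.d0 / np.linalg.norm(jitter)
    return s.position + CREATE_OFFSET * p.d0 * rhat + jitter


def adapt_population(
    system: SurfelSystem,
    neighbor_counts: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[list[AdaptationEvent], np.ndarray, int]:
    """Apply the three density rules and mutate the system atomically.

    Parameters
    ----------
    neighbor_counts:
        Per-row count of same-object neighbours within ``alpha * d0``.
    pairs:
        Optional directed same-object pair rows ``(I, J)`` from the current
        neighbour search; recomputed if omitted.

    Returns
    -------
    (events, keep_mask, n_created):
        The ordered event list, the boolean row mask of surviving pre-existing
        rows, and the number of appended surfels — callers carrying per-row
        arrays (e.g. accumulated forces) use the latter two to stay aligned.
    """
    p = system.params
    n = len(system)
    counts = np.asarray(neighbor_counts)
    if counts.shape != (n,):
        raise ValueError("neighbor_counts must have one entry per surfel")

    if pairs is None:
        from .neighbors import build_index

        idx = build_index(system)
        I, J, _, _ = idx.pairs_within(p.d_threshold)
        same = system.object_ids[I] == system.object_ids[J]
        I, J = I[same], J[same]
    else:
        I, J = pairs

    cooldown = getattr(system, "_spawn_cooldown", None)
    if cooldown is None or len(cooldown) != n:
        cooldown = np.zeros(n, dtype=np.int64)
    cooldown = np.maximum(cooldown - 1, 0)

    eligible = (system.states == SurfelState.ACTIVE) & (system.ages > p.balance_period)
    remove_crowded = eligible & (counts > p.n_remove)
    remove_isolated = eligible & (counts < p.n_isolated)
    align_sum = np.zeros(n)
    if len(I):
        align = np.einsum(
            "ij,ij->i", system.normals[I], system.normals[J]
        )
        align_sum = np.bincount(I, weights=align, minlength=n)
    with np.errstate(invalid="ignore"):
        mean_align = np.where(counts > 0, align_sum / np.maximum(counts, 1), 1.0)
    create = (
        eligible
        & (counts <= p.n_create)
        & (counts >= p.n_isolated)
        & (cooldown == 0)
        & (mean_align >= COHERENCE_MIN)
    )

    # neighbour rows per creator, from the directed pair list
    order = np.argsort(I, kind="stable")
    I_s, J_s = I[order], J[order]
    starts = np.searchsorted(I_s, np.arange(n))
    ends = np.searchsorted(I_s, np.arange(n) + 1)

    events: list[AdaptationEvent] = []
    new_pos: list[np.ndarray] = []
    new_nrm: list[np.ndarray] = []
    new_obj: list[int] = []
    new_parent_rows: list[int] = []
    min_sep = MIN_CREATE_SEP * p.d0

    for i in np.nonzero(create)[0]:
        nb_rows = J_s[starts[i] : ends[i]]
        if len(nb_rows) == 0:
            continue  # isolated rule governs surfels with no neighbours
        r = _repulsion_direction(
            system.positions[i],
            system.normals[i],
            system.positions[nb_rows],
            p.d_threshold,
        )
        norm = np.linalg.norm(r)
        rhat = r / norm if norm > 1e-9 else _random_tangent(system.normals[i], system.rng)
        jitter = system.rng.standard_normal(3)
        jitter *= CREATE_JITTER * p.d0 / np.linalg.norm(jitter)
        pos = system.positions[i] + CREATE_OFFSET * p.d0 * rhat + jitter
        # reject proposals that would land on existing or just-proposed surface
        d_exist = np.linalg.norm(system.positions[nb_rows] - pos[None, :], axis=1)
        too_close = d_exist.min() < min_sep if len(d_exist) else False
        same_new = [q for k, q in enumerate(new_pos) if new_obj[k] == system.object_ids[i]]
        if same_new and not too_close:
            d_new = np.linalg.norm(np.array(same_new) - pos[None, :], axis=1)
            too_close = bool(d_new.min() < min_sep)
        if too_close:
            continue
        new_pos.append(pos)
        new_nrm.append(system.normals[i].copy())
        new_obj.append(int(system.object_ids[i]))
        new_parent_rows.append(int(i))
        cooldown[i] = p.balance_period

    removed = remove_crowded | remove_isolated
    for i in np.nonzero(remove_crowded)[0]:
        events.append(AdaptationEvent(EventKind.REMOVED_CROWDED, int(system.ids[i])))
    for i in np.nonzero(remove_isolated)[0]:
        events.append(AdaptationEvent(EventKind.REMOVED_ISOLATED, int(system.ids[i])))

    parent_ids = [int(system.ids[r]) for r in new_parent_rows]
    keep_mask = ~removed
    system.remove_rows(removed)
    system._spawn_cooldown = np.concatenate(
        [cooldown[keep_mask], np.zeros(len(new_pos), dtype=np.int64)]
    )

    n_created = len(new_pos)
    if n_created:
        from .core import Surfel as _S

        created = [
            _S(id=-1, position=new_pos[k], normal=new_nrm[k], object_id=new_obj[k])
            for k in range(n_created)
        ]
        new_ids = system.add_surfels(created)
        for k, nid in enumerate(new_ids):
            events.append(
                AdaptationEvent(
                    EventKind.CREATED,
                    int(nid),
                    new_position=new_pos[k],
                    parent_id=parent_ids[k],
                )
            )
    return events, keep_mask, n_created
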