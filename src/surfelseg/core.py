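"""Core data structures: surfels, parameters, and the evolving surfel system.

A *surfel* (SURFace ELement) is an oriented particle — a position plus a unit
normal — representing a small patch of a surface.  A collection of surfels
forms a deformable, topology-adaptive surface: a highly coarse-grained model
of a lipid membrane, where particles keep a preferred spacing ``d0``, favour
co-planarity with their neighbours, and are attracted to local intensity
maxima of a 3D image.

The :class:`SurfelSystem` stores the population in structure-of-arrays form
(NumPy arrays) for speed; :class:`Surfel` is the per-particle record used at
the API boundary (seeding, inspection, tests).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "SurfelState",
    "Surfel",
    "Params",
    "SurfelSystem",
    "make_surfel",
    "validate_params",
    "StabilityWarning",
]


class StabilityWarning(UserWarning):
    """Raised when a parameter lies outside the empirically stable regime."""


class SurfelState(enum.IntEnum):
    """Lifecycle of a surfel.

    ``ACTIVE`` surfels move and may spawn/remove; ``CONVERGED`` surfels met the
    motion criteria over a full convergence window; ``LOCKED`` surfels are
    frozen forever (they still exert forces on neighbours, but are never
    updated again within a run).
    """

    ACTIVE = 0
    CONVERGED = 1
    LOCKED = 2


@dataclasses.dataclass
class Surfel:
    """One oriented particle.

    Attributes
    ----------
    id:
        Unique integer within a system (``-1`` until registered).
    position:
        3-vector, continuous voxel coordinates (x, y, z), sub-voxel precision.
    normal:
        Unit 3-vector, outward surface orientation.
    object_id:
        Segmentation target this surfel belongs to.  Surfels of different
        objects interact only through repulsion.
    state:
        Lifecycle state, see :class:`SurfelState`.
    age:
        Integration steps since creation.
    still_counter:
        Consecutive steps with sub-threshold motion (convergence bookkeeping).
    """

    id: int
    position: np.ndarray
    normal: np.ndarray
    object_id: int = 0
    state: SurfelState = SurfelState.ACTIVE
    age: int = 0
    still_counter: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)


def make_surfel(position: Sequence[float], normal: Sequence[float], object_id: int = 0) -> Surfel:
    """Create an active surfel, renormalising ``normal`` to unit length.

    Raises
    ------
    ValueError
        If the normal vector is zero (orientation undefined).
    """
    position = np.asarray(position, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if position.shape != (3,) or normal.shape != (3,):
        raise ValueError("position and normal must be 3-vectors")
    nn = float(np.linalg.norm(normal))
    if not np.isfinite(nn) or nn == 0.0:
        raise ValueError("surfel normal must be a non-zero finite vector")
    return Surfel(id=-1, position=position, normal=normal / nn, object_id=int(object_id))


@dataclasses.dataclass
class Params:
    """All tunables of the method.

    Forces are expressed as displacement per integration step in units of
    ``d0`` (the explicit-Euler viscous update multiplies the resulting force
    by ``d0`` pixels).  Only ``d0`` and ``f_pressure`` normally need to be set
    by the user; everything else defaults to a stable set point.

    Attributes
    ----------
    d0:
        Equilibrium inter-surfel distance, pixels.  Sets the minimum feature
        size that can be segmented; typical range 1–20.
    alpha:
        Sphere-of-influence radius factor: neighbours are surfels within
        ``alpha * d0``; the same count drives density adaptation.
    f_pressure:
        Constant balloon force along the normal; positive inflates, negative
        deflates.  Stable within roughly [-0.04, 0.04].
    f_signal:
        Constant norm of the image-attachment force.
    k_dist:
        Stiffness scaling of the preferred-distance force profile.  Kept well
        below 1 so that the explicit Euler update (displacement = d0 x force)
        damps rather than amplifies spring modes.
    k_plane:
        Stiffness of the co-planarity position force.
    k_tilt:
        Stiffness of the normal-alignment torque.
    n_create / n_remove / n_isolated:
        Density limits on the neighbour count within ``alpha*d0``: spawn a new
        surfel when count <= ``n_create`` (and >= ``n_isolated``), self-remove
        when count > ``n_remove``, clear as spurious when count < ``n_isolated``.
    balance_period:
        Steps after creation during which a surfel can neither die nor spawn.
    search_band:
        Half-width, pixels, of the local-maximum search along the normal.
        ``None`` means ``d0``.
    conv_window / conv_disp_tol / conv_rot_tol:
        A surfel converges when, over a window of ``conv_window`` steps, its
        net displacement stays below ``conv_disp_tol * d0`` px and its net
        rotation below ``conv_rot_tol`` rad.  Net (start-to-end) motion is
        used so that surfels caught in tiny zero-mean limit cycles of the
        discrete dynamics still converge.
    max_steps:
        Default iteration cap for :func:`surfelseg.integrator.run`.
    rng_seed:
        Seed of the single RNG driving all randomness (creation jitter).
    """

    d0: float = 3.0
    alpha: float = 1.75
    f_pressure: float = 0.01
    f_signal: float = 0.05
    k_dist: float = 0.1
    k_plane: float = 0.03
    k_tilt: float = 0.2
    n_create: int = 7
    n_remove: int = 13
    n_isolated: int = 3
    balance_period: int = 10
    search_band: float | None = None
    conv_window: int = 50
    conv_disp_tol: float = 0.01
    conv_rot_tol: float = 0.01
    max_steps: int = 5000
    rng_seed: int = 0

    @property
    def d_threshold(self) -> float:
        """Density-estimation radius == sphere-of-influence radius, pixels."""
        return self.alpha * self.d0

    @property
    def band(self) -> float:
        """Effective half-width of the maximum search, pixels."""
        return self.d0 if self.search_band is None else self.search_band

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "Params":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def validate_params(p: Params) -> Params:
    """Check hard invariants; warn on values outside the stable regime.

    Returns ``p`` unchanged when valid.  Hard violations (non-positive d0,
    alpha <= 1, inconsistent density limits, non-positive stiffnesses) raise
    ``ValueError``; soft ones (|f_pressure| > 0.04, d0 outside [1, 20]) emit a
    :class:`StabilityWarning` only.
    """
    if not (p.d0 > 0):
        raise ValueError(f"d0 must be > 0, got {p.d0}")
    if not (p.alpha > 1):
        raise ValueError(f"alpha must be > 1, got {p.alpha}")
    if not (p.n_isolated < p.n_create < p.n_remove):
        raise ValueError(
            "density limits must satisfy n_isolated < n_create < n_remove, got "
            f"{p.n_isolated}, {p.n_create}, {p.n_remove}"
        )
    for name in ("f_signal", "k_dist", "k_plane", "k_tilt"):
        if not (getattr(p, name) > 0):
            raise ValueError(f"{name} must be > 0, got {getattr(p, name)}")
    if p.balance_period < 0 or p.conv_window < 1:
        raise ValueError("balance_period must be >= 0 and conv_window >= 1")
    if p.search_band is not None and not (p.search_band > 0):
        raise ValueError("search_band must be > 0 when given")
    if abs(p.f_pressure) > 0.04:
        warnings.warn(
            f"f_pressure={p.f_pressure} outside [-0.04, 0.04]; the particle "
            "system may become unstable",
            StabilityWarning,
            stacklevel=2,
        )
    if not (1.0 <= p.d0 <= 20.0):
        warnings.warn(
            f"d0={p.d0} outside the typical range [1, 20] pixels",
            StabilityWarning,
            stacklevel=2,
        )
    return p


class SurfelSystem:
    """The evolving surfel population, stored as parallel arrays.

    Arrays (all length N, kept in sync):

    - ``positions`` (N, 3) float — continuous voxel coordinates (x, y, z)
    - ``normals``   (N, 3) float — unit vectors
    - ``ids``       (N,) int — unique, never reused
    - ``object_ids`` (N,) int
    - ``states``    (N,) int8 — :class:`SurfelState` values
    - ``ages``      (N,) int
    - ``still_counters`` (N,) int

    All randomness (creation jitter, symmetric-neighbourhood fallbacks) flows
    from ``self.rng``, seeded by ``params.rng_seed``: identical seeds give
    identical runs.
    """

    def __init__(self, params: Params, rng_seed: int | None = None):
        self.params = validate_params(params)
        self.positions = np.empty((0, 3), dtype=float)
        self.normals = np.empty((0, 3), dtype=float)
        self.ids = np.empty(0, dtype=np.int64)
        self.object_ids = np.empty(0, dtype=np.int64)
        self.states = np.empty(0, dtype=np.int8)
        self.ages = np.empty(0, dtype=np.int64)
        self.still_counters = np.empty(0, dtype=np.int64)
        self.step_count = 0
        self._next_id = 0
        seed = params.rng_seed if rng_seed is None else rng_seed
        self.rng = np.random.default_rng(seed)
        # last-step neighbour pairs (row indices), set by the integrator
        self._last_pairs: tuple[np.ndarray, np.ndarray] | None = None

    # -- construction --------------------------------------------------

    @classmethod
    def from_surfels(cls, surfels: Iterable[Surfel], params: Params,
                     rng_seed: int | None = None) -> "SurfelSystem":
        sys_ = cls(params, rng_seed=rng_seed)
        sys_.add_surfels(surfels)
        return sys_

    def add_surfels(self, surfels: Iterable[Surfel]) -> np.ndarray:
        """Register surfels, assigning fresh unique ids.  Returns the new ids."""
        surfels = list(surfels)
        if not surfels:
            return np.empty(0, dtype=np.int64)
        pos = np.array([s.position for s in surfels], dtype=float)
        nrm = np.array([s.normal for s in surfels], dtype=float)
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(nrm)):
            raise ValueError("non-finite surfel position or normal")
        norms = np.linalg.norm(nrm, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero surfel normal")
        nrm /= norms[:, None]
        n = len(surfels)
        new_ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.positions = np.vstack([self.positions, pos])
        self.normals = np.vstack([self.normals, nrm])
        self.ids = np.concatenate([self.ids, new_ids])
        self.object_ids = np.concatenate(
            [self.object_ids, np.array([s.object_id for s in surfels], dtype=np.int64)]
        )
        self.states = np.concatenate(
            [self.states, np.array([int(s.state) for s in surfels], dtype=np.int8)]
        )
        self.ages = np.concatenate(
            [self.ages, np.array([s.age for s in surfels], dtype=np.int64)]
        )
        self.still_counters = np.concatenate(
            [self.still_counters, np.array([s.still_counter for s in surfels], dtype=np.int64)]
        )
        return new_ids

    def remove_rows(self, mask: np.ndarray) -> None:
        """Drop surfels where ``mask`` is True (row mask, not ids)."""
        keep = ~np.asarray(mask, dtype=bool)
        self.positions = self.positions[keep]
        self.normals = self.normals[keep]
        self.ids = self.ids[keep]
        self.object_ids = self.object_ids[keep]
        self.states = self.states[keep]
        self.ages = self.ages[keep]
        self.still_counters = self.still_counters[keep]

    # -- views ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_active(self) -> int:
        return int(np.sum(self.states == SurfelState.ACTIVE))

    @property
    def n_converged(self) -> int:
        return int(np.sum(self.states == SurfelState.CONVERGED))

    @property
    def n_locked(self) -> int:
        return int(np.sum(self.states == SurfelState.LOCKED))

    def surfels(self) -> list[Surfel]:
        """Materialise the population as a list of :class:`Surfel` records."""
        return [
            Surfel(
                id=int(self.ids[i]),
                position=self.positions[i].copy(),
                normal=self.normals[i].copy(),
                object_id=int(self.object_ids[i]),
                state=SurfelState(int(self.states[i])),
                age=int(self.ages[i]),
                still_counter=int(self.still_counters[i]),
            )
            for i in range(len(self))
        ]

    def row_of_id(self, surfel_id: int) -> int:
        rows = np.nonzero(self.ids == surfel_id)[0]
        if len(rows) == 0:
            raise KeyError(f"no surfel with id {surfel_id}")
        return int(rows[0])

    def check_invariants(self) -> None:
        """Assert structural invariants (unique ids, unit normals)."""
        if len(np.unique(self.ids)) != len(self.ids):
            raise AssertionError("duplicate surfel ids")
        if len(self):
            dev = np.abs(np.linalg.norm(self.normals, axis=1) - 1.0).max()
            if dev > 1e-9:
                raise AssertionError(f"non-unit normal, max deviation {dev}")
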