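"""Initial surfel configurations: spheres, planar-ROI skeletons, clouds.

A seed is a closed starter surface from which the segmentation evolves.
Spheres are the common case; a *skeleton* seed interpolates a stack of
planar ROIs into a generalized cylinder (for elongated or non-spherical
objects); a *cloud* seed wraps an existing oriented point cloud — e.g. the
output of the previous time frame when tracking a moving object.

Multiple seeds may share one object id (they will merge into a single
surface on contact) or carry distinct ids (their surfaces then mutually
repel and never merge).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from shapely.geometry import Point, Polygon

from .core import Surfel, make_surfel

__all__ = ["SeedSpec", "sphere_seed", "skeleton_seed", "cloud_seed", "load_seed_specs", "build_seed_surfels"]

#: default maturity assigned to seed surfels so that density adaptation is
#: immediately allowed (a seed is an established surface, not fresh growth).
_MATURE = 11

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclasses.dataclass
class SeedSpec:
    """Declarative description of one seed (config-file friendly).

    ``kind`` is one of ``sphere`` (center + radius), ``skeleton`` (list of
    ``(z, polygon)`` ROIs, polygons as Nx2 vertex lists in voxel units) or
    ``cloud`` (oriented points as Nx6 ``x y z nx ny nz`` rows, or a PLY
    path).  ``object_id`` groups seeds: seeds sharing an id merge on
    contact; distinct ids repel.
    """

    kind: str
    object_id: int = 0
    center: Sequence[float] | None = None
    radius: float | None = None
    rois: list[tuple[float, np.ndarray]] | None = None
    points: np.ndarray | None = None
    path: str | None = None


def sphere_seed(
    center: Sequence[float], radius: float, d0: float, object_id: int = 0
) -> list[Surfel]:
    """Tessellate a sphere with surfels at spacing ~ d0, normals outward.

    Uses the Fibonacci sphere lattice with
    ``n = round(4 pi R^2 / ((sqrt(3)/2) d0^2))`` points, i.e. one ideal
    hexagonal tile of side d0 per surfel.  Spheres coarser than d0 cannot be
    tessellated and are rejected.
    """
    center = np.asarray(center, dtype=float)
    if radius < d0:
        raise ValueError(f"seed radius {radius} must be >= d0 = {d0}")
    if radius < 1.5 * d0:
        warnings.warn(
            f"seed radius {radius} is below 1.5*d0 = {1.5 * d0}: neighbour "
            "normals differ by order-one angles at this curvature and the "
            "inflating front may fail to attach to thin structures; prefer "
            "a larger seed or a smaller d0",
            stacklevel=2,
        )
    n = int(round(4.0 * np.pi * radius**2 / ((np.sqrt(3.0) / 2.0) * d0**2)))
    n = max(n, 4)
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    theta = GOLDEN_ANGLE * i
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    out: list[Surfel] = []
    for k in range(n):
        s = make_surfel(center + radius * dirs[k], dirs[k], object_id)
        s.age = _MATURE
        out.append(s)
    return out


def _resample_closed(poly: np.ndarray, m: int) -> np.ndarray:
    """Resample a closed polygon to m points at equal arc length."""
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        raise ValueError("degenerate polygon with zero perimeter")
    t = np.linspace(0.0, total, m, endpoint=False)
    x = np.interp(t, arclen, closed[:, 0])
    y = np.interp(t, arclen, closed[:, 1])
    return np.column_stack([x, y])


def _align_ring(prev: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Cyclically shift ring points to best match the previous ring."""
    m = len(ring)
    best, best_cost = 0, np.inf
    for shift in range(m):
        cost = np.sum((np.roll(ring, -shift, axis=0) - prev) ** 2)
        if cost < best_cost:
            best, best_cost = shift, cost
    return np.roll(ring, -best, axis=0)


def _cap_points(poly: np.ndarray, d0: float) -> np.ndarray:
    """Hexagonal-grid points covering the interior of a polygon, spacing d0."""
    shp = Polygon(poly)
    minx, miny, maxx, maxy = shp.bounds
    dy = d0 * np.sqrt(3.0) / 2.0
    pts = []
    row = 0
    y = miny
    while y <= maxy:
        x0 = minx + (d0 / 2.0 if row % 2 else 0.0)
        x = x0
        while x <= maxx:
            if shp.contains(Point(x, y)):
                pts.append((x, y))
            x += d0
        y += dy
        row += 1
    return np.array(pts, dtype=float).reshape(-1, 2)


def skeleton_seed(
    rois: Sequence[tuple[float, np.ndarray]], d0: float, object_id: int = 0
) -> list[Surfel]:
    """Interpolate planar ROIs into a capped generalized cylinder of surfels.

    ``rois`` is a list of ``(z, polygon)`` with at least two distinct
    z-slices; polygons are closed Nx2 vertex lists (voxel units, not
    self-intersecting).  Consecutive outlines are matched by normalized arc
    length (with a cyclic-shift alignment to minimise twist) and linearly
    interpolated at ~ d0 axial spacing; the two end slices are capped with
    flat disks.  Normals point outward.
    """
    rois = sorted(((float(z), np.asarray(poly, dtype=float)) for z, poly in rois),
                  key=lambda t: t[0])
    if len(rois) < 2:
        raise ValueError("a skeleton seed needs at least two ROIs at distinct z")
    zs = [z for z, _ in rois]
    if len(set(zs)) != len(zs):
        raise ValueError("ROI z-slices must be distinct")
    for _, poly in rois:
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("each ROI polygon needs at least 3 (x, y) vertices")
        if not Polygon(poly).is_valid:
            raise ValueError("self-intersecting or degenerate ROI polygon")

    perims = [Polygon(poly).length for _, poly in rois]
    m = max(int(round(max(perims) / d0)), 8)

    rings: list[np.ndarray] = []  # (m, 3) per ring
    prev2d: np.ndarray | None = None
    for (za, pa), (zb, pb) in zip(rois[:-1], rois[1:]):
        ra = _resample_closed(pa, m) if prev2d is None else prev2d
        rb = _align_ring(ra, _resample_closed(pb, m))
        n_layers = max(int(round((zb - za) / d0)), 1)
        start_t = 0 if prev2d is None else 1
        for k in range(start_t, n_layers + 1):
            t = k / n_layers
            ring2d = (1 - t) * ra + t * rb
            z = (1 - t) * za + t * zb
            rings.append(np.column_stack([ring2d, np.full(m, z)]))
        prev2d = rb

    surfels: list[Surfel] = []
    n_rings = len(rings)
    for ri, ring in enumerate(rings):
        centroid = ring.mean(axis=0)
        below = rings[max(ri - 1, 0)]
        above = rings[min(ri + 1, n_rings - 1)]
        for k in range(m):
            t1 = ring[(k + 1) % m] - ring[(k - 1) % m]  # along the ring
            t2 = above[k] - below[k]  # along the axis
            nrm = np.cross(t2, t1)
            if np.linalg.norm(nrm) < 1e-9:
                nrm = ring[k] - centroid
                nrm[2] = 0.0
            if (ring[k] - centroid) @ nrm < 0:
                nrm = -nrm
            s = make_surfel(ring[k], nrm, object_id)
            s.age = _MATURE
            surfels.append(s)

    for (z, poly), sign in ((rois[0], -1.0), (rois[-1], +1.0)):
        for x, y in _cap_points(poly, d0):
            s = make_surfel((x, y, z), (0.0, 0.0, sign), object_id)
            s.age = _MATURE
            surfels.append(s)
    return surfels


def cloud_seed(points: np.ndarray, object_id: int = 0, balance_period: int = 10) -> list[Surfel]:
    """Wrap an oriented point cloud (Nx6: x y z nx ny nz) as mature surfels.

    Typical use: feed the converged cloud of the previous time frame as the
    seed of the next one.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 6 or len(points) == 0:
        raise ValueError("points must be a non-empty (N, 6) array: x y z nx ny nz")
    out = []
    for row in points:
        s = make_surfel(row[:3], row[3:6], object_id)
        s.age = balance_period + 1
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# seed config files
# ---------------------------------------------------------------------------


def load_seed_specs(path: str | Path) -> list[SeedSpec]:
    """Read a YAML/JSON list of seed definitions.

    Each entry is a mapping with ``kind`` plus the geometry fields of
    :class:`SeedSpec`; skeleton ROIs are given as
    ``rois: [{z: 10, polygon: [[x, y], ...]}, ...]``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list) or not raw:
        raise ValueError("seed file must contain a non-empty list of seeds")
    specs = []
    for entry in raw:
        kind = entry.get("kind")
        if kind not in ("sphere", "skeleton", "cloud"):
            raise ValueError(f"unknown seed kind: {kind!r}")
        spec = SeedSpec(kind=kind, object_id=int(entry.get("object_id", 0)))
        if kind == "sphere":
            spec.center = [float(v) for v in entry["center"]]
            spec.radius = float(entry["radius"])
        elif kind == "skeleton":
            spec.rois = [
                (float(r["z"]), np.asarray(r["polygon"], dtype=float))
                for r in entry["rois"]
            ]
        else:
            if "path" in entry:
                spec.path = str(entry["path"])
            else:
                spec.points = np.asarray(entry["points"], dtype=float)
        specs.append(spec)
    return specs


def build_seed_surfels(specs: Sequence[SeedSpec], d0: float) -> list[Surfel]:
    """Instantiate all seeds of a config as one surfel list."""
    out: list[Surfel] = []
    for spec in specs:
        if spec.kind == "sphere":
            out.extend(sphere_seed(spec.center, spec.radius, d0, spec.object_id))
        elif spec.kind == "skeleton":
            out.extend(skeleton_seed(spec.rois, d0, spec.object_id))
        else:
            pts = spec.points
            if pts is None:
                from .analysis import load_ply

                cloud = load_ply(spec.path)
                pts = np.hstack([cloud.positions, cloud.normals])
            out.extend(cloud_seed(pts, spec.object_id))
    return out
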