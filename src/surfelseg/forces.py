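"""Surfel–surfel interactions and image/pressure forces.

All forces are displacements per integration step in units of ``d0`` (the
Euler update multiplies by ``d0`` pixels).  Three pair interactions act
between same-object neighbours:

- ``F_dist = k_dist * f(d/d0) * u`` — preferred-distance force along the
  inter-surfel unit vector ``u``: harmonic repulsion below ``d0``, a
  breakable attractive bond above (vanishing at ``d0`` and at infinity);
- ``F_plane = k_plane * (u . (n_i + n_j)) * n_i`` — co-planarity force;
- ``T_tilt = -k_tilt * (n_i . u) * u`` — normal-alignment increment, which
  removes the component of the normal lying along ``u`` (the restoring
  orientation of the torque: it drives normals perpendicular to the local
  surface plane; the opposite sign would tip them into it).

Surfels of *different* objects keep only the repulsive branch of ``F_dist``
(mutual surface exclusion) and exchange no planar force or torque.

The image acts through a constant-norm attachment force ``F_signal`` directed
along the normal toward the nearest local intensity maximum, plus a constant
balloon pressure ``F_pressure = f_pressure * n``.  Both become null when the
surfel sits at a local maximum.

Scalar, per-pair functions define the contract; ``*_bulk`` variants are the
vectorised forms used by the integrator and are cross-checked against the
scalar ones in the test suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import Params, Surfel
from .image import Image3D

__all__ = [
    "PairInteraction",
    "ImageForce",
    "f_dist_profile",
    "pair_interaction",
    "pair_interaction_repulsive_only",
    "local_max_offset",
    "image_force",
]

#: width of the attractive bond of the distance profile, in units of d0.
#: The bond force effectively vanishes well before d ~ alpha*d0, so the
#: residual second-ring attraction of a closed surface stays far below the
#: first-ring repulsion (a wider bond makes free closed surfaces slowly
#: self-collapse).
BOND_WIDTH = 0.3

#: a profile flatter than this (max - min intensity) carries no maximum.
FLAT_TOL = 1e-6

#: "near a local maximum" means within this many pixels of it (one sampling
#: step of the maximum search).
AT_MAX_TOL = 0.5

#: sampling step of the maximum search along the normal, pixels.
SEARCH_STEP = 0.5


@dataclasses.dataclass
class PairInteraction:
    """Forces and torque exerted by surfel j on surfel i."""

    f_dist: np.ndarray
    f_plane: np.ndarray
    t_tilt: np.ndarray

    @property
    def force(self) -> np.ndarray:
        return self.f_dist + self.f_plane


@dataclasses.dataclass
class ImageForce:
    """Resolved image force (signal + pressure) on one surfel."""

    f_total: np.ndarray
    at_maximum: bool


def f_dist_profile(x: float | np.ndarray, w: float = BOND_WIDTH):
    """Signed magnitude of the preferred-distance force at ``x = d / d0``.

    Positive values attract toward the neighbour.  Below the equilibrium
    (x < 1) the force is harmonic repulsion ``x - 1``; above it, the bond is
    attractive but breakable, ``(x - 1) * exp(-(x - 1)^2 / w^2)``, vanishing
    at equilibrium and at infinity.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(
            "d/d0 must be > 0 (coincident surfels must be jittered upstream)"
        )
    t = x - 1.0
    out = np.where(t < 0, t, t * np.exp(-(t * t) / (w * w)))
    return float(out) if out.ndim == 0 else out


def _repulsive_profile(x: np.ndarray) -> np.ndarray:
    """Harmonic branch only: min(x - 1, 0)."""
    return np.minimum(np.asarray(x, dtype=float) - 1.0, 0.0)


def pair_interaction(si: Surfel, sj: Surfel, p: Params) -> PairInteraction:
    """Full same-object pair interaction of j on i.

    ``F_dist`` is parallel to the inter-surfel unit vector ``u``; ``T_tilt``
    likewise.  Together the three terms favour equal spacing ``d0`` and local
    co-planarity.
    """
    diff = sj.position - si.position
    d = float(np.linalg.norm(diff))
    if d == 0.0:
        raise ValueError("coincident surfel positions")
    u = diff / d
    f_dist = p.k_dist * f_dist_profile(d / p.d0) * u
    f_plane = p.k_plane * float(u @ (si.normal + sj.normal)) * si.normal
    t_tilt = -p.k_tilt * float(si.normal @ u) * u
    return PairInteraction(f_dist=f_dist, f_plane=f_plane, t_tilt=t_tilt)


def pair_interaction_repulsive_only(si: Surfel, sj: Surfel, p: Params) -> PairInteraction:
    """Inter-object interaction: repulsion only, no planar force or torque.

    Used when ``si`` and ``sj`` belong to different segmentation objects, so
    distinct surfaces exclude each other without merging.
    """
    if si.object_id == sj.object_id:
        raise ValueError(
            "repulsive-only interaction is for surfels of different objects"
        )
    diff = sj.position - si.position
    d = float(np.linalg.norm(diff))
    if d == 0.0:
        raise ValueError("coincident surfel positions")
    u = diff / d
    f_dist = p.k_dist * float(_repulsive_profile(d / p.d0)) * u
    zero = np.zeros(3)
    return PairInteraction(f_dist=f_dist, f_plane=zero, t_tilt=zero.copy())


# ---------------------------------------------------------------------------
# image interaction
# ---------------------------------------------------------------------------


def _search_offsets(band: float) -> np.ndarray:
    """Signed sampling offsets spanning [-band, band], ordered by |s|.

    Ordering by |s| makes the (first-occurrence) argmax of a tied plateau pick
    the offset closest to the surfel, so a surfel already on a thick ridge is
    treated as at the maximum rather than dragged to the plateau edge.
    """
    if band <= 0:
        raise ValueError("band must be > 0")
    k = max(int(round(band / SEARCH_STEP)), 1)
    s = np.arange(-k, k + 1) * SEARCH_STEP
    order = np.lexsort((s, np.abs(s)))
    return s[order]


def local_max_offset(
    img: Image3D, position: np.ndarray, normal: np.ndarray, band: float
) -> float | None:
    """Signed offset (pixels) of the intensity maximum along the normal.

    Samples trilinearly at ``p + s * n`` for ``s`` on a uniform grid of step
    0.5 px spanning ``[-band, band]`` (the normal is scaled through the voxel
    spacing so the band is isotropic in physical space).  Returns ``None``
    when the profile is flat or entirely outside the volume; out-of-volume
    samples rank below any in-volume intensity.
    """
    s_vals, vals = _profile(img, np.asarray(position, float)[None, :],
                            np.asarray(normal, float)[None, :], band)
    return _offset_from_profile(s_vals, vals[0])


def _profile(img: Image3D, P: np.ndarray, N: np.ndarray, band: float):
    s_vals = _search_offsets(band)
    step = _voxel_steps(img, N)
    pts = P[:, None, :] + s_vals[None, :, None] * step[:, None, :]
    vals = img.sample_many(pts.reshape(-1, 3)).reshape(len(P), len(s_vals))
    return s_vals, vals


def _voxel_steps(img: Image3D, N: np.ndarray) -> np.ndarray:
    """Per-surfel voxel-frame step of one pixel along the physical normal."""
    m = N * img.spacing[None, :]
    norm = np.linalg.norm(m, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return (m / norm) / img.spacing[None, :]


def _offset_from_profile(s_vals: np.ndarray, vals: np.ndarray) -> float | None:
    inside = ~np.isnan(vals)
    if not inside.any():
        return None
    if np.nanmax(vals) - np.nanmin(vals) < FLAT_TOL:
        return None
    ranked = np.where(inside, vals, -np.inf)
    return float(s_vals[int(np.argmax(ranked))])


def image_force(s: Surfel, img: Image3D, p: Params) -> ImageForce:
    """Total image force (signal + pressure) resolved along the normal.

    No maximum in the band -> pressure only.  Maximum within 0.5 px -> both
    forces null (the surfel is attached).  Otherwise the constant-norm signal
    force points toward the maximum and the pressure adds algebraically.
    """
    s_star = local_max_offset(img, s.position, s.normal, p.band)
    if s_star is None:
        return ImageForce(f_total=p.f_pressure * s.normal, at_maximum=False)
    if abs(s_star) <= AT_MAX_TOL:
        return ImageForce(f_total=np.zeros(3), at_maximum=True)
    mag = np.sign(s_star) * p.f_signal + p.f_pressure
    return ImageForce(f_total=mag * s.normal, at_maximum=False)


# ---------------------------------------------------------------------------
# vectorised forms used by the integrator
# ---------------------------------------------------------------------------


def pair_forces_bulk(
    d: np.ndarray,
    u: np.ndarray,
    ni: np.ndarray,
    nj: np.ndarray,
    same_object: np.ndarray,
    p: Params,
):
    """Per-pair force and torque arrays for directed pairs j -> i.

    Parameters are parallel arrays over pairs: distances ``d``, unit vectors
    ``u`` (i to j), normals ``ni``/``nj``, and a same-object mask.  Returns
    ``(F, T)`` where ``F = F_dist + F_plane`` and ``T`` is the tilt torque.

    Two classes of pair get repulsion only (no bond, no planar force, no
    torque): surfels of different objects (surface exclusion), and
    same-object surfels with *anti-parallel* normals (``n_i . n_j < 0``).
    The latter are opposite faces of the sheet meeting face-to-face — e.g.
    the two sides of a collapsing neck — not in-plane neighbours: bonding or
    torquing across such a contact would glue and crumple the sheet instead
    of letting it pinch off.
    """
    x = d / p.d0
    full = same_object & (np.einsum("ij,ij->i", ni, nj) >= 0.0)
    fmag = np.where(
        full,
        p.k_dist * f_dist_profile(np.maximum(x, 1e-12)),
        p.k_dist * _repulsive_profile(x),
    )
    F = fmag[:, None] * u
    udotn = np.einsum("ij,ij->i", u, ni + nj)
    F = F + np.where(full, p.k_plane * udotn, 0.0)[:, None] * ni
    tmag = np.where(full, -p.k_tilt * np.einsum("ij,ij->i", ni, u), 0.0)
    T = tmag[:, None] * u
    return F, T


def image_forces_bulk(img: Image3D, P: np.ndarray, N: np.ndarray, p: Params):
    """Vectorised image force for many surfels.

    Returns ``(F, at_max)``: (n, 3) force array and boolean attachment mask.
    """
    n = len(P)
    if n == 0:
        return np.zeros((0, 3)), np.zeros(0, dtype=bool)
    s_vals, vals = _profile(img, P, N, p.band)
    inside = ~np.isnan(vals)
    any_inside = inside.any(axis=1)
    ranked = np.where(inside, vals, -np.inf)
    vmax = ranked.max(axis=1)
    vmin = np.where(inside, vals, np.inf).min(axis=1)
    flat = ~any_inside | (vmax - vmin < FLAT_TOL)
    s_star = s_vals[np.argmax(ranked, axis=1)]
    at_max = ~flat & (np.abs(s_star) <= AT_MAX_TOL)
    mag = np.where(
        flat,
        p.f_pressure,
        np.where(at_max, 0.0, np.sign(s_star) * p.f_signal + p.f_pressure),
    )
    return mag[:, None] * N, at_max
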