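"""Synthetic test volumes for benchmarking the segmentation.

All phantoms render *shells* (membrane-like bright surfaces of ~2 voxel
thickness and intensity 1 on a zero background), because the image force
seeks intensity maxima — the natural contrast of fluorescently labelled
membranes.  Optional zero-mean Gaussian noise is added from a seeded RNG, so
a given spec is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .image import Image3D

__all__ = [
    "PhantomSpec",
    "sphere_shell",
    "plane_with_hole",
    "torus",
    "two_spheres",
    "generate",
]

DEFAULT_THICKNESS = 2.0


@dataclasses.dataclass
class PhantomSpec:
    """Declarative phantom description (config-file friendly)."""

    kind: str  # sphere_shell | plane_with_hole | torus | two_spheres
    size: tuple[int, int, int] = (100, 100, 100)
    center: Sequence[float] | None = None
    radius: float | None = None
    centers: Sequence[Sequence[float]] | None = None
    radii: Sequence[float] | None = None
    r_hole: float | None = None
    r_major: float | None = None
    r_minor: float | None = None
    thickness: float = DEFAULT_THICKNESS
    noise_sigma: float = 0.0
    rng_seed: int = 0


def _coords(size: tuple[int, int, int]):
    nx, ny, nz = size
    z, y, x = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    return x.astype(float), y.astype(float), z.astype(float)


def _finish(binary: np.ndarray, noise_sigma: float, seed: int) -> Image3D:
    vol = binary.astype(float)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sigma, size=vol.shape)
    return Image3D(voxels=vol)


def sphere_shell(
    size: tuple[int, int, int] = (100, 100, 100),
    center: Sequence[float] | None = None,
    radius: float = 30.0,
    thickness: float = DEFAULT_THICKNESS,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Image3D:
    """Hollow sphere: voxels within thickness/2 of radius R set to 1."""
    if center is None:
        center = [(s - 1) / 2.0 for s in size]
    cx, cy, cz = center
    half = min(size) / 2.0
    if radius + thickness / 2.0 + 2.0 > half:
        raise ValueError("sphere shell does not fit inside the volume with margin")
    x, y, z = _coords(size)
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
    shell = np.abs(r - radius) <= thickness / 2.0
    return _finish(shell, noise_sigma, seed)


def plane_with_hole(
    size: tuple[int, int, int] = (100, 100, 100),
    r_hole: float = 10.0,
    thickness: float = DEFAULT_THICKNESS,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Image3D:
    """Volume cut in half by a bright mid-plane slab pierced by a round hole.

    The slab sits at z = size_z/2; the hole is centred on the volume's
    central (z) axis with radius ``r_hole``.
    """
    if not (r_hole < 45):
        raise ValueError("r_hole must be < 45 voxels")
    nx, ny, nz = size
    zc = nz / 2.0
    x, y, z = _coords(size)
    slab = np.abs(z - zc) <= thickness / 2.0
    rho = np.sqrt((x - (nx - 1) / 2.0) ** 2 + (y - (ny - 1) / 2.0) ** 2)
    plane = slab & (rho >= r_hole)
    return _finish(plane, noise_sigma, seed)


def torus(
    size: tuple[int, int, int] = (100, 100, 100),
    center: Sequence[float] | None = None,
    r_major: float = 25.0,
    r_minor: float = 10.0,
    thickness: float = DEFAULT_THICKNESS,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Image3D:
    """Hollow torus shell around a spine circle of radius ``r_major``."""
    if center is None:
        center = [(s - 1) / 2.0 for s in size]
    cx, cy, cz = center
    if r_major + r_minor + thickness / 2.0 + 2.0 > min(size) / 2.0:
        raise ValueError("torus does not fit inside the volume with margin")
    x, y, z = _coords(size)
    rho = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    dist_spine = np.sqrt((rho - r_major) ** 2 + (z - cz) ** 2)
    shell = np.abs(dist_spine - r_minor) <= thickness / 2.0
    return _finish(shell, noise_sigma, seed)


def two_spheres(
    size: tuple[int, int, int] = (100, 100, 100),
    centers: Sequence[Sequence[float]] = ((30, 50, 50), (70, 50, 50)),
    radii: Sequence[float] = (15.0, 15.0),
    thickness: float = DEFAULT_THICKNESS,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Image3D:
    """Union of two disjoint sphere shells (fission test target)."""
    (c1, c2), (r1, r2) = centers, radii
    gap = np.linalg.norm(np.asarray(c1, float) - np.asarray(c2, float))
    if gap <= r1 + r2 + thickness:
        raise ValueError("the two spheres must be disjoint (shells included)")
    x, y, z = _coords(size)
    shells = np.zeros(x.shape, dtype=bool)
    for (cx, cy, cz), rad in zip(centers, radii):
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        shells |= np.abs(r - rad) <= thickness / 2.0
    return _finish(shells, noise_sigma, seed)


def generate(spec: PhantomSpec) -> Image3D:
    """Build the phantom described by a :class:`PhantomSpec`."""
    if spec.kind == "sphere_shell":
        return sphere_shell(
            spec.size, spec.center, spec.radius if spec.radius else 30.0,
            spec.thickness, spec.noise_sigma, spec.rng_seed
        )
    if spec.kind == "plane_with_hole":
        return plane_with_hole(
            spec.size, spec.r_hole if spec.r_hole is not None else 10.0,
            spec.thickness, spec.noise_sigma, spec.rng_seed
        )
    if spec.kind == "torus":
        return torus(
            spec.size, spec.center,
            spec.r_major if spec.r_major else 25.0,
            spec.r_minor if spec.r_minor else 10.0,
            spec.thickness, spec.noise_sigma, spec.rng_seed
        )
    if spec.kind == "two_spheres":
        return two_spheres(
            spec.size,
            spec.centers if spec.centers else ((30, 50, 50), (70, 50, 50)),
            spec.radii if spec.radii else (15.0, 15.0),
            spec.thickness, spec.noise_sigma, spec.rng_seed
        )
    raise ValueError(f"unknown phantom kind: {spec.kind!r}")
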