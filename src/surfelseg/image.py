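"""3D intensity volumes with physical voxel spacing.

Coordinates are 0-based, voxel-centre continuous coordinates ``(x, y, z)``:
voxel ``[z, y, x]`` of the array has its centre at coordinate ``(x, y, z)``.
All surfel positions live in this frame; physical spacing only matters when
sampling along a normal in anisotropic data and when reporting measurements
in physical units.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = ["Image3D", "load_volume", "save_volume"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Image3D:
    """Scalar intensity volume.

    Attributes
    ----------
    voxels:
        3D float array indexed ``[z, y, x]`` (z = page index of a TIFF stack).
    spacing:
        Physical units per voxel along ``(x, y, z)``; strictly positive.
    """

    voxels: np.ndarray
    spacing: np.ndarray = dataclasses.field(
        default_factory=lambda: np.ones(3, dtype=float)
    )

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive floats (sx, sy, sz)")

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.voxels.shape
        return nx, ny, nz

    def sample(self, position) -> float | None:
        """Trilinear intensity at a continuous (x, y, z) position.

        Returns ``None`` for positions outside the volume (callers rank the
        marker below every in-volume intensity).
        """
        v = self.sample_many(np.asarray(position, dtype=float)[None, :])[0]
        return None if np.isnan(v) else float(v)

    def sample_many(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised trilinear sampling; NaN marks out-of-volume positions.

        ``positions`` is (N, 3) in (x, y, z) order.  A position is outside
        when any coordinate leaves ``[0, dim - 1]`` (the voxel-centre span).
        """
        positions = np.asarray(positions, dtype=float)
        nz, ny, nx = self.voxels.shape
        coords = positions[:, ::-1].T  # (3, N) in (z, y, x) order
        vals = ndimage.map_coordinates(
            self.voxels, coords, order=1, mode="nearest"
        )
        hi = np.array([nx - 1, ny - 1, nz - 1], dtype=float)
        outside = np.any((positions < 0) | (positions > hi), axis=1)
        vals = vals.astype(float)
        vals[outside] = np.nan
        return vals


def load_volume(path: str | Path) -> Image3D:
    """Read a multi-page grayscale TIFF as an :class:`Image3D`.

    The page index becomes z.  Voxel spacing is taken from the TIFF
    resolution tags (x, y) and the ImageJ ``spacing`` metadata entry (z) when
    present; otherwise (1, 1, 1) is used and a warning logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            spacing = _spacing_from_tiff(tf)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"{path} is not a readable TIFF volume: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise ValueError(f"{path} is a single 2D page; a z-stack is required")
    if arr.ndim != 3:
        raise ValueError(f"{path} has unsupported dimensionality {arr.ndim}")
    if spacing is None:
        logger.warning("%s carries no spacing metadata; assuming (1, 1, 1)", path)
        spacing = np.ones(3)
    return Image3D(voxels=arr.astype(float), spacing=spacing)


def _spacing_from_tiff(tf: "tifffile.TiffFile") -> np.ndarray | None:
    page = tf.pages[0]
    sx = sy = None
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is not None and yres is not None:
        xr = xres.value[0] / xres.value[1]
        yr = yres.value[0] / yres.value[1]
        if xr > 0 and yr > 0:
            sx, sy = 1.0 / xr, 1.0 / yr
    sz = None
    meta = tf.imagej_metadata
    if meta and "spacing" in meta:
        sz = float(meta["spacing"])
    if sx is None:
        return None
    return np.array([sx, sy, sz if sz is not None else 1.0], dtype=float)


def save_volume(img: Image3D, path: str | Path) -> None:
    """Write an :class:`Image3D` as an ImageJ-style multi-page float TIFF."""
    path = Path(path)
    sx, sy, sz = img.spacing
    tifffile.imwrite(
        path,
        img.voxels.astype(np.float32),
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": float(sz), "unit": "pixel", "axes": "ZYX"},
    )
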