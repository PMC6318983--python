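"""Fixed-radius near-neighbour search over surfel positions.

A uniform hash grid with cell edge equal to the sphere-of-influence radius
(``alpha * d0``).  With the contract ``radius <= cell_size``, scanning the
27-cell neighbourhood of the query point is exact, so both single queries and
the bulk all-pairs enumeration used by the integrator are closed-ball exact
(ties at distance == radius are included).

The index is a snapshot: it is rebuilt from scratch at the start of every
integration step.
"""

from __future__ import annotations

import numpy as np

from .core import SurfelSystem

__all__ = ["NeighborIndex", "build_index"]

_OFFSETS = np.array(
    [(ox, oy, oz) for ox in (-1, 0, 1) for oy in (-1, 0, 1) for oz in (-1, 0, 1)],
    dtype=np.int64,
)


class NeighborIndex:
    """Uniform-grid spatial index answering fixed-radius queries.

    Parameters
    ----------
    positions:
        (N, 3) float array of points (continuous voxel coordinates).
    ids:
        (N,) int array of surfel ids (parallel to ``positions``).
    cell_size:
        Grid cell edge; queries with radius above this are rejected.
    """

    def __init__(self, positions: np.ndarray, ids: np.ndarray, cell_size: float):
        positions = np.asarray(positions, dtype=float)
        ids = np.asarray(ids, dtype=np.int64)
        if cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        bad = ~np.all(np.isfinite(positions), axis=1) if len(positions) else np.zeros(0, bool)
        if np.any(bad):
            raise ValueError(
                f"non-finite position for surfel id(s) {ids[bad].tolist()}"
            )
        self.positions = positions
        self.ids = ids
        self.cell_size = float(cell_size)
        n = len(positions)
        if n == 0:
            self._cells = np.empty((0, 3), dtype=np.int64)
            self._min = np.zeros(3, dtype=np.int64)
            self._dims = np.ones(3, dtype=np.int64)
            self._keys = np.empty(0, dtype=np.int64)
            self._order = np.empty(0, dtype=np.int64)
            self._uniq = np.empty(0, dtype=np.int64)
            self._starts = np.empty(0, dtype=np.int64)
            self._counts = np.empty(0, dtype=np.int64)
            return
        cells = np.floor(positions / self.cell_size).astype(np.int64)
        self._cells = cells
        self._min = cells.min(axis=0)
        # pad dims by 2 and shift by 1 so that +-1 cell offsets stay inside
        # the raveling range and cannot alias another cell's key
        self._dims = cells.max(axis=0) - self._min + 3
        self._keys = self._ravel(cells)
        self._order = np.argsort(self._keys, kind="stable")
        sorted_keys = self._keys[self._order]
        self._uniq, self._starts = np.unique(sorted_keys, return_index=True)
        self._counts = np.diff(np.append(self._starts, n))

    def _ravel(self, cells: np.ndarray) -> np.ndarray:
        s = cells - self._min + 1
        d = self._dims
        return (s[..., 0] * d[1] + s[..., 1]) * d[2] + s[..., 2]

    # -- introspection -------------------------------------------------

    @property
    def grid(self) -> dict[tuple[int, int, int], list[int]]:
        """Mapping cell -> list of surfel ids (built on demand)."""
        out: dict[tuple[int, int, int], list[int]] = {}
        for i in range(len(self.positions)):
            out.setdefault(tuple(self._cells[i]), []).append(int(self.ids[i]))
        return out

    def cell_of(self, surfel_id: int) -> tuple[int, int, int]:
        row = int(np.nonzero(self.ids == surfel_id)[0][0])
        return tuple(int(c) for c in self._cells[row])

    # -- queries -------------------------------------------------------

    def query_radius(
        self,
        center: np.ndarray,
        radius: float,
        exclude_id: int | None = None,
    ) -> np.ndarray:
        """Ids of all points with Euclidean distance <= radius from center.

        The closed ball is used (ties included).  ``radius`` must not exceed
        ``cell_size`` — the single-ring guarantee of the grid.
        """
        if radius > self.cell_size + 1e-12:
            raise ValueError(
                f"radius {radius} exceeds cell_size {self.cell_size}; "
                "rebuild the index with a larger cell"
            )
        if len(self.positions) == 0:
            return np.empty(0, dtype=np.int64)
        center = np.asarray(center, dtype=float)
        ccell = np.floor(center / self.cell_size).astype(np.int64)
        cand = self._rows_in_cells(ccell[None, :] + _OFFSETS)
        if len(cand) == 0:
            return np.empty(0, dtype=np.int64)
        d2 = np.sum((self.positions[cand] - center) ** 2, axis=1)
        ok = d2 <= radius * radius + 1e-12
        found = self.ids[cand[ok]]
        if exclude_id is not None:
            found = found[found != exclude_id]
        return found

    def _rows_in_cells(self, cells: np.ndarray) -> np.ndarray:
        """Row indices of all points lying in any of the given cells."""
        keys = self._ravel(cells)
        pos = np.searchsorted(self._uniq, keys)
        pos = np.minimum(pos, len(self._uniq) - 1) if len(self._uniq) else pos
        hit = len(self._uniq) > 0
        if not hit:
            return np.empty(0, dtype=np.int64)
        found = self._uniq[pos] == keys
        starts = self._starts[pos[found]]
        counts = self._counts[pos[found]]
        tot = int(counts.sum())
        if tot == 0:
            return np.empty(0, dtype=np.int64)
        base = np.repeat(starts, counts)
        reset = np.repeat(np.cumsum(counts) - counts, counts)
        return self._order[base + np.arange(tot) - reset]

    def pairs_within(self, radius: float):
        """All directed pairs (i, j), i != j, with distance <= radius.

        Returns row-index arrays ``(I, J, d, u)`` where ``d`` are distances
        and ``u`` the unit vectors from i to j.  Exact under the
        ``radius <= cell_size`` contract.
        """
        if radius > self.cell_size + 1e-12:
            raise ValueError("radius exceeds cell_size")
        n = len(self.positions)
        if n < 2:
            e = np.empty(0, dtype=np.int64)
            return e, e.copy(), np.empty(0), np.empty((0, 3))
        I_parts, J_parts = [], []
        for off in _OFFSETS:
            tkeys = self._ravel(self._cells + off)
            pos = np.searchsorted(self._uniq, tkeys)
            pos = np.minimum(pos, len(self._uniq) - 1)
            found = self._uniq[pos] == tkeys
            qrows = np.nonzero(found)[0]
            starts = self._starts[pos[found]]
            counts = self._counts[pos[found]]
            tot = int(counts.sum())
            if tot == 0:
                continue
            base = np.repeat(starts, counts)
            reset = np.repeat(np.cumsum(counts) - counts, counts)
            jrows = self._order[base + np.arange(tot) - reset]
            irows = np.repeat(qrows, counts)
            I_parts.append(irows)
            J_parts.append(jrows)
        I = np.concatenate(I_parts)
        J = np.concatenate(J_parts)
        keep = I != J
        I, J = I[keep], J[keep]
        diff = self.positions[J] - self.positions[I]
        d2 = np.einsum("ij,ij->i", diff, diff)
        keep = d2 <= radius * radius + 1e-12
        I, J, diff = I[keep], J[keep], diff[keep]
        d = np.sqrt(d2[keep])
        with np.errstate(invalid="ignore", divide="ignore"):
            u = diff / d[:, None]
        return I, J, d, u


def build_index(system: SurfelSystem, cell_size: float | None = None) -> NeighborIndex:
    """Index all surfels of a system (any state) on a uniform grid.

    The default cell edge is the sphere-of-influence radius ``alpha * d0``.
    """
    if cell_size is None:
        cell_size = system.params.d_threshold
    return NeighborIndex(system.positions, system.ids, cell_size)
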