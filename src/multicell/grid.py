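"""Uniform interaction grid: O(n) candidate-neighbor lookup for mechanics.

Cells are registered in cubic mechanics voxels of edge length
``edge`` (um), chosen at least as large as the maximum cell-cell
interaction distance so that the 27-voxel Moore neighborhood of a
cell's voxel is guaranteed to contain every cell within interaction
range.  The candidate-set size is bounded by
``27 * V_mech / min cell volume``, which keeps the total cost of
velocity computation linear in the number of cells.
"""

from __future__ import annotations

import itertools

import numpy as np

from multicell.errors import ConfigurationError

DEFAULT_MECHANICS_VOXEL_EDGE = 30.0

_MOORE = [np.array(d) for d in itertools.product((-1, 0, 1), repeat=3)]
#: half of the 26 neighbor offsets (lexicographically positive), used to
#: enumerate each unordered voxel pair exactly once
_HALF_OFFSETS = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]


class InteractionGrid:
    """Per-voxel cell registries plus a cell -> voxel map.

    The grid is conceptually unbounded: registries are created lazily
    for occupied voxels, so cells may wander outside any fixed domain
    without losing mechanics.
    """

    def __init__(self, edge: float = DEFAULT_MECHANICS_VOXEL_EDGE):
        if edge <= 0:
            raise ConfigurationError(f"mechanics voxel edge must be positive, got {edge}")
        self.edge = float(edge)
        self._voxels: dict[tuple, list] = {}
        self._cell_voxel: dict[int, tuple] = {}

    @property
    def voxel_volume(self) -> float:
        return self.edge**3

    def voxel_coords(self, position) -> tuple[int, int, int]:
        return tuple(int(np.floor(p / self.edge)) for p in position)

    # ---------------------------------------------------------- registration

    def register(self, cell) -> None:
        key = self.voxel_coords(cell.position)
        self._voxels.setdefault(key, []).append(cell)
        self._cell_voxel[cell.id] = key

    def deregister(self, cell) -> None:
        key = self._cell_voxel.pop(cell.id, None)
        if key is None:
            return
        bucket = self._voxels.get(key, [])
        bucket[:] = [c for c in bucket if c.id != cell.id]
        if not bucket:
            self._voxels.pop(key, None)

    def update(self, cell) -> None:
        """Re-register a cell whose position may have changed."""
        key = self.voxel_coords(cell.position)
        old = self._cell_voxel.get(cell.id)
        if key == old:
            return
        self.deregister(cell)
        self._voxels.setdefault(key, []).append(cell)
        self._cell_voxel[cell.id] = key

    def rebuild(self, cells) -> None:
        self._voxels.clear()
        self._cell_voxel.clear()
        for cell in cells:
            self.register(cell)

    def __contains__(self, cell) -> bool:
        return cell.id in self._cell_voxel

    def __len__(self) -> int:
        return len(self._cell_voxel)

    # --------------------------------------------------------------- queries

    def cells_in_voxel(self, key: tuple) -> list:
        return self._voxels.get(tuple(key), [])

    def neighbor_candidates(self, cell) -> list:
        """All cells (other than ``cell``) registered in the 27-voxel
        Moore neighborhood of the cell's voxel.  This is a superset of
        every cell within interaction range provided the voxel edge is
        at least the maximum interaction distance."""
        key = self._cell_voxel.get(cell.id)
        if key is None:
            key = self.voxel_coords(cell.position)
        out = []
        for d in _MOORE:
            for other in self._voxels.get((key[0] + d[0], key[1] + d[1], key[2] + d[2]), ()):
                if other.id != cell.id:
                    out.append(other)
        return out

    def max_candidate_count(self) -> int:
        """Largest |N(i)| over all registered cells (audit helper)."""
        best = 0
        for key, bucket in self._voxels.items():
            neigh = 0
            for d in _MOORE:
                neigh += len(self._voxels.get(
                    (key[0] + d[0], key[1] + d[1], key[2] + d[2]), ()))
            for _ in bucket:
                best = max(best, neigh - 1)
        return best


# ----------------------------------------------------------- vectorized pairs

def _range_concat(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate ``[arange(s, s+c) for s, c in zip(starts, counts)]``."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    reps = np.repeat(np.arange(starts.size), counts)
    ends = np.cumsum(counts)
    within = np.arange(total) - np.repeat(ends - counts, counts)
    return starts[reps] + within


def candidate_pairs(positions: np.ndarray, edge: float) -> tuple[np.ndarray, np.ndarray]:
    """Unordered candidate pairs (i, j) of cells whose mechanics voxels
    are identical or Moore-adjacent; each pair appears exactly once.

    Fully vectorized; used by the mechanics phase each step.  The
    result is a superset of all pairs within interaction range when
    ``edge`` is at least the maximum interaction distance.
    """
    n = len(positions)
    if n < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    coords = np.floor(np.asarray(positions) / edge).astype(np.int64)
    coords -= coords.min(axis=0) - 1      # pad by one ring: offsets never wrap
    dims = coords.max(axis=0) + 2
    v = (coords[:, 0] * dims[1] + coords[:, 1]) * dims[2] + coords[:, 2]
    order = np.argsort(v, kind="stable")
    sv = v[order]

    pi: list[np.ndarray] = []
    pj: list[np.ndarray] = []

    # pairs within the same voxel
    starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
    group_counts = np.diff(np.r_[starts, sv.size])
    group_end = np.repeat(starts + group_counts, group_counts)
    p = np.arange(n)
    later = group_end - p - 1
    flat = _range_concat(p + 1, later)
    pi.append(order[np.repeat(p, later)])
    pj.append(order[flat])

    # pairs across each unordered adjacent-voxel pair
    for off in _HALF_OFFSETS:
        dv = (off[0] * dims[1] + off[1]) * dims[2] + off[2]
        target = v + dv
        left = np.searchsorted(sv, target, side="left")
        right = np.searchsorted(sv, target, side="right")
        counts = right - left
        if counts.any():
            pi.append(np.repeat(np.arange(n), counts))
            pj.append(order[_range_concat(left, counts)])

    return np.concatenate(pi), np.concatenate(pj)
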