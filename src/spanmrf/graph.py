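"""Spot neighbor graphs for array-based and imaging-based platforms.

Array platforms (classic ST, 10x Visium) index spots on an integer grid; the
neighbor relation is the lattice adjacency. Imaging platforms (osmFISH,
MERFISH) provide Euclidean cell centroids; the neighbor relation is a
symmetrized k-nearest-neighbor graph (default ``k=15``).

Grid conventions
----------------
* ``array_grid_square`` (classic ST): rook adjacency — up to 4 neighbors at
  ``(row±1, col)`` and ``(row, col±1)``.
* ``array_grid_hex`` (Visium "array" coordinates, where column parity
  alternates with row parity): up to 6 neighbors at ``(row, col±2)`` and
  ``(row±1, col±1)``.

Graphs are stored 0-based as per-spot neighbor index sets; they are always
symmetric with no self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpotCoordinates",
    "NeighborGraph",
    "build_knn_graph",
    "build_grid_graph",
    "neighbor_type_counts",
]

GRID_MODES = ("array_grid_square", "array_grid_hex")

# neighbor offsets on the Visium hex lattice in array coordinates
_HEX_OFFSETS = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))
_SQUARE_OFFSETS = ((0, -1), (0, 1), (-1, 0), (1, 0))


@dataclass(frozen=True)
class SpotCoordinates:
    """Per-spot positions: integer ``(row, col)`` for grids, float ``(x, y)``
    for Euclidean platforms."""

    positions: np.ndarray
    mode: str = "euclidean"
    spot_ids: list[str] | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n_spots, 2) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if self.mode not in GRID_MODES + ("euclidean",):
            raise ValueError(f"unknown coordinate mode {self.mode!r}")
        if self.mode in GRID_MODES:
            if not np.allclose(pos, np.round(pos)):
                raise ValueError("grid coordinates must be integers")
            keys = {tuple(p) for p in np.round(pos).astype(int)}
            if len(keys) != pos.shape[0]:
                raise ValueError("grid positions must be unique per spot")
        object.__setattr__(self, "positions", pos)

    @property
    def n_spots(self) -> int:
        return self.positions.shape[0]


@dataclass
class NeighborGraph:
    """Symmetric adjacency over spots, stored as a list of neighbor sets."""

    n_spots: int
    adjacency: list[set[int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.adjacency) != self.n_spots:
            raise ValueError("adjacency length must equal n_spots")
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if not (0 <= j < self.n_spots):
                    raise ValueError(f"neighbor index {j} out of range")
                if j == i:
                    raise ValueError(f"self-loop at spot {i}")
                if i not in self.adjacency[j]:
                    raise ValueError(f"asymmetric edge ({i}, {j})")

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency], dtype=int)

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        """Unordered edges as sorted (i, j) pairs with i < j."""
        return [(i, j) for i in range(self.n_spots) for j in self.adjacency[i] if i < j]

    def neighbor_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (indptr, indices) view with sorted neighbor lists."""
        indptr = np.zeros(self.n_spots + 1, dtype=np.int64)
        for i, nbrs in enumerate(self.adjacency):
            indptr[i + 1] = indptr[i] + len(nbrs)
        indices = np.empty(indptr[-1], dtype=np.int64)
        for i, nbrs in enumerate(self.adjacency):
            indices[indptr[i]:indptr[i + 1]] = sorted(nbrs)
        return indptr, indices


def build_knn_graph(coords: SpotCoordinates, k: int = 15) -> NeighborGraph:
    """Symmetrized k-nearest-neighbor graph on Euclidean coordinates.

    Each spot is linked to its ``k`` nearest neighbors by Euclidean distance;
    the relation is then symmetrized by union, so degrees of at least ``k``
    are possible. Distance ties are broken in favor of the lower spot index,
    making the construction deterministic. Default ``k=15``.
    """
    if coords.mode != "euclidean":
        raise ValueError("build_knn_graph requires euclidean coordinates")
    n = coords.n_spots
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n_spots, got k={k}, n_spots={n}")
    pos = coords.positions
    adjacency: list[set[int]] = [set() for _ in range(n)]
    # chunked brute force keeps memory bounded and tie-breaking exact
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = ((pos[start:stop, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        # stable argsort on distance -> ties resolved by lower index
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        for local, i in enumerate(rows):
            for j in order[local]:
                adjacency[i].add(int(j))
                adjacency[int(j)].add(int(i))
    return NeighborGraph(n_spots=n, adjacency=adjacency)


def build_grid_graph(coords: SpotCoordinates) -> NeighborGraph:
    """Lattice adjacency for array platforms; missing spots are simply absent."""
    if coords.mode not in GRID_MODES:
        raise ValueError("build_grid_graph requires a grid coordinate mode")
    offsets = _SQUARE_OFFSETS if coords.mode == "array_grid_square" else _HEX_OFFSETS
    pos = np.round(coords.positions).astype(int)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(pos)}
    adjacency: list[set[int]] = [set() for _ in range(coords.n_spots)]
    for i, (r, c) in enumerate(pos):
        for dr, dc in offsets:
            j = index.get((int(r) + dr, int(c) + dc))
            if j is not None:
                adjacency[i].add(j)
                adjacency[j].add(i)
    return NeighborGraph(n_spots=coords.n_spots, adjacency=adjacency)


def neighbor_type_counts(graph: NeighborGraph, z: np.ndarray, K: int) -> np.ndarray:
    """Tabulate u[i, l] = number of neighbors of spot i with label l.

    Labels are 0-based codes in ``[0, K)``. Row i sums to the degree of i.
    """
    z = np.asarray(z)
    if len(z) != graph.n_spots:
        raise ValueError("label vector length must equal n_spots")
    if z.size and (z.min() < 0 or z.max() >= K):
        raise ValueError(f"labels must lie in [0, {K})")
    u = np.zeros((graph.n_spots, K), dtype=np.int64)
    for i, nbrs in enumerate(graph.adjacency):
        for j in nbrs:
            u[i, z[j]] += 1
    return u
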