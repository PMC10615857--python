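"""Sparse adjacency graphs over pixel/voxel coordinate sets.

Used for contact-run arc lengths, 3D contact-patch geodesic diameters and
skeleton path lengths.  Edge weights are physical Euclidean distances.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra


def _neighbor_offsets(ndim: int, reach: int = 1) -> np.ndarray:
    offs = [o for o in product(range(-reach, reach + 1), repeat=ndim) if any(o)]
    return np.array(offs, dtype=np.int64)


def adjacency_graph(
    coords: np.ndarray, spacing: tuple[float, ...], reach: int = 1
) -> csr_matrix:
    """Weighted adjacency over integer grid coordinates.

    Two elements are adjacent when their index offset is within a
    Chebyshev distance of ``reach`` (reach=1 gives 8-/26-connectivity).
    Weights are Euclidean distances under ``spacing``.
    """
    coords = np.asarray(coords, dtype=np.int64)
    n = coords.shape[0]
    sp = np.asarray(spacing, dtype=float)
    index = {tuple(c): i for i, c in enumerate(coords)}
    rows, cols, weights = [], [], []
    for off in _neighbor_offsets(coords.shape[1], reach):
        w = float(np.sqrt(((off * sp) ** 2).sum()))
        shifted = coords + off
        for i, c in enumerate(shifted):
            j = index.get(tuple(c))
            if j is not None:
                rows.append(i)
                cols.append(j)
                weights.append(w)
    return csr_matrix((weights, (rows, cols)), shape=(n, n))


def graph_components(graph: csr_matrix) -> tuple[int, np.ndarray]:
    return connected_components(graph, directed=False)


def geodesic_diameter(graph: csr_matrix, n_sweeps: int = 3) -> float:
    """Approximate longest shortest path via repeated farthest-point sweeps.

    Exact on trees; a tight lower bound on general graphs (convex patches
    in practice).  Unreachable pairs are ignored (call per component).
    """
    n = graph.shape[0]
    if n == 0:
        return 0.0
    if n == 1:
        return 0.0
    src = 0
    best = 0.0
    for _ in range(n_sweeps):
        dist = dijkstra(graph, directed=False, indices=src)
        dist[~np.isfinite(dist)] = -1.0
        far = int(np.argmax(dist))
        if dist[far] <= best:
            break
        best = float(dist[far])
        src = far
    return best


def path_between(graph: csr_matrix, i: int, j: int) -> tuple[float, list[int]]:
    """Shortest path length and node sequence between two nodes."""
    dist, pred = dijkstra(
        graph, directed=False, indices=i, return_predecessors=True
    )
    if not np.isfinite(dist[j]):
        raise ValueError("nodes are not connected")
    path = [j]
    while path[-1] != i:
        path.append(int(pred[path[-1]]))
    path.reverse()
    return float(dist[j]), path


def farthest_pair(graph: csr_matrix, n_sweeps: int = 3) -> tuple[float, int, int]:
    """Geodesic diameter with its endpoint node indices."""
    n = graph.shape[0]
    if n <= 1:
        return 0.0, 0, 0
    src, best, pair = 0, 0.0, (0, 0)
    for _ in range(n_sweeps):
        dist = dijkstra(graph, directed=False, indices=src)
        dist[~np.isfinite(dist)] = -1.0
        far = int(np.argmax(dist))
        if dist[far] <= best:
            break
        best = float(dist[far])
        pair = (src, far)
        src = far
    return best, pair[0], pair[1]
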