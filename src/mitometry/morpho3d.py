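"""3D mitochondrial architecture from label volumes.

Volume is the exact voxel count times the physical voxel volume.
Surface area comes from a 0.5-level marching-cubes isosurface with
anisotropy-aware spacing (voxel-face counting overestimates curved
surfaces by ~50% and is deliberately avoided).

Skeleton-based metrics resample anisotropic volumes to an isotropic grid
(nearest-neighbour, at the finest pitch) before 3D thinning; lengths are
reported in physical units.  Object "length" is the longest geodesic
along the centerline graph plus the local radius at each of its two
endpoints (end-cap correction); blob-like objects fall back to the 3D
Feret diameter with a flag.

MOAS (mitochondria-on-a-string) detection segments the radius profile of
the longest centerline path into bulbs and thin connecting tunnels; all
thresholds are parameters since no numeric definition exists upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.measure import marching_cubes, mesh_surface_area
from skimage.morphology import skeletonize

from .core import NM_PER_UM, LabelMap, LabelMapError

_26_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


@dataclass
class MoasParams:
    tunnel_radius_frac: float = 0.35
    min_tunnel_length_nm: float = 200.0
    min_bulb_radius_nm: float = 100.0
    min_bulbs: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.tunnel_radius_frac < 1):
            raise ValueError("tunnel_radius_frac must be in (0, 1)")
        if self.min_tunnel_length_nm <= 0 or self.min_bulb_radius_nm <= 0:
            raise ValueError("lengths must be positive")
        if self.min_bulbs < 2:
            raise ValueError("min_bulbs must be >= 2")


def moas_rule(
    bulb_radius_nm: float,
    tunnel_radius_nm: float,
    tunnel_length_nm: float,
    n_bulbs: int,
    params: MoasParams | None = None,
) -> bool:
    """Analytic MOAS decision for idealized beads-on-string geometry.

    Used by the phantom generator to derive construction labels for
    parameter-recovery tests.
    """
    p = params or MoasParams()
    return (
        n_bulbs >= p.min_bulbs
        and bulb_radius_nm >= p.min_bulb_radius_nm
        and tunnel_length_nm >= p.min_tunnel_length_nm
        and tunnel_radius_nm <= p.tunnel_radius_frac * bulb_radius_nm
    )


@dataclass
class MitoRecord3D:
    object_id: int
    volume_um3: float
    surface_area_um2: float
    length_um: float = float("nan")
    feret_length_um: float = float("nan")
    length_is_feret_fallback: bool = False
    junction_count: int = 0
    hyperbranched: bool = False
    moas: bool = False
    tunnel_segments: int = 0


@dataclass
class SkeletonGraph:
    """Centerline graph of one labelled object.

    ``graph`` is an undirected networkx graph whose nodes are ints with
    attributes ``coord_nm`` (z, y, x physical) and ``radius_nm`` (interior
    distance-transform value); edges carry ``length_nm``.
    """

    graph: nx.Graph
    object_id: int
    iso_spacing_nm: float
    degenerate: bool = False

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def endpoints(self) -> list[int]:
        return [n for n, d in self.graph.degree() if d == 1]

    def junction_nodes(self) -> list[int]:
        return [n for n, d in self.graph.degree() if d >= 3]


# ---------------------------------------------------------------------------
# volume & surface


def measure_objects_3d(map_: LabelMap) -> list[MitoRecord3D]:
    """Per-object volume (exact) and marching-cubes surface area."""
    if map_.dims != 3:
        raise LabelMapError("measure_objects_3d requires a 3D label map")
    ids = map_.object_ids()
    if ids.size == 0:
        raise LabelMapError("label volume contains no objects")
    spacing = map_.calibration.spacing(3)
    vox_um3 = map_.calibration.voxel_volume_nm3 / NM_PER_UM**3
    out = []
    for oid in ids:
        mask = map_.mask(int(oid))
        vol = int(mask.sum()) * vox_um3
        out.append(
            MitoRecord3D(
                object_id=int(oid),
                volume_um3=vol,
                surface_area_um2=surface_area_um2(mask, spacing),
            )
        )
    return out


def surface_area_um2(
    mask: np.ndarray,
    spacing_nm: tuple[float, float, float],
    smooth_sigma_vox: float = 1.0,
) -> float:
    """0.5-level isosurface area of a binary mask, in μm².

    The mask is lightly Gaussian-smoothed (default 1.0 voxel) before
    meshing: marching cubes on a raw binary volume produces a staircased
    surface that overestimates curved areas by ~8%.
    """
    padded = np.pad(mask, 2).astype(float)
    if smooth_sigma_vox > 0:
        smoothed = ndimage.gaussian_filter(padded, smooth_sigma_vox)
        # tiny objects can be smoothed below the level; fall back to binary
        if smoothed.max() > 0.5:
            padded = smoothed
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing_nm)
    return float(mesh_surface_area(verts, faces)) / NM_PER_UM**2


def feret_diameter_3d_um(mask: np.ndarray, spacing_nm: tuple[float, float, float]) -> float:
    """Max caliper over the hull of boundary-voxel corners (physical)."""
    struct = ndimage.generate_binary_structure(3, 1)
    boundary = mask & ~ndimage.binary_erosion(mask, struct, border_value=0)
    coords = np.argwhere(boundary).astype(float)
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    sp = np.asarray(spacing_nm)
    offs = np.array(
        [[a, b, c] for a in (-0.5, 0.5) for b in (-0.5, 0.5) for c in (-0.5, 0.5)]
    )
    corners = (coords[:, None, :] + offs[None, :, :]).reshape(-1, 3) * sp
    if coords.shape[0] <= 2:
        d = np.linalg.norm(corners[:, None] - corners[None, :], axis=-1)
        return float(d.max()) / NM_PER_UM
    hull = ConvexHull(corners)
    pts = corners[hull.vertices]
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return float(d.max()) / NM_PER_UM


# ---------------------------------------------------------------------------
# skeletonization


def _resample_isotropic(mask: np.ndarray, spacing_nm: tuple[float, float, float]):
    iso = float(min(spacing_nm))
    factors = tuple(s / iso for s in spacing_nm)
    if np.allclose(factors, 1.0):
        return mask, iso
    out = ndimage.zoom(mask.astype(np.uint8), zoom=factors, order=0).astype(bool)
    return out, iso


def skeletonize_object(map_: LabelMap, object_id: int) -> SkeletonGraph:
    """Thin one object to a centerline graph with per-node radii."""
    if map_.dims != 3:
        raise LabelMapError("skeletonize_object requires a 3D label map")
    mask = map_.mask(object_id)
    if not mask.any():
        raise LabelMapError(f"object {object_id} not present")
    spacing = map_.calibration.spacing(3)
    iso_mask, iso_nm = _resample_isotropic(mask, spacing)
    dt = ndimage.distance_transform_edt(iso_mask) * iso_nm

    extents = [int(np.ptp(ax)) + 1 for ax in np.nonzero(iso_mask)]
    if all(e < 3 for e in extents):
        g = nx.Graph()
        com = np.array(ndimage.center_of_mass(iso_mask))
        g.add_node(
            0,
            coord_nm=tuple(com * iso_nm),
            radius_nm=float(dt.max()),
        )
        return SkeletonGraph(g, object_id, iso_nm, degenerate=True)

    skel = skeletonize(iso_mask)
    coords = np.argwhere(skel)
    if coords.shape[0] == 0:  # thinning can erase tiny objects entirely
        g = nx.Graph()
        com = np.array(ndimage.center_of_mass(iso_mask))
        g.add_node(0, coord_nm=tuple(com * iso_nm), radius_nm=float(dt.max()))
        return SkeletonGraph(g, object_id, iso_nm, degenerate=True)

    index = {tuple(c): i for i, c in enumerate(coords)}
    g = nx.Graph()
    for i, c in enumerate(coords):
        g.add_node(
            i,
            coord_nm=tuple(np.asarray(c, dtype=float) * iso_nm),
            radius_nm=float(max(dt[tuple(c)], iso_nm / 2.0)),
        )
    for c, i in index.items():
        for off in _26_OFFSETS:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            j = index.get(nb)
            if j is not None and j > i:
                w = float(np.linalg.norm(np.asarray(off, dtype=float))) * iso_nm
                g.add_edge(i, j, length_nm=w)
    return SkeletonGraph(g, object_id, iso_nm)


def _longest_path(g: nx.Graph) -> tuple[float, list[int]]:
    """Longest geodesic (double-sweep; exact on trees) in nm."""
    nodes = list(g.nodes)
    if len(nodes) < 2:
        return 0.0, nodes
    src = nodes[0]
    best_len, best_path = 0.0, [src]
    for _ in range(3):
        lengths, paths = nx.single_source_dijkstra(g, src, weight="length_nm")
        far = max(lengths, key=lengths.get)
        if lengths[far] <= best_len:
            break
        best_len, best_path = lengths[far], paths[far]
        src = far
    return best_len, best_path


def _smoothed_polyline_length_nm(coords: np.ndarray, window: int = 5) -> float:
    """Arc length of a voxel path after boxcar smoothing.

    A digital 26-connected path overestimates the length of oblique
    smooth curves by up to ~8% (zigzag); a short moving average of the
    node coordinates removes the artifact without shortening straight
    runs.
    """
    if len(coords) < 2:
        return 0.0
    if len(coords) > window >= 3:
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.pad(coords, ((pad, pad), (0, 0)), mode="edge")
        coords = np.column_stack(
            [np.convolve(padded[:, k], kernel, mode="valid") for k in range(3)]
        )
    return float(np.linalg.norm(np.diff(coords, axis=0), axis=1).sum())


def object_length(skel: SkeletonGraph, map_: LabelMap | None = None) -> tuple[float, bool]:
    """Length of the object in μm.

    Returns ``(length_um, feret_fallback)``.  The primary estimate is the
    longest centerline geodesic (zigzag-smoothed) plus the endpoint radii
    as an end-cap correction; when the centerline is shorter than the
    local thickness (blob), the 3D Feret diameter of the object is used
    instead (requires ``map_``).
    """
    g = skel.graph
    length_nm, path = _longest_path(g)
    if path:
        r0 = g.nodes[path[0]]["radius_nm"]
        r1 = g.nodes[path[-1]]["radius_nm"]
        coords = np.array([g.nodes[n]["coord_nm"] for n in path])
        smooth_nm = _smoothed_polyline_length_nm(coords)
    else:
        r0 = r1 = 0.0
        smooth_nm = 0.0
    blob_like = skel.degenerate or length_nm < 2.0 * max(r0, r1)
    if blob_like and map_ is not None:
        feret = feret_diameter_3d_um(
            map_.mask(skel.object_id), map_.calibration.spacing(3)
        )
        return feret, True
    return (smooth_nm + r0 + r1) / NM_PER_UM, blob_like


def prune_spurs(skel: SkeletonGraph, min_spur_voxels: int = 3) -> SkeletonGraph:
    """Remove terminal branches shorter than ``min_spur_voxels`` voxels."""
    g = skel.graph.copy()
    min_len_nm = min_spur_voxels * skel.iso_spacing_nm
    changed = True
    while changed:
        changed = False
        for ep in [n for n, d in g.degree() if d == 1]:
            if ep not in g:
                continue
            # walk from the endpoint to the first junction
            path = [ep]
            length = 0.0
            cur, prev = ep, None
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if g.degree(cur) >= 3 or not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["length_nm"]
                prev, cur = cur, nxt
                path.append(cur)
                if g.degree(cur) >= 3:
                    break
            if g.degree(cur) >= 3 and length < min_len_nm:
                g.remove_nodes_from(path[:-1])
                changed = True
    return SkeletonGraph(g, skel.object_id, skel.iso_spacing_nm, skel.degenerate)


def branch_stats(
    skel: SkeletonGraph, hyperbranch_min_junctions: int = 3
) -> tuple[int, bool]:
    """Junction count after spur pruning, and the hyperbranching flag.

    Adjacent junction voxels (a thinning artifact at a single anatomical
    branch point) are merged: the count is the number of connected
    clusters of degree>=3 nodes.
    """
    pruned = prune_spurs(skel)
    g = pruned.graph
    jnodes = [n for n, d in g.degree() if d >= 3]
    if not jnodes:
        return 0, False
    sub = g.subgraph(jnodes)
    n_junctions = nx.number_connected_components(sub)
    return n_junctions, n_junctions >= hyperbranch_min_junctions


# ---------------------------------------------------------------------------
# MOAS / nanotunnels


def detect_moas(
    skel: SkeletonGraph, params: MoasParams | None = None
) -> tuple[bool, int]:
    """Detect mitochondria-on-a-string morphology on the main path.

    The radius profile of the longest centerline geodesic is segmented
    into bulbs (radius >= ``min_bulb_radius_nm``); each inter-bulb run is
    a tunnel when its median radius is <= ``tunnel_radius_frac`` x the
    median adjacent-bulb radius and its arc length is >=
    ``min_tunnel_length_nm``.  MOAS requires >= ``min_bulbs`` bulbs
    connected through >= 1 tunnel.
    """
    p = params or MoasParams()
    g = skel.graph
    _, path = _longest_path(g)
    if len(path) < 3:
        return False, 0
    radii = np.array([g.nodes[n]["radius_nm"] for n in path])
    seg_len = np.array(
        [g.edges[path[i], path[i + 1]]["length_nm"] for i in range(len(path) - 1)]
    )
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])

    is_bulb = radii >= p.min_bulb_radius_nm
    # maximal runs of bulb / non-bulb nodes
    runs: list[tuple[bool, int, int]] = []  # (bulbness, start, end inclusive)
    start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or is_bulb[i] != is_bulb[start]:
            runs.append((bool(is_bulb[start]), start, i - 1))
            start = i

    bulb_runs = [(s, e) for b, s, e in runs if b]
    if len(bulb_runs) < p.min_bulbs:
        return False, 0

    tunnels = 0
    for k in range(len(bulb_runs) - 1):
        s_prev, e_prev = bulb_runs[k]
        s_next, e_next = bulb_runs[k + 1]
        gap_lo, gap_hi = e_prev + 1, s_next - 1
        if gap_hi < gap_lo:
            continue
        gap_radii = radii[gap_lo : gap_hi + 1]
        gap_length = arc[s_next] - arc[e_prev]
        adjacent = np.concatenate(
            [radii[s_prev : e_prev + 1], radii[s_next : e_next + 1]]
        )
        if (
            gap_length >= p.min_tunnel_length_nm
            and np.median(gap_radii) <= p.tunnel_radius_frac * np.median(adjacent)
        ):
            tunnels += 1
    return tunnels >= 1, tunnels


# ---------------------------------------------------------------------------
# full pipeline


def analyze_objects_3d(
    map_: LabelMap,
    moas_params: MoasParams | None = None,
    hyperbranch_min_junctions: int = 3,
) -> list[MitoRecord3D]:
    """Volume, surface, length, branching and MOAS for every object."""
    records = measure_objects_3d(map_)
    spacing = map_.calibration.spacing(3)
    for rec in records:
        skel = skeletonize_object(map_, rec.object_id)
        length_um, fallback = object_length(skel, map_)
        rec.length_um = length_um
        rec.length_is_feret_fallback = fallback
        rec.feret_length_um = feret_diameter_3d_um(mask := map_.mask(rec.object_id), spacing)
        rec.junction_count, rec.hyperbranched = branch_stats(
            skel, hyperbranch_min_junctions
        )
        rec.moas, rec.tunnel_segments = detect_moas(skel, moas_params)
    return records


def records_to_frame(records: list[MitoRecord3D]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in records])


def skeleton_to_frame(skel: SkeletonGraph):
    """Edge list with physical coordinates, for CSV export."""
    import pandas as pd

    rows = []
    for u, v, data in skel.graph.edges(data=True):
        cu = skel.graph.nodes[u]["coord_nm"]
        cv = skel.graph.nodes[v]["coord_nm"]
        rows.append(
            {
                "object_id": skel.object_id,
                "z0_nm": cu[0], "y0_nm": cu[1], "x0_nm": cu[2],
                "z1_nm": cv[0], "y1_nm": cv[1], "x1_nm": cv[2],
                "length_nm": data["length_nm"],
                "radius0_nm": skel.graph.nodes[u]["radius_nm"],
                "radius1_nm": skel.graph.nodes[v]["radius_nm"],
            }
        )
    return pd.DataFrame(rows)
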