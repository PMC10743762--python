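"""Ordering of common-point clouds into a polyline and uniform resampling.

The intersection of the medial surfaces is an unordered, roughly
1-voxel-thick point cloud along the vessel axis.  It is ordered by building
a proximity graph in mm space, taking the minimum spanning tree of its
largest connected component, and walking the tree's longest geodesic path
(diameter, found by a double Dijkstra sweep) — short side spurs fall off
the diameter automatically.  The ordered polyline is then resampled at
uniform arc-length positions.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyExtractionError, InvalidCenterlineError
from .medial_fusion import CommonPointSet
from .vessel_io import BinaryVolume, Centerline

__all__ = ["order_points", "resample", "resample_polyline"]


def _farthest(tree: nx.Graph, source) -> tuple:
    lengths = nx.single_source_dijkstra_path_length(tree, source, weight="weight")
    # deterministic tie-break on node id
    node = max(lengths, key=lambda u: (lengths[u], u))
    return node, lengths[node]


def _bridge_components(graph: nx.Graph, pts: np.ndarray) -> None:
    """Connect graph components with single-linkage (closest-pair) edges.

    Every common point lies inside the vessel lumen, so a longitudinal gap
    between fragments is part of the same tube and can be spanned by its
    shortest crossing edge.
    """
    comps = [sorted(c) for c in nx.connected_components(graph)]
    while len(comps) > 1:
        comps.sort(key=len, reverse=True)
        main = comps[0]
        tree = cKDTree(pts[main])
        best = None
        for ci, comp in enumerate(comps[1:], start=1):
            dist, nearest = tree.query(pts[comp])
            k = int(np.argmin(dist))
            if best is None or dist[k] < best[0]:
                best = (float(dist[k]), main[int(nearest[k])], comp[k], ci)
        d, u, v, ci = best
        graph.add_edge(u, v, weight=d)
        comps[0] = main + comps.pop(ci)


def order_points(
    common: CommonPointSet, vol: BinaryVolume, tol_voxels: int = 1
) -> Centerline:
    """Order a common point set into the longest path through its MST.

    Neighboring points are connected when their mm distance is at most
    ``(2 * tol_voxels + 1)`` voxel diagonals, which bridges the lateral
    quantization jitter left by the per-axis snapping; remaining fragments
    are joined by their closest-pair edges.  The returned polyline is the
    longest geodesic path (graph diameter) of the minimum spanning tree,
    so short lateral spurs are dropped automatically.
    """
    if len(common) == 0:
        raise EmptyExtractionError("common point set is empty")
    if len(common) < 2:
        raise EmptyExtractionError("common point set has a single point")

    h = vol.voxel_size
    pts = vol.origin + common.voxels.astype(float) * h
    d_max = (2 * tol_voxels + 1) * np.sqrt(3.0) * h + 1e-9

    pairs = cKDTree(pts).query_pairs(d_max, output_type="ndarray")
    graph = nx.Graph()
    graph.add_nodes_from(range(pts.shape[0]))
    if pairs.shape[0]:
        w = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        graph.add_weighted_edges_from(
            (int(i), int(j), float(d)) for (i, j), d in zip(pairs, w)
        )
    _bridge_components(graph, pts)

    tree = nx.minimum_spanning_tree(graph, weight="weight")
    start, _ = _farthest(tree, 0)
    end, _ = _farthest(tree, start)
    path = nx.shortest_path(tree, start, end, weight="weight")
    return Centerline(pts[path])


def resample_polyline(xyz: np.ndarray, n: int, values: np.ndarray = None):
    """Piecewise-linear resampling of a polyline at uniform arc lengths.

    Returns ``(points, resampled_values, arc_positions)``; ``values`` (e.g.
    radii) are interpolated along the same arc-length parameter.  Endpoints
    are preserved exactly.
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[0] < 2 or n < 2:
        raise InvalidCenterlineError("resampling needs >= 2 points and n >= 2")
    seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise InvalidCenterlineError("cannot resample a zero-length line")
    s = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(s, arc, xyz[:, c]) for c in range(3)])
    out[0], out[-1] = xyz[0], xyz[-1]
    vals = None if values is None else np.interp(s, arc, np.asarray(values, float))
    return out, vals, s


def resample(line: Centerline, n: int = 1000) -> Centerline:
    """Resample a centerline to ``n`` uniformly spaced points along its length."""
    pts, _, _ = resample_polyline(line.xyz, n)
    return Centerline(pts)
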