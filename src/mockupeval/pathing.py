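"""Shortest obstacle-free paths via a visibility graph.

In a polygonal environment the Euclidean shortest path between two points
bends only at obstacle corners, so the shortest path through the free
space (room boundary eroded by the body radius, fixed footprints dilated
by it, mitred so everything stays polygonal) is found exactly by running
Dijkstra on the visibility graph over those corners.  This is both the
movement backbone of the scenario simulator and the baseline ("how long
did the walk need to be?") of the impediment detector.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.prepared import prep

from .errors import ReachabilityError
from .layout import RoomLayout, free_space

#: Free space is grown by this much (m) before visibility tests so that
#: segments lying exactly on the region boundary (corner-to-corner edges)
#: are not rejected by floating-point grazing.
_EPS = 1e-9


def _region_vertices(region) -> list[tuple[float, float]]:
    polys = [region] if isinstance(region, Polygon) else list(region.geoms)
    verts: list[tuple[float, float]] = []
    for poly in polys:
        verts.extend(poly.exterior.coords[:-1])
        for ring in poly.interiors:
            verts.extend(ring.coords[:-1])
    return [(float(x), float(y)) for x, y in verts]


def plan_path(
    start: tuple[float, float],
    goal: tuple[float, float],
    layout: RoomLayout,
    inflation: float = 0.0,
    extra_obstacles=(),
) -> list[tuple[float, float]]:
    """Shortest polyline from ``start`` to ``goal`` for a disc of radius
    ``inflation`` among walls and fixed footprints (plus any
    ``extra_obstacles`` polygons, e.g. a parked cart).

    Returns the vertex list, starting at ``start`` and ending at ``goal``;
    intermediate vertices sit on inflated-obstacle corners.  Raises
    :class:`ReachabilityError` if an endpoint is blocked or no path exists.
    """
    region = free_space(layout, inflation, extra_obstacles=extra_obstacles)
    grown = region.buffer(_EPS)
    prepared = prep(grown)
    for name, pt in (("start", start), ("goal", goal)):
        if not prepared.covers(Point(pt)):
            raise ReachabilityError(
                f"{name} point {pt} is blocked (inside an inflated obstacle "
                f"or outside the inflated boundary) in layout {layout.layout_id!r}"
            )

    direct = LineString([start, goal])
    if prepared.covers(direct):
        return [tuple(map(float, start)), tuple(map(float, goal))]

    nodes = [tuple(map(float, start)), tuple(map(float, goal))]
    nodes += _region_vertices(region)
    arr = np.asarray(nodes)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            seg = LineString([nodes[i], nodes[j]])
            if seg.length == 0.0:
                continue
            if prepared.covers(seg):
                graph.add_edge(i, j, weight=float(np.hypot(*(arr[i] - arr[j]))))
    try:
        idx_path = nx.dijkstra_path(graph, 0, 1, weight="weight")
    except nx.NetworkXNoPath:
        raise ReachabilityError(
            f"no obstacle-free path from {start} to {goal} in layout "
            f"{layout.layout_id!r} at inflation {inflation}"
        ) from None
    return [nodes[i] for i in idx_path]


def path_length(polyline) -> float:
    pts = np.asarray(polyline, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def walk_positions(polyline, speed: float, dt: float) -> np.ndarray:
    """Positions sampled every ``dt`` while traversing ``polyline`` at
    constant ``speed``; includes the start and always finishes exactly at
    the final vertex (the last step may be short).  Used by the simulator."""
    if speed <= 0 or dt <= 0:
        raise ValueError("speed and dt must be > 0")
    pts = np.asarray(polyline, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = int(math.floor(total / (speed * dt)))
    dists = speed * dt * np.arange(n + 1)
    if total - dists[-1] > 1e-9:
        dists = np.append(dists, total)
    xs = np.interp(dists, cum, pts[:, 0])
    ys = np.interp(dists, cum, pts[:, 1])
    return np.column_stack([xs, ys])
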