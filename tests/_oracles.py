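"""Independent oracles used by the test suite.

These deliberately re-derive quantities along different routes than the
implementation: a lattice Dijkstra for shortest-path lengths, a plain
per-leg loop for the impediment predicate, and rasterized areas for
polygon dilation.
"""

from __future__ import annotations

import math

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import LineString, Point

from mockupeval.layout import free_space

# 32-connected lattice moves: max overestimate of Euclidean length ~1%.
_MOVES = [
    (1, 0), (0, 1), (1, 1), (1, -1),
    (2, 1), (1, 2), (2, -1), (1, -2),
    (3, 1), (1, 3), (3, -1), (1, -3),
    (3, 2), (2, 3), (3, -2), (2, -3),
]


def grid_dijkstra_length(layout, start, goal, inflation, cell=0.05):
    """Shortest-path length via Dijkstra on a fine lattice over the free
    space; independent of the visibility-graph implementation."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    region = free_space(layout, inflation)
    minx, miny, maxx, maxy = layout.polygon.bounds
    nx = int(round((maxx - minx) / cell))
    ny = int(round((maxy - miny) / cell))
    xs = minx + (np.arange(nx) + 0.5) * cell
    ys = miny + (np.arange(ny) + 0.5) * cell
    gx, gy = np.meshgrid(xs, ys)  # shape (ny, nx)
    free = shapely.contains_xy(region, gx.ravel(), gy.ravel()).reshape(ny, nx)

    def shift(mask, dx, dy):
        out = np.zeros_like(mask)
        ys0, ys1 = max(dy, 0), ny + min(dy, 0)
        xs0, xs1 = max(dx, 0), nx + min(dx, 0)
        out[ys0:ys1, xs0:xs1] = mask[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
        return out

    rows, cols, weights = [], [], []
    idx = np.arange(ny * nx).reshape(ny, nx)
    for dx, dy in _MOVES:
        ok = free & shift(free, dx, dy)
        # the move must not cut through blocked cells
        m = max(abs(dx), abs(dy))
        for k in range(1, m):
            fx, fy = k * dx / m, k * dy / m
            for ox, oy in {(math.floor(fx), math.floor(fy)), (math.ceil(fx), math.ceil(fy))}:
                ok &= shift(free, int(ox), int(oy))
        src = idx[ok]
        dst = src - dy * nx - dx
        rows.append(src)
        cols.append(dst)
        weights.append(np.full(len(src), math.hypot(dx, dy) * cell))
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ny * nx, ny * nx),
    )

    def nearest_free(pt):
        ix = int(np.clip(round((pt[0] - minx) / cell - 0.5), 0, nx - 1))
        iy = int(np.clip(round((pt[1] - miny) / cell - 0.5), 0, ny - 1))
        if free[iy, ix]:
            return iy, ix
        fy, fx = np.nonzero(free)
        d = (xs[fx] - pt[0]) ** 2 + (ys[fy] - pt[1]) ** 2
        k = int(np.argmin(d))
        return int(fy[k]), int(fx[k])

    siy, six = nearest_free(start)
    giy, gix = nearest_free(goal)
    dist = dijkstra(graph.tocsr(), directed=False, indices=siy * nx + six)
    core = float(dist[giy * nx + gix])
    if not np.isfinite(core):
        return math.inf
    snap_s = math.hypot(xs[six] - start[0], ys[siy] - start[1])
    snap_g = math.hypot(xs[gix] - goal[0], ys[giy] - goal[1])
    return core + snap_s + snap_g


def brute_force_impediment_legs(legs, log, config, layout):
    """Plain re-application of the impediment rule, leg by leg.

    Returns the set of (subject, t_start, to_object) keys of legs judged
    impediments, using explicit loops and the same rule semantics:
    strict > for the ratio, >= for the absolute excess, and corridor
    intrusion (baseline dilated by 2 x person_radius) by any other person
    or movable object during the leg's time window.
    """
    flagged = set()
    corridor_r = 2 * config.person_radius
    for leg in legs:
        if leg.excluded or not leg.baseline_path:
            continue
        ratio_hit = leg.actual_length > config.detour_ratio_threshold * leg.baseline_length
        excess_hit = leg.actual_length - leg.baseline_length >= config.detour_length_threshold
        if not (ratio_hit and excess_hit):
            continue
        baseline = LineString(leg.baseline_path)
        intruded = False
        for track in log.tracks:
            if track.subject_id == leg.subject_id:
                continue
            lo = max(leg.t_start, track.t_start)
            hi = min(leg.t_end, track.t_end)
            if hi <= lo:
                continue
            t = lo
            while t <= hi + 1e-9:
                p = track.position_at(min(t, hi))
                if track.subject_kind == "agent":
                    if baseline.distance(Point(p)) <= corridor_r + config.person_radius:
                        intruded = True
                        break
                else:
                    fp = layout.object_by_id(track.subject_id).polygon
                    c = fp.centroid
                    moved = affinity.translate(fp, xoff=p[0] - c.x, yoff=p[1] - c.y)
                    if baseline.distance(moved) <= corridor_r:
                        intruded = True
                        break
                t += 0.25
            if intruded:
                break
        if not intruded:
            tracked = {t.subject_id for t in log.tracks}
            for obj in layout.movable_objects():
                if obj.object_id not in tracked and baseline.distance(obj.polygon) <= corridor_r:
                    intruded = True
                    break
        if intruded:
            flagged.add((leg.subject_id, round(leg.t_start, 6), leg.to_object))
    return flagged


def polyline_length(points) -> float:
    pts = np.asarray(points, dtype=float)
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T))) if len(pts) > 1 else 0.0


def rasterized_area(geom, cell=0.02) -> float:
    """Area of a shapely geometry by counting fine-grid cell centres."""
    minx, miny, maxx, maxy = geom.bounds
    xs = np.arange(minx - cell, maxx + cell, cell) + cell / 2
    ys = np.arange(miny - cell, maxy + cell, cell) + cell / 2
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
    return float(inside.sum()) * cell * cell
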