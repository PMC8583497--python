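"""Automated behavioural data collection from trajectory logs.

Codes the measures used in simulation-based mock-up evaluations of
healthcare rooms:

* **visits** — dwell intervals inside an object's interaction zone,
* **legs** — travelled paths between consecutive visits/doorway
  crossings, with actual and baseline (shortest feasible) lengths,
* **impediments** — legs more than 20% *and* at least 1 m longer than the
  baseline, attributable to a person or movable object that intruded the
  baseline corridor,
* **bumps** — unintended contacts between entities, debounced,
* **interruptions** — annotation-driven attention diversions during an
  open task,
* **task completion times** — room entry to room exit per agent,
* **link analysis** — dwell-time occupancy grid and high-traffic cells.

Note on scale: the 20% ratio test is invariant under scaling all
coordinates by a factor k, but the 1 m absolute test is not — a scaled-
down floor plan will under-detect impediments unless
``detour_length_threshold`` is scaled with it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import nearest_points

from .config import AnalysisConfig
from .errors import ReachabilityError, ValidationError
from .layout import RoomLayout, free_space
from .pathing import path_length, plan_path
from .trajectory import Track, TrajectoryLog, resample_track

#: Speed for dwell detection: positions are box-smoothed over SPEED_SMOOTH
#: seconds, then centrally differenced over SPEED_WINDOW.  Smoothing first
#: suppresses per-sample tracking jitter (which otherwise dominates the
#: two-point estimate at dwell speeds) without hiding real walking.
SPEED_WINDOW = 0.5
SPEED_SMOOTH = 0.4
#: Legs are measured on a track resampled at this interval (s) so polyline
#: length reflects the walked route, not accumulated jitter.
MEASURE_DT = 0.5
#: Two consecutive visits at the same object closer than this (m) of
#: intermediate movement emit no leg.
MIN_LEG_LENGTH = 0.05


@dataclass(frozen=True)
class Visit:
    subject_id: str
    object_id: str
    t_start: float
    t_end: float

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValidationError("visit must have t_end > t_start")


@dataclass(frozen=True)
class Leg:
    """One travelled path between two anchors (visits or doorway crossings)."""

    subject_id: str
    from_object: str
    to_object: str
    t_start: float
    t_end: float
    actual_length: float
    baseline_length: float
    baseline_path: tuple[tuple[float, float], ...] = ()
    subtask_tag: str = ""
    excluded: bool = False  # baseline unreachable; skipped by detectors


@dataclass(frozen=True)
class BehaviorEvent:
    kind: str  # bump | impediment | interruption
    t: float
    participants: tuple[str, ...]
    context: str = ""
    leg: Leg | None = None

    def __post_init__(self):
        if self.kind not in ("bump", "impediment", "interruption"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "bump" and len(self.participants) != 2:
            raise ValidationError("bump must have exactly 2 participants")


@dataclass
class OccupancyGrid:
    origin: tuple[float, float]
    cell: float
    dwell: np.ndarray  # seconds per cell, shape (ny, nx)
    high_traffic_cells: set[tuple[int, int]]
    paths: dict[str, np.ndarray] = field(default_factory=dict)
    in_room_seconds: dict[str, float] = field(default_factory=dict)

    def total_dwell(self) -> float:
        return float(self.dwell.sum())


@dataclass
class MeasureReport:
    """Per-scenario, per-layout counts and times for every measure."""

    scenario_id: str
    layout_id: str
    n_interruptions: int
    n_bumps: int
    n_impediments: int
    n_impediments_by_subtask: dict[str, int]
    task_times: dict[str, float]
    occupancy: OccupancyGrid
    config: AnalysisConfig
    events: tuple[BehaviorEvent, ...] = ()
    legs: tuple[Leg, ...] = ()
    visits: tuple[Visit, ...] = ()

    def summary(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "layout_id": self.layout_id,
            "n_interruptions": self.n_interruptions,
            "n_bumps": self.n_bumps,
            "n_impediments": self.n_impediments,
            "n_impediments_by_subtask": dict(self.n_impediments_by_subtask),
            "task_times": {k: round(v, 3) for k, v in self.task_times.items()},
        }


# ---------------------------------------------------------------------------
# visits


def _box_smooth(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x
    pad = np.concatenate([np.repeat(x[0], k), x, np.repeat(x[-1], k)])
    kernel = np.ones(k) / k
    return np.convolve(pad, kernel, mode="same")[k:-k]


def _smoothed_speed(ts: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Central-difference speed over SPEED_WINDOW on box-smoothed positions
    (clamped at the ends); assumes a uniform time grid."""
    if len(ts) > 1:
        dt = float(ts[1] - ts[0])
        k = max(1, int(round(SPEED_SMOOTH / dt)))
        xy = np.column_stack([_box_smooth(xy[:, 0], k), _box_smooth(xy[:, 1], k)])
    half = SPEED_WINDOW / 2.0
    t_lo = np.clip(ts - half, ts[0], ts[-1])
    t_hi = np.clip(ts + half, ts[0], ts[-1])
    x_lo = np.interp(t_lo, ts, xy[:, 0])
    x_hi = np.interp(t_hi, ts, xy[:, 0])
    y_lo = np.interp(t_lo, ts, xy[:, 1])
    y_hi = np.interp(t_hi, ts, xy[:, 1])
    span = np.maximum(t_hi - t_lo, 1e-9)
    return np.hypot(x_hi - x_lo, y_hi - y_lo) / span


def segment_visits(
    log: TrajectoryLog, layout: RoomLayout, config: AnalysisConfig
) -> list[Visit]:
    """Dwell-based visit coding.

    A visit opens when a subject's smoothed speed stays below
    ``dwell_speed_threshold`` for at least ``dwell_min_duration`` while
    inside an object's interaction zone, and closes when the subject
    leaves that zone.  Overlapping zones are tied-broken to the object
    with the nearest footprint.  Visits are non-overlapping per subject.
    """
    if not layout.objects:
        return []
    dt = 1.0 / log.sample_rate
    zones = [(obj, obj.zone()) for obj in layout.objects]
    visits: list[Visit] = []
    for track in log.agent_tracks():
        rt = resample_track(track, dt)
        ts = rt.times()
        xy = rt.positions()
        speed = _smoothed_speed(ts, xy)
        slow = speed < config.dwell_speed_threshold
        inside = np.zeros((len(ts), len(zones)), dtype=bool)
        for j, (obj, zone) in enumerate(zones):
            inside[:, j] = shapely.contains_xy(zone, xy[:, 0], xy[:, 1])
        i = 0
        n = len(ts)
        while i < n:
            if not (slow[i] and inside[i].any()):
                i += 1
                continue
            # tie-break: nearest footprint among zones containing the point
            candidates = np.flatnonzero(inside[i])
            if len(candidates) == 1:
                j_star = int(candidates[0])
            else:
                p = Point(xy[i])
                j_star = int(
                    min(candidates, key=lambda j: zones[j][0].polygon.distance(p))
                )
            # extend the slow run while still inside the chosen zone
            k = i
            while k + 1 < n and slow[k + 1] and inside[k + 1, j_star]:
                k += 1
            if ts[k] - ts[i] + dt >= config.dwell_min_duration:
                # visit closes on zone exit, regardless of speed
                e = k
                while e + 1 < n and inside[e + 1, j_star]:
                    e += 1
                visits.append(
                    Visit(
                        subject_id=track.subject_id,
                        object_id=zones[j_star][0].object_id,
                        t_start=float(ts[i]),
                        t_end=float(ts[e]),
                    )
                )
                i = e + 1
            else:
                i = k + 1
    visits.sort(key=lambda v: (v.subject_id, v.t_start))
    return visits


# ---------------------------------------------------------------------------
# doorway crossings and task times


def doorway_crossings(track: Track, layout: RoomLayout) -> list[tuple[float, str, str]]:
    """(time, doorway name, 'in'|'out') for every boundary crossing through
    a doorway, in time order."""
    poly = layout.polygon
    xy = track.positions()
    ts = track.times()
    was_inside = shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
    crossings = []
    for i in range(len(ts) - 1):
        if was_inside[i] == was_inside[i + 1]:
            continue
        seg = LineString([xy[i], xy[i + 1]])
        for dw in layout.doorways:
            if seg.distance(dw.segment) < 0.3:
                hit = seg.intersection(dw.segment)
                if not hit.is_empty:
                    frac = seg.project(hit.centroid) / max(seg.length, 1e-9)
                else:
                    frac = 0.5
                t_cross = float(ts[i] + frac * (ts[i + 1] - ts[i]))
                crossings.append(
                    (t_cross, dw.name, "in" if was_inside[i + 1] else "out")
                )
                break
    return crossings


def task_completion_times(log: TrajectoryLog, layout: RoomLayout) -> dict[str, float]:
    """Per agent: first inward doorway crossing to last outward crossing.

    Agents who never exit are timed to their last sample (with a warning);
    agents never observed inside the room are excluded (with a warning).
    """
    if not layout.doorways:
        raise ValidationError("layout has no doorways; task times undefined")
    times: dict[str, float] = {}
    poly = layout.polygon
    for track in log.agent_tracks():
        crossings = doorway_crossings(track, layout)
        entries = [c for c in crossings if c[2] == "in"]
        exits = [c for c in crossings if c[2] == "out"]
        if entries and exits:
            times[track.subject_id] = exits[-1][0] - entries[0][0]
        elif entries:
            warnings.warn(
                f"agent {track.subject_id!r} never exited; timing to last sample"
            )
            times[track.subject_id] = track.t_end - entries[0][0]
        else:
            xy = track.positions()
            if shapely.contains_xy(poly, xy[:, 0], xy[:, 1]).any():
                warnings.warn(
                    f"agent {track.subject_id!r} has no entry crossing; "
                    "timing from first sample"
                )
                t_exit = exits[-1][0] if exits else track.t_end
                times[track.subject_id] = t_exit - track.t_start
            else:
                warnings.warn(f"agent {track.subject_id!r} never inside the room; excluded")
    return times


# ---------------------------------------------------------------------------
# legs


def _subtask_tag_for(log: TrajectoryLog, subject_id: str, visit: Visit) -> str:
    for ev in log.events:
        if (
            ev.type == "note"
            and ev.subject_id == subject_id
            and ev.target == visit.object_id
            and ev.label.startswith("subtask=")
            and visit.t_start - 1.0 <= ev.t <= visit.t_end + 1.0
        ):
            return ev.label.split("=", 1)[1]
    return ""


def _segment_polyline(track: Track, t0: float, t1: float) -> np.ndarray:
    """Positions every MEASURE_DT within [t0, t1] (both endpoints included)."""
    n = max(1, int(math.ceil((t1 - t0) / MEASURE_DT)))
    grid = np.linspace(t0, t1, n + 1)
    ts = track.times()
    xy = track.positions()
    return np.column_stack(
        [np.interp(grid, ts, xy[:, 0]), np.interp(grid, ts, xy[:, 1])]
    )


def build_legs(
    visits: list[Visit],
    log: TrajectoryLog,
    layout: RoomLayout,
    config: AnalysisConfig,
) -> list[Leg]:
    """One leg per consecutive (visit | doorway crossing) pair per subject.

    ``actual_length`` is the walked polyline length between the two
    anchors; ``baseline_length`` is the shortest feasible path between the
    same endpoints among walls and fixed obstacles at body inflation —
    movable objects and people are deliberately excluded from the
    baseline, because they are precisely the potential causes of detours.
    """
    region = free_space(layout, config.person_radius)
    legs: list[Leg] = []
    by_subject: dict[str, list[Visit]] = {}
    for v in visits:
        by_subject.setdefault(v.subject_id, []).append(v)
    for track in log.agent_tracks():
        sid = track.subject_id
        anchors: list[tuple[float, float, str, str]] = []  # (t_start, t_end, ref, kind)
        for (t_c, name, _direction) in doorway_crossings(track, layout):
            anchors.append((t_c, t_c, name, "doorway"))
        for v in by_subject.get(sid, []):
            anchors.append((v.t_start, v.t_end, v.object_id, "visit"))
        anchors.sort()
        for (a, b) in zip(anchors, anchors[1:]):
            t0, ref_a, kind_a = a[1], a[2], a[3]
            t1, ref_b, kind_b = b[0], b[2], b[3]
            if t1 <= t0:
                continue
            poly = _segment_polyline(track, t0, t1)
            actual = path_length(poly)
            if kind_a == "visit" and kind_b == "visit" and ref_a == ref_b:
                if actual < MIN_LEG_LENGTH:
                    continue  # no intermediate movement: no leg
            start = tuple(poly[0])
            goal = tuple(poly[-1])
            # noise or an on-boundary crossing point can leave the anchor
            # marginally outside free space; snap to the nearest free point
            start = _snap_into(region, start)
            goal = _snap_into(region, goal)
            tag = ""
            if kind_b == "visit":
                visit_b = next(
                    v for v in by_subject[sid] if v.object_id == ref_b and v.t_start == b[0]
                )
                tag = _subtask_tag_for(log, sid, visit_b)
            try:
                bpath = plan_path(start, goal, layout, config.person_radius)
                blen = path_length(bpath)
            except ReachabilityError:
                warnings.warn(
                    f"baseline unreachable for leg {ref_a!r}->{ref_b!r} of "
                    f"{sid!r}; excluded from impediment analysis"
                )
                legs.append(
                    Leg(
                        subject_id=sid, from_object=ref_a, to_object=ref_b,
                        t_start=t0, t_end=t1, actual_length=actual,
                        baseline_length=float("nan"), subtask_tag=tag, excluded=True,
                    )
                )
                continue
            legs.append(
                Leg(
                    subject_id=sid, from_object=ref_a, to_object=ref_b,
                    t_start=t0, t_end=t1, actual_length=actual,
                    baseline_length=max(blen, 1e-9),
                    baseline_path=tuple((float(x), float(y)) for x, y in bpath),
                    subtask_tag=tag,
                )
            )
    return legs


def _snap_into(region, pt):
    p = Point(pt)
    if region.buffer(1e-9).covers(p):
        return pt
    nearest = nearest_points(region, p)[0]
    return (float(nearest.x), float(nearest.y))


# ---------------------------------------------------------------------------
# impediments


def _entity_positions(track: Track, t0: float, t1: float, step: float = 0.25) -> np.ndarray:
    lo = max(t0, track.t_start)
    hi = min(t1, track.t_end)
    if hi <= lo:
        return np.empty((0, 2))
    grid = np.arange(lo, hi + 1e-9, step)
    ts = track.times()
    xy = track.positions()
    return np.column_stack(
        [np.interp(grid, ts, xy[:, 0]), np.interp(grid, ts, xy[:, 1])]
    )


def detect_impediments(
    legs: list[Leg],
    log: TrajectoryLog,
    config: AnalysisConfig,
    layout: RoomLayout | None = None,
) -> list[BehaviorEvent]:
    """Impediment rule: actual > ratio x baseline (strict), excess >= 1 m,
    and a person or movable object intruded the baseline corridor
    (baseline path dilated by 2 x person_radius) during the leg.

    Participants are the impeded subject and the intruding entity.
    ``layout`` lets parked movable objects without tracks count as
    potential intruders at their layout position.
    """
    events: list[BehaviorEvent] = []
    tracked_ids = {t.subject_id for t in log.tracks}
    for leg in legs:
        if leg.excluded or not leg.baseline_path:
            continue
        if not leg.actual_length > config.detour_ratio_threshold * leg.baseline_length:
            continue
        if not leg.actual_length - leg.baseline_length >= config.detour_length_threshold:
            continue
        # attribution corridor: baseline dilated by 2 x person_radius; an
        # entity intrudes when its shape (disc or footprint) reaches it,
        # i.e. when its distance to the baseline polyline is small enough
        baseline = LineString(leg.baseline_path)
        corridor_r = 2 * config.person_radius
        intruder = None
        for track in log.tracks:
            if track.subject_id == leg.subject_id:
                continue
            pos = _entity_positions(track, leg.t_start, leg.t_end)
            if len(pos) == 0:
                continue
            if track.subject_kind == "agent":
                reach = corridor_r + config.person_radius
                if any(baseline.distance(Point(p)) <= reach for p in pos):
                    intruder = track.subject_id
                    break
            else:
                obj = layout.object_by_id(track.subject_id) if layout else None
                if obj is None:
                    if any(baseline.distance(Point(p)) <= corridor_r for p in pos):
                        intruder = track.subject_id
                        break
                else:
                    fp = obj.polygon
                    c = fp.centroid
                    for p in pos:
                        moved = affinity.translate(fp, xoff=p[0] - c.x, yoff=p[1] - c.y)
                        if baseline.distance(moved) <= corridor_r:
                            intruder = track.subject_id
                            break
                    if intruder:
                        break
        if intruder is None and layout is not None:
            for obj in layout.movable_objects():
                if obj.object_id in tracked_ids:
                    continue
                if baseline.distance(obj.polygon) <= corridor_r:
                    intruder = obj.object_id
                    break
        if intruder is not None:
            events.append(
                BehaviorEvent(
                    kind="impediment",
                    t=leg.t_start,
                    participants=(leg.subject_id, intruder),
                    context=leg.subtask_tag or f"{leg.from_object}->{leg.to_object}",
                    leg=leg,
                )
            )
    return events


# ---------------------------------------------------------------------------
# bumps


def _common_grid(log: TrajectoryLog) -> np.ndarray:
    dt = 1.0 / log.sample_rate
    return np.arange(log.t_start, log.t_end + dt / 2, dt)


def _grid_positions(track: Track, grid: np.ndarray) -> np.ndarray:
    """Positions on the grid; NaN where the track is not alive."""
    ts = track.times()
    xy = track.positions()
    out = np.full((len(grid), 2), np.nan)
    alive = (grid >= ts[0] - 1e-9) & (grid <= ts[-1] + 1e-9)
    out[alive, 0] = np.interp(grid[alive], ts, xy[:, 0])
    out[alive, 1] = np.interp(grid[alive], ts, xy[:, 1])
    return out


def _contact_runs(contact: np.ndarray, grid: np.ndarray, merge_gap: float):
    """Maximal contact intervals after merging gaps <= merge_gap."""
    idx = np.flatnonzero(contact)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if grid[i] - grid[prev] <= merge_gap + 1e-9:
            prev = i
        else:
            runs.append((grid[start], grid[prev]))
            start = prev = i
    runs.append((grid[start], grid[prev]))
    return runs


def detect_bumps(
    log: TrajectoryLog,
    layout: RoomLayout,
    config: AnalysisConfig,
    visits: list[Visit] | None = None,
) -> list[BehaviorEvent]:
    """Unintended-contact coding, debounced.

    Entities are agents (discs of ``person_radius``), tracked movable
    objects (footprints translated to the current pose) and untracked
    layout objects (static footprints).  Two entities are in contact when
    their shapes come within ``contact_margin``.  Contiguous contact of
    the same pair separated by gaps <= ``bump_merge_gap`` merges into one
    event.  A contact is *intended* — and excluded — when the agent is
    visiting, or en route to visit, that object: operating equipment
    requires touching it.
    """
    if visits is None:
        visits = segment_visits(log, layout, config)
    grid = _common_grid(log)
    r = config.person_radius
    margin = config.contact_margin

    entities: list[tuple[str, str, np.ndarray | None, Polygon | None]] = []
    tracked_ids = set()
    for track in log.tracks:
        tracked_ids.add(track.subject_id)
        pos = _grid_positions(track, grid)
        if track.subject_kind == "agent":
            entities.append((track.subject_id, "agent", pos, None))
        else:
            fp = layout.object_by_id(track.subject_id).polygon
            entities.append((track.subject_id, "object", pos, fp))
    for obj in layout.objects:
        if obj.object_id not in tracked_ids:
            entities.append((obj.object_id, "object", None, obj.polygon))

    visit_index: dict[str, list[Visit]] = {}
    for v in visits:
        visit_index.setdefault(v.subject_id, []).append(v)

    def intended(agent_id: str, object_id: str, t: float) -> bool:
        vs = visit_index.get(agent_id, [])
        for v in vs:
            if v.object_id == object_id and v.t_start <= t <= v.t_end:
                return True
        upcoming = [v for v in vs if v.t_start > t]
        if upcoming and min(upcoming, key=lambda v: v.t_start).object_id == object_id:
            return True
        return False

    events: list[BehaviorEvent] = []
    for i in range(len(entities)):
        for j in range(i + 1, len(entities)):
            id_a, kind_a, pos_a, fp_a = entities[i]
            id_b, kind_b, pos_b, fp_b = entities[j]
            if kind_a == "object" and kind_b == "object" and pos_a is None and pos_b is None:
                continue  # two parked objects: static geometry, not behaviour
            contact = _pair_contact(
                grid, kind_a, pos_a, fp_a, kind_b, pos_b, fp_b, r, margin
            )
            for (t0, t1) in _contact_runs(contact, grid, config.bump_merge_gap):
                if kind_a == "agent" and kind_b == "object" and intended(id_a, id_b, t0):
                    continue
                if kind_b == "agent" and kind_a == "object" and intended(id_b, id_a, t0):
                    continue
                events.append(
                    BehaviorEvent(
                        kind="bump", t=float(t0), participants=(id_a, id_b)
                    )
                )
    events.sort(key=lambda e: e.t)
    return events


def _pair_contact(grid, kind_a, pos_a, fp_a, kind_b, pos_b, fp_b, r, margin):
    n = len(grid)
    contact = np.zeros(n, dtype=bool)
    if kind_a == "agent" and kind_b == "agent":
        d = np.hypot(pos_a[:, 0] - pos_b[:, 0], pos_a[:, 1] - pos_b[:, 1])
        valid = ~np.isnan(d)
        contact[valid] = d[valid] <= 2 * r + margin
        return contact
    if kind_a == "agent" or kind_b == "agent":
        if kind_a == "agent":
            agent_pos, obj_pos, fp = pos_a, pos_b, fp_b
        else:
            agent_pos, obj_pos, fp = pos_b, pos_a, fp_a
        reach = fp.buffer(r + margin)
        if obj_pos is None:  # static object
            valid = ~np.isnan(agent_pos[:, 0])
            contact[valid] = shapely.contains_xy(
                reach, agent_pos[valid, 0], agent_pos[valid, 1]
            )
        else:
            c = fp.centroid
            rel_x = agent_pos[:, 0] - (obj_pos[:, 0] - c.x)
            rel_y = agent_pos[:, 1] - (obj_pos[:, 1] - c.y)
            valid = ~(np.isnan(rel_x) | np.isnan(agent_pos[:, 0]))
            contact[valid] = shapely.contains_xy(reach, rel_x[valid], rel_y[valid])
        return contact
    # object vs object (at least one tracked): per-sample polygon distance,
    # evaluated coarsely — carts move slowly and footprints are large
    ca = fp_a.centroid if fp_a is not None else None
    cb = fp_b.centroid if fp_b is not None else None
    for k in range(0, n, 2):
        pa = fp_a
        if pos_a is not None:
            if np.isnan(pos_a[k, 0]):
                continue
            pa = affinity.translate(fp_a, xoff=pos_a[k, 0] - ca.x, yoff=pos_a[k, 1] - ca.y)
        pb = fp_b
        if pos_b is not None:
            if np.isnan(pos_b[k, 0]):
                continue
            pb = affinity.translate(fp_b, xoff=pos_b[k, 0] - cb.x, yoff=pos_b[k, 1] - cb.y)
        if pa.distance(pb) <= margin:
            contact[k] = True
    return contact


# ---------------------------------------------------------------------------
# interruptions


def extract_interruptions(log: TrajectoryLog) -> list[BehaviorEvent]:
    """One event per interruption annotation inside the interrupted
    subject's open task window; annotations outside tasks are dropped with
    a warning."""
    subject_ids = {t.subject_id for t in log.tracks}
    windows: dict[str, list[list[float]]] = {}
    for ev in sorted(log.events, key=lambda e: e.t):
        if ev.type == "task_start":
            windows.setdefault(ev.subject_id, []).append([ev.t, math.inf])
        elif ev.type == "task_end":
            open_wins = [w for w in windows.get(ev.subject_id, []) if w[1] == math.inf]
            if open_wins:
                open_wins[-1][1] = ev.t
    events: list[BehaviorEvent] = []
    for ev in log.events:
        if ev.type != "interruption":
            continue
        if ev.subject_id not in subject_ids:
            raise ValidationError(
                f"interruption references unknown subject {ev.subject_id!r}"
            )
        in_task = any(
            w[0] <= ev.t <= w[1] for w in windows.get(ev.subject_id, [])
        )
        if not in_task:
            warnings.warn(
                f"interruption at t={ev.t} for {ev.subject_id!r} occurs outside "
                "any task; dropped"
            )
            continue
        interrupter = ev.target or "unknown"
        events.append(
            BehaviorEvent(
                kind="interruption",
                t=ev.t,
                participants=(interrupter, ev.subject_id),
                context=ev.label,
            )
        )
    return events


# ---------------------------------------------------------------------------
# link analysis


def link_analysis(
    log: TrajectoryLog, layout: RoomLayout, config: AnalysisConfig
) -> OccupancyGrid:
    """Dwell-time-per-cell occupancy over the boundary's bounding box.

    Each resampled agent sample contributes its sample interval to the
    cell containing it while inside the room, so total grid dwell equals
    total in-room time by construction.  High-traffic cells are those at
    or above ``high_traffic_percentile`` of positive-dwell cells.
    """
    minx, miny, maxx, maxy = layout.polygon.bounds
    cell = config.grid_cell
    if cell > (maxx - minx) or cell > (maxy - miny):
        raise ValueError("grid cell larger than the room")
    nx = int(math.ceil((maxx - minx) / cell))
    ny = int(math.ceil((maxy - miny) / cell))
    dwell = np.zeros((ny, nx))
    dt = 1.0 / log.sample_rate
    poly = layout.polygon
    paths: dict[str, np.ndarray] = {}
    in_room: dict[str, float] = {}
    for track in log.agent_tracks():
        rt = resample_track(track, dt)
        xy = rt.positions()
        paths[track.subject_id] = xy
        inside = shapely.contains_xy(poly, xy[:-1, 0], xy[:-1, 1])
        pts = xy[:-1][inside]
        in_room[track.subject_id] = float(inside.sum()) * dt
        if len(pts) == 0:
            continue
        ix = np.clip(((pts[:, 0] - minx) / cell).astype(int), 0, nx - 1)
        iy = np.clip(((pts[:, 1] - miny) / cell).astype(int), 0, ny - 1)
        np.add.at(dwell, (iy, ix), dt)
    positive = dwell[dwell > 0]
    high: set[tuple[int, int]] = set()
    if len(positive):
        thr = np.percentile(positive, config.high_traffic_percentile)
        ys, xs = np.nonzero(dwell >= thr)
        high = {(int(y), int(x)) for y, x in zip(ys, xs) if dwell[y, x] > 0}
    return OccupancyGrid(
        origin=(minx, miny), cell=cell, dwell=dwell,
        high_traffic_cells=high, paths=paths, in_room_seconds=in_room,
    )


def high_traffic_near(
    grid: OccupancyGrid, layout: RoomLayout, object_id: str, within: float = 0.75
) -> bool:
    """True if any high-traffic cell centre lies within ``within`` metres
    of the object's footprint (used to check congestion hot spots)."""
    fp = layout.object_by_id(object_id).polygon
    for (iy, ix) in grid.high_traffic_cells:
        cx = grid.origin[0] + (ix + 0.5) * grid.cell
        cy = grid.origin[1] + (iy + 0.5) * grid.cell
        if fp.distance(Point(cx, cy)) <= within:
            return True
    return False


# ---------------------------------------------------------------------------
# orchestration


def compute_measures(
    log: TrajectoryLog, layout: RoomLayout, config: AnalysisConfig | None = None
) -> MeasureReport:
    """Run the full coding pipeline on one log and collate a report."""
    if config is None:
        config = AnalysisConfig()
    visits = segment_visits(log, layout, config)
    legs = build_legs(visits, log, layout, config)
    impediments = detect_impediments(legs, log, config, layout=layout)
    bumps = detect_bumps(log, layout, config, visits=visits)
    interruptions = extract_interruptions(log)
    times = task_completion_times(log, layout)
    occupancy = link_analysis(log, layout, config)
    by_subtask: dict[str, int] = {}
    for ev in impediments:
        tag = ev.leg.subtask_tag if ev.leg else ""
        if tag:
            by_subtask[tag] = by_subtask.get(tag, 0) + 1
    return MeasureReport(
        scenario_id=log.scenario_id,
        layout_id=log.layout_id,
        n_interruptions=len(interruptions),
        n_bumps=len(bumps),
        n_impediments=len(impediments),
        n_impediments_by_subtask=by_subtask,
        task_times=times,
        occupancy=occupancy,
        config=config,
        events=tuple(interruptions + bumps + impediments),
        legs=tuple(legs),
        visits=tuple(visits),
    )
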