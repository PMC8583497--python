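"""Scripted multi-agent scenario simulator with planted ground truth.

Agents enter through a doorway, walk visibility-graph shortest paths
between scripted targets at a scripted speed, dwell at each target for a
drawn duration, and exit.  The script can plant three kinds of ground
truth, recorded in :class:`GroundTruth` so detectors can be tested for
recovery:

* **block obstructions** — a movable object parks across a corridor for a
  time window, forcing agents who travel then to take a measurably longer
  route (a planted impediment);
* **contact obstructions** — a movable object is placed brushing past an
  agent's path for an instant, guaranteeing an unintended contact (a
  planted bump);
* **interruptions** — annotation events emitted while the interrupted
  agent has an open task.

Only the resulting *measures* are meant to be realistic (who was where,
for how long, and what it forced others to do), not human locomotion:
avoidance is a simple priority rule (the earlier-entering agent has right
of way; the other pauses), and positional noise is small, per-sample and
truncated so planted geometry is preserved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from shapely import affinity
from shapely.geometry import Point, Polygon

from .config import AnalysisConfig
from .errors import FormatError, ReachabilityError, SimulationError, ValidationError
from .layout import RoomLayout, free_space
from .pathing import path_length, plan_path, walk_positions
from .trajectory import EventAnnotation, Track, TrackSample, TrajectoryLog

#: Planning inflation margin (m) added to the body radius so that clipped
#: positional noise can never push a sample inside a body-radius-inflated
#: fixed obstacle.
PLAN_MARGIN = 0.08
#: Per-sample positional noise: zero-mean normal, s.d. (m), truncated.
NOISE_SD = 0.02
NOISE_CLIP = 0.05
#: Standing distance (m) beyond the inflated footprint when using an object.
STANDOFF = 0.10
#: How far outside/inside the doorway agents start and finish (m).
DOOR_OFFSET = 0.4
#: Priority avoidance: pause when the next step would come this close (m)
#: to a higher-priority agent, for at most MAX_WAIT seconds.
AVOID_FACTOR = 0.1
MAX_WAIT = 8.0
#: A detour is recorded as planted ground truth only when the planned
#: route clears the default detection thresholds (ratio 1.20, excess 1 m)
#: with a margin, so ground truth is unambiguous under measurement noise.
PLANT_RATIO = 1.25
PLANT_EXCESS = 1.1
#: Speed of movable objects travelling between stations (m/s).
CART_SPEED = 1.0
#: Offset (m) from the agent's centre at which a contact obstruction is
#: parked: inside contact range (person_radius + footprint reach) but
#: outside overlap, robust to clipped noise.
CONTACT_OFFSET = 0.35


@dataclass(frozen=True)
class DwellSpec:
    """Dwell-duration distribution at a task step (seconds)."""

    mean: float
    spread: float = 0.0
    family: str = "fixed"  # fixed | uniform | lognormal

    def __post_init__(self):
        if self.mean <= 0:
            raise ValidationError("dwell mean must be > 0")
        if self.family not in ("fixed", "uniform", "lognormal"):
            raise ValidationError(f"unknown dwell family {self.family!r}")
        if self.spread < 0:
            raise ValidationError("dwell spread must be >= 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.family == "fixed" or self.spread == 0.0:
            return self.mean
        if self.family == "uniform":
            lo = max(0.5, self.mean - self.spread)
            return float(rng.uniform(lo, self.mean + self.spread))
        # lognormal parametrized by arithmetic mean and s.d.
        cv2 = (self.spread / self.mean) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, math.sqrt(sigma2)))


@dataclass(frozen=True)
class TaskStep:
    """Visit one target (object id or interaction-point name) and dwell."""

    target: str
    dwell: DwellSpec
    tag: str = ""


@dataclass(frozen=True)
class AgentScript:
    role: str
    entry_time: float
    entry_doorway: str
    steps: tuple[TaskStep, ...]
    speed: float = 1.2

    def __post_init__(self):
        if self.entry_time < 0:
            raise ValidationError(f"agent {self.role!r}: entry_time must be >= 0")
        if self.speed <= 0:
            raise ValidationError(f"agent {self.role!r}: speed must be > 0")


@dataclass(frozen=True)
class Obstruction:
    """A planted movable-object placement.

    ``mode="block"``: the object parks at ``location`` during
    [t_start, t_end], forcing detours.  ``mode="contact"``: the object is
    placed brushing ``target_role``'s path at ``t_start`` for a moment,
    guaranteeing a bump.
    """

    object_id: str
    mode: str
    t_start: float
    t_end: float
    location: tuple[float, float] | None = None
    target_role: str = ""

    def __post_init__(self):
        if self.mode not in ("block", "contact"):
            raise ValidationError(f"obstruction mode must be block|contact, got {self.mode!r}")
        if self.t_end < self.t_start:
            raise ValidationError("obstruction window must have t_end >= t_start")
        if self.mode == "block" and self.location is None:
            raise ValidationError("block obstruction requires a location")
        if self.mode == "contact" and not self.target_role:
            raise ValidationError("contact obstruction requires a target_role")


@dataclass(frozen=True)
class ScenarioScript:
    scenario_id: str
    agents: tuple[AgentScript, ...]
    interruption_plan: tuple[tuple[float, str, str], ...] = ()
    obstruction_plan: tuple[Obstruction, ...] = ()

    def __post_init__(self):
        roles = [a.role for a in self.agents]
        if len(set(roles)) != len(roles):
            raise ValidationError("agent roles must be unique within a scenario")


@dataclass(frozen=True)
class PlantedDetour:
    role: str
    step_index: int
    target: str
    t_start: float
    t_end: float
    baseline_length: float
    detour_length: float


@dataclass(frozen=True)
class PlantedBump:
    t: float
    role: str
    object_id: str


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually planted (for recovery testing)."""

    planted_detour_legs: tuple[PlantedDetour, ...] = ()
    planted_bump_events: tuple[PlantedBump, ...] = ()
    planted_interruptions: int = 0

    @property
    def planted_bumps(self) -> int:
        return len(self.planted_bump_events)

    def to_dict(self) -> dict:
        return {
            "planted_interruptions": self.planted_interruptions,
            "planted_bumps": self.planted_bumps,
            "planted_detour_legs": [
                {
                    "role": d.role,
                    "step_index": d.step_index,
                    "target": d.target,
                    "t_start": d.t_start,
                    "t_end": d.t_end,
                    "baseline_length": d.baseline_length,
                    "detour_length": d.detour_length,
                }
                for d in self.planted_detour_legs
            ],
            "planted_bump_details": [
                {"t": b.t, "role": b.role, "object_id": b.object_id}
                for b in self.planted_bump_events
            ],
        }


def _slug(role: str) -> str:
    return "".join(c.lower() if c.isalnum() else "_" for c in role).strip("_")


def _door_points(layout: RoomLayout, doorway_name: str):
    dw = layout.doorway_by_name(doorway_name)
    mx, my = dw.midpoint
    dx = dw.end[0] - dw.start[0]
    dy = dw.end[1] - dw.start[1]
    norm = math.hypot(dx, dy)
    nx, ny = -dy / norm, dx / norm
    cand_in = (mx + nx * DOOR_OFFSET, my + ny * DOOR_OFFSET)
    if layout.polygon.covers(Point(cand_in)):
        inside, outside = cand_in, (mx - nx * DOOR_OFFSET, my - ny * DOOR_OFFSET)
    else:
        inside = (mx - nx * DOOR_OFFSET, my - ny * DOOR_OFFSET)
        outside = cand_in
    return outside, inside


def _standing_point(layout: RoomLayout, target: str, from_pos, inflation: float):
    """Feasible point to stand at while using ``target``."""
    if target in layout.interaction_points:
        return layout.interaction_points[target]
    try:
        obj = layout.object_by_id(target)
    except KeyError:
        raise SimulationError(f"script target {target!r} not found in layout") from None
    region = free_space(layout, inflation)
    ring = obj.polygon.buffer(inflation + STANDOFF, join_style="round").exterior
    nearest = ring.interpolate(ring.project(Point(from_pos)))
    if region.covers(nearest):
        return (float(nearest.x), float(nearest.y))
    best, best_d = None, math.inf
    for frac in np.linspace(0.0, 1.0, 64, endpoint=False):
        pt = ring.interpolate(frac, normalized=True)
        if region.covers(pt):
            d = pt.distance(Point(from_pos))
            if d < best_d:
                best, best_d = (float(pt.x), float(pt.y)), d
    if best is None:
        raise SimulationError(
            f"no feasible standing point around target {target!r} in layout "
            f"{layout.layout_id!r}"
        )
    return best


def _snap_to_region(region, pt):
    p = Point(pt)
    if region.covers(p):
        return pt
    from shapely.ops import nearest_points

    nearest = nearest_points(region, p)[0]
    return (float(nearest.x), float(nearest.y))


def _obstacle_polygon(layout: RoomLayout, obstruction: Obstruction) -> Polygon:
    obj = layout.object_by_id(obstruction.object_id)
    fp = obj.polygon
    cx, cy = fp.centroid.x, fp.centroid.y
    lx, ly = obstruction.location
    return affinity.translate(fp, xoff=lx - cx, yoff=ly - cy)


class _CartTimeline:
    """Piecewise-stationary movable-object motion between stations.

    Travel between stations follows an obstacle-aware route (the cart is
    approximated by its circumscribed disc); when no such route exists the
    cart falls back to a straight line.
    """

    def __init__(self, park: tuple[float, float], layout: RoomLayout, radius: float):
        self.stations: list[tuple[float, float, tuple[float, float]]] = []
        self.park = park
        self.layout = layout
        self.radius = radius
        self._route_cache: dict = {}

    def add_station(self, t0: float, t1: float, pos: tuple[float, float]):
        self.stations.append((t0, t1, pos))
        self.stations.sort()

    def _route(self, a, b):
        key = (a, b)
        if key in self._route_cache:
            return self._route_cache[key]
        result = self._compute_route(a, b)
        self._route_cache[key] = result
        return result

    def _compute_route(self, a, b):
        # parked poses sit against walls, outside the cart-radius free
        # space; route between the nearest free points instead
        region = free_space(self.layout, self.radius)
        a2, b2 = _snap_to_region(region, a), _snap_to_region(region, b)
        try:
            poly = [a] + plan_path(a2, b2, self.layout, self.radius) + [b]
        except ReachabilityError:
            poly = [a, b]
        pts = np.asarray(poly, dtype=float)
        seg = np.hypot(*np.diff(pts, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        return pts, cum

    def position_at(self, t: float) -> tuple[float, float]:
        prev_end, prev_pos = 0.0, self.park
        for t0, t1, pos in self.stations:
            pts, cum = self._route(prev_pos, pos)
            travel = cum[-1] / CART_SPEED
            depart = max(prev_end, t0 - travel)
            if t < depart:
                return prev_pos
            if t < depart + travel:
                d = (t - depart) * CART_SPEED
                return (
                    float(np.interp(d, cum, pts[:, 0])),
                    float(np.interp(d, cum, pts[:, 1])),
                )
            if t <= t1:
                return pos
            prev_end, prev_pos = t1, pos
        return prev_pos


def generate_scenario(
    script: ScenarioScript,
    layout: RoomLayout,
    config: AnalysisConfig,
    seed: int,
    sample_rate: float = 10.0,
) -> tuple[TrajectoryLog, GroundTruth]:
    """Simulate one scenario enactment.

    Deterministic for fixed (script, layout, config, seed): repeated calls
    produce identical logs sample for sample.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    inflation = config.person_radius + PLAN_MARGIN
    avoid_dist = 2 * config.person_radius + AVOID_FACTOR

    # --- staggered entries through a shared doorway
    agents = sorted(script.agents, key=lambda a: (a.entry_time, a.role))
    entry_times: dict[str, float] = {}
    for ag in agents:
        t = ag.entry_time
        while any(
            abs(t - entry_times[o.role]) < 1.0
            for o in agents
            if o.role in entry_times and o.entry_doorway == ag.entry_doorway
        ):
            warnings.warn(
                f"agents entering doorway {ag.entry_doorway!r} at overlapping "
                f"times; staggering {ag.role!r} by 2 s"
            )
            t += 2.0
        entry_times[ag.role] = t

    block_obs = [o for o in script.obstruction_plan if o.mode == "block"]
    contact_obs = [o for o in script.obstruction_plan if o.mode == "contact"]
    block_polys = {id(o): _obstacle_polygon(layout, o) for o in block_obs}

    events: list[EventAnnotation] = []
    planted_detours: list[PlantedDetour] = []
    # true (noiseless) agent trajectories, built in priority order
    built: dict[str, tuple[np.ndarray, np.ndarray]] = {}  # role -> (t, xy)

    def others_near(role: str, t: float, pos) -> bool:
        for other_role, (ts, xy) in built.items():
            if other_role == role or not ts[0] <= t <= ts[-1]:
                continue
            ox = np.interp(t, ts, xy[:, 0])
            oy = np.interp(t, ts, xy[:, 1])
            if math.hypot(pos[0] - ox, pos[1] - oy) < avoid_dist:
                return True
        return False

    for ag in agents:
        t0 = entry_times[ag.role]
        outside, inside = _door_points(layout, ag.entry_doorway)
        ts: list[float] = [t0]
        pts: list[tuple[float, float]] = [outside]
        now = t0

        def append_walk(polyline, speed):
            nonlocal now
            positions = walk_positions(polyline, speed, dt)
            waited = 0.0
            for pos in positions[1:]:
                pos = (float(pos[0]), float(pos[1]))
                while waited < MAX_WAIT and others_near(ag.role, now + dt, pos):
                    now += dt
                    waited += dt
                    ts.append(now)
                    pts.append(pts[-1])
                now += dt
                ts.append(now)
                pts.append(pos)

        def append_dwell(duration):
            nonlocal now
            n = max(1, int(round(duration / dt)))
            for _ in range(n):
                now += dt
                ts.append(now)
                pts.append(pts[-1])

        events.append(
            EventAnnotation(t=round(t0, 6), type="task_start", subject_id=_slug(ag.role))
        )
        append_walk([outside, inside], ag.speed)
        for k, step in enumerate(ag.steps):
            goal = _standing_point(layout, step.target, pts[-1], inflation)
            active = [
                o for o in block_obs if o.t_start <= now <= o.t_end
            ]
            try:
                base = plan_path(pts[-1], goal, layout, inflation)
            except ReachabilityError as exc:
                raise SimulationError(
                    f"target {step.target!r} unreachable for {ag.role!r}: {exc}"
                ) from exc
            chosen = base
            if active:
                try:
                    detoured = plan_path(
                        pts[-1], goal, layout, inflation,
                        extra_obstacles=[block_polys[id(o)] for o in active],
                    )
                except ReachabilityError:
                    warnings.warn(
                        f"obstruction makes target {step.target!r} unreachable "
                        f"for {ag.role!r}; walking the unobstructed route"
                    )
                    detoured = base
                base_len, det_len = path_length(base), path_length(detoured)
                leg_start = now
                if det_len > PLANT_RATIO * base_len and det_len - base_len >= PLANT_EXCESS:
                    chosen = detoured
                    planted_detours.append(
                        PlantedDetour(
                            role=ag.role,
                            step_index=k,
                            target=step.target,
                            t_start=leg_start,
                            t_end=leg_start + det_len / ag.speed + MAX_WAIT,
                            baseline_length=base_len,
                            detour_length=det_len,
                        )
                    )
                elif det_len > base_len:
                    chosen = detoured
            append_walk(chosen, ag.speed)
            if step.tag:
                events.append(
                    EventAnnotation(
                        t=round(now, 6), type="note", subject_id=_slug(ag.role),
                        target=step.target, label=f"subtask={step.tag}",
                    )
                )
            append_dwell(step.dwell.draw(rng))
        append_walk([pts[-1], inside, outside], ag.speed)
        events.append(
            EventAnnotation(t=round(now, 6), type="task_end", subject_id=_slug(ag.role))
        )
        built[ag.role] = (np.asarray(ts), np.asarray(pts))

    # --- contact-mode obstructions: park a cart brushing the agent's path
    planted_bumps: list[PlantedBump] = []
    contact_stations: dict[str, list[tuple[float, float, tuple[float, float]]]] = {}
    for obs in contact_obs:
        if obs.target_role not in built:
            warnings.warn(f"contact obstruction targets unknown role {obs.target_role!r}; skipped")
            continue
        ts, xy = built[obs.target_role]
        fixed_fps = [o.polygon for o in layout.fixed_objects()]
        placed = False
        for cand in np.arange(obs.t_start, obs.t_end + 1e-9, dt):
            if placed or not ts[0] + 1.0 <= cand <= ts[-1] - 1.0:
                continue
            p0 = np.array([np.interp(cand - 0.5, ts, xy[:, 0]), np.interp(cand - 0.5, ts, xy[:, 1])])
            p1 = np.array([np.interp(cand + 0.5, ts, xy[:, 0]), np.interp(cand + 0.5, ts, xy[:, 1])])
            if np.hypot(*(p1 - p0)) <= 0.5:  # dwelling, not walking
                continue
            t_c = float(cand)
            pos = np.array([np.interp(t_c, ts, xy[:, 0]), np.interp(t_c, ts, xy[:, 1])])
            heading = (p1 - pos) / max(np.hypot(*(p1 - pos)), 1e-9)
            for side in (1.0, -1.0):
                perp = np.array([-heading[1], heading[0]]) * side
                loc = pos + perp * CONTACT_OFFSET
                poly = _obstacle_polygon(
                    layout,
                    Obstruction(obs.object_id, "block", obs.t_start, obs.t_end, (loc[0], loc[1])),
                )
                if layout.polygon.covers(poly) and not any(
                    poly.intersects(fp) for fp in fixed_fps
                ):
                    contact_stations.setdefault(obs.object_id, []).append(
                        (t_c - 0.2, t_c + 0.3, (float(loc[0]), float(loc[1])))
                    )
                    planted_bumps.append(
                        PlantedBump(t=t_c, role=obs.target_role, object_id=obs.object_id)
                    )
                    placed = True
                    break
        if not placed:
            warnings.warn(
                f"no feasible contact placement for {obs.target_role!r} in "
                f"[{obs.t_start}, {obs.t_end}]; skipped"
            )

    # --- interruption plan
    planted_interruptions = 0
    for (t_i, interrupter, interrupted) in script.interruption_plan:
        if interrupted not in built or interrupter not in built:
            raise SimulationError(
                f"interruption references unknown role(s): {interrupter!r}/{interrupted!r}"
            )
        ts, _ = built[interrupted]
        if ts[0] <= t_i <= ts[-1]:
            events.append(
                EventAnnotation(
                    t=float(t_i), type="interruption",
                    subject_id=_slug(interrupted), target=_slug(interrupter),
                )
            )
            planted_interruptions += 1
        else:
            warnings.warn(
                f"planned interruption at t={t_i} falls outside {interrupted!r}'s "
                "task window; skipped"
            )

    # --- assemble tracks (noise drawn in fixed order for determinism)
    tracks: list[Track] = []
    for ag in agents:
        ts, xy = built[ag.role]
        noise = np.clip(
            rng.normal(0.0, NOISE_SD, size=xy.shape), -NOISE_CLIP, NOISE_CLIP
        )
        noisy = xy + noise
        samples = tuple(
            TrackSample(round(float(t), 6), float(p[0]), float(p[1]))
            for t, p in zip(ts, noisy)
        )
        tracks.append(
            Track(subject_id=_slug(ag.role), subject_kind="agent", role=ag.role, samples=samples)
        )

    t_end_all = max(ts[-1] for ts, _ in built.values())
    moved_ids = sorted(
        {o.object_id for o in block_obs} | set(contact_stations.keys())
    )
    for oid in moved_ids:
        obj = layout.object_by_id(oid)
        fp = obj.polygon
        park = (float(fp.centroid.x), float(fp.centroid.y))
        circumradius = max(
            math.hypot(x - park[0], y - park[1]) for x, y in fp.exterior.coords
        )
        timeline = _CartTimeline(park, layout, circumradius)
        for o in block_obs:
            if o.object_id == oid:
                timeline.add_station(o.t_start, o.t_end, o.location)
        for station in contact_stations.get(oid, []):
            timeline.add_station(*station)
        grid = np.arange(0.0, t_end_all + dt / 2, dt)
        samples = tuple(
            TrackSample(round(float(t), 6), *timeline.position_at(float(t))) for t in grid
        )
        tracks.append(
            Track(subject_id=oid, subject_kind="movable_object", role="", samples=samples)
        )

    log = TrajectoryLog(
        scenario_id=script.scenario_id,
        layout_id=layout.layout_id,
        tracks=tuple(tracks),
        events=tuple(sorted(events, key=lambda e: (e.t, e.subject_id, e.type))),
        sample_rate=sample_rate,
    )
    truth = GroundTruth(
        planted_detour_legs=tuple(planted_detours),
        planted_bump_events=tuple(planted_bumps),
        planted_interruptions=planted_interruptions,
    )
    return log, truth


# ---------------------------------------------------------------------------
# script file I/O


def script_to_dict(script: ScenarioScript) -> dict:
    return {
        "scenario_id": script.scenario_id,
        "agents": [
            {
                "role": a.role,
                "entry_time": float(a.entry_time),
                "entry_doorway": a.entry_doorway,
                "speed": float(a.speed),
                "steps": [
                    {
                        "target": s.target,
                        "tag": s.tag,
                        "dwell": {
                            "mean": float(s.dwell.mean),
                            "spread": float(s.dwell.spread),
                            "family": s.dwell.family,
                        },
                    }
                    for s in a.steps
                ],
            }
            for a in script.agents
        ],
        "interruption_plan": [
            [float(t), a, b] for (t, a, b) in script.interruption_plan
        ],
        "obstruction_plan": [
            {
                "object_id": o.object_id,
                "mode": o.mode,
                "t_start": float(o.t_start),
                "t_end": float(o.t_end),
                "location": list(map(float, o.location)) if o.location else None,
                "target_role": o.target_role,
            }
            for o in script.obstruction_plan
        ],
    }


def script_from_dict(data: dict) -> ScenarioScript:
    try:
        agents = tuple(
            AgentScript(
                role=str(a["role"]),
                entry_time=float(a["entry_time"]),
                entry_doorway=str(a["entry_doorway"]),
                speed=float(a.get("speed", 1.2)),
                steps=tuple(
                    TaskStep(
                        target=str(s["target"]),
                        tag=str(s.get("tag", "")),
                        dwell=DwellSpec(
                            mean=float(s["dwell"]["mean"]),
                            spread=float(s["dwell"].get("spread", 0.0)),
                            family=str(s["dwell"].get("family", "fixed")),
                        ),
                    )
                    for s in a["steps"]
                ),
            )
            for a in data["agents"]
        )
        return ScenarioScript(
            scenario_id=str(data["scenario_id"]),
            agents=agents,
            interruption_plan=tuple(
                (float(t), str(x), str(y)) for (t, x, y) in data.get("interruption_plan", [])
            ),
            obstruction_plan=tuple(
                Obstruction(
                    object_id=str(o["object_id"]),
                    mode=str(o["mode"]),
                    t_start=float(o["t_start"]),
                    t_end=float(o["t_end"]),
                    location=tuple(map(float, o["location"])) if o.get("location") else None,
                    target_role=str(o.get("target_role", "")),
                )
                for o in data.get("obstruction_plan", [])
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed scenario script: {exc}") from exc


def load_script(path) -> ScenarioScript:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: not valid YAML: {exc}") from exc
    return script_from_dict(data)


def write_script(script: ScenarioScript, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(script_to_dict(script), sort_keys=False, default_flow_style=None)
    )
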