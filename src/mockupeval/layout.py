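"""Room geometry: boundary, doorways, object footprints, interaction points.

Layouts live in a small YAML dialect (key/value plus ordered vertex lists,
all lengths in metres, planar floor-plan coordinates with the origin at a
designated room corner).  ``write_layout`` emits a canonical serialization
so that ``load_layout(write_layout(L))`` reproduces ``L`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .errors import FormatError, ValidationError

Coord = tuple[float, float]

#: Distance tolerance (m) for "lies on the boundary" checks; well below
#: any plausible surveying precision of a floor plan.
_GEOM_TOL = 1e-6


@dataclass(frozen=True)
class ObjectSpec:
    """One piece of room equipment with a planar footprint.

    ``mobility`` distinguishes furniture that constrains paths permanently
    (``"fixed"``: cabinets, counters, fridge) from equipment that moves
    during a scenario (``"movable"``: carts) and therefore can cause
    impediments rather than shaping baselines.  ``interaction_radius`` is
    the visit zone: a subject dwelling within this distance of the
    footprint counts as using the object.
    """

    object_id: str
    name: str
    footprint: tuple[Coord, ...]
    mobility: str = "fixed"
    interaction_radius: float = 0.6

    def __post_init__(self):
        problems = []
        if self.mobility not in ("fixed", "movable"):
            problems.append(
                f"object {self.object_id!r}: mobility must be 'fixed' or "
                f"'movable', got {self.mobility!r}"
            )
        if self.interaction_radius < 0:
            problems.append(f"object {self.object_id!r}: interaction_radius < 0")
        try:
            poly = Polygon(self.footprint)
            bad = not poly.is_valid or poly.area <= 0
        except Exception:
            bad = True
        if len(self.footprint) < 3 or bad:
            problems.append(
                f"object {self.object_id!r}: footprint must be a simple "
                "polygon with positive area"
            )
        if problems:
            raise ValidationError(problems)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.footprint)

    def zone(self) -> Polygon:
        """Interaction zone: footprint dilated by the interaction radius."""
        return self.polygon.buffer(self.interaction_radius)


@dataclass(frozen=True)
class Doorway:
    """A named segment of the room boundary; crossing it defines entry/exit."""

    name: str
    start: Coord
    end: Coord

    @property
    def segment(self) -> LineString:
        return LineString([self.start, self.end])

    @property
    def midpoint(self) -> Coord:
        return (
            (self.start[0] + self.end[0]) / 2.0,
            (self.start[1] + self.end[1]) / 2.0,
        )


@dataclass(frozen=True)
class RoomLayout:
    """Static geometry of one candidate room design."""

    layout_id: str
    boundary: tuple[Coord, ...]
    doorways: tuple[Doorway, ...] = ()
    objects: tuple[ObjectSpec, ...] = ()
    interaction_points: dict[str, Coord] = field(default_factory=dict)

    def __post_init__(self):
        problems = []
        poly = Polygon(self.boundary)
        if len(self.boundary) < 3 or not poly.is_valid:
            problems.append("boundary must be a simple (non-self-intersecting) polygon")
        elif poly.area <= 0:
            problems.append("boundary must have positive area")
        else:
            ring = LineString(list(self.boundary) + [self.boundary[0]])
            for obj in self.objects:
                try:
                    fp = obj.polygon
                except Exception:  # invalid footprint reported by ObjectSpec
                    continue
                if not poly.buffer(_GEOM_TOL).contains(fp):
                    problems.append(
                        f"object {obj.object_id!r} footprint lies outside the boundary"
                    )
            for dw in self.doorways:
                if dw.segment.distance(ring) > _GEOM_TOL or not (
                    ring.distance(Point(dw.start)) <= _GEOM_TOL
                    and ring.distance(Point(dw.end)) <= _GEOM_TOL
                ):
                    problems.append(f"doorway {dw.name!r} does not lie on the boundary")
        ids = [o.object_id for o in self.objects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            problems.append(f"duplicate object ids: {', '.join(dupes)}")
        if problems:
            raise ValidationError(problems)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.boundary)

    def object_by_id(self, object_id: str) -> ObjectSpec:
        for obj in self.objects:
            if obj.object_id == object_id:
                return obj
        raise KeyError(object_id)

    def doorway_by_name(self, name: str) -> Doorway:
        for dw in self.doorways:
            if dw.name == name:
                return dw
        raise KeyError(name)

    def fixed_objects(self) -> tuple[ObjectSpec, ...]:
        return tuple(o for o in self.objects if o.mobility == "fixed")

    def movable_objects(self) -> tuple[ObjectSpec, ...]:
        return tuple(o for o in self.objects if o.mobility == "movable")


def inflate_obstacles(layout: RoomLayout, radius: float):
    """Fixed-object footprints and boundary walls dilated by ``radius``.

    Persons are modelled as discs, so planning a path for a person centre
    requires growing every static obstacle by the body radius.  Movable
    objects are excluded: they are dynamic, and circumnavigating them is
    exactly what the impediment rule attributes.

    Returns a list of shapely polygons: one per fixed footprint (dilated
    with mitred corners so the result stays polygonal) plus, when
    ``radius > 0``, a wall band of width ``2*radius`` straddling the
    boundary ring.  Dilation is monotone in ``radius``.
    """
    if radius < 0:
        raise ValueError("inflation radius must be >= 0")
    if radius < 1e-12:  # buffers with subnormal radii degenerate to empty
        radius = 0.0
    obstacles = []
    for obj in layout.fixed_objects():
        fp = obj.polygon
        if radius > 0:
            fp = fp.buffer(radius, join_style="mitre")
        obstacles.append(fp)
    if radius > 0:
        outer = layout.polygon.buffer(radius, join_style="mitre")
        inner = layout.polygon.buffer(-radius, join_style="mitre")
        obstacles.append(outer.difference(inner))
    return obstacles


def free_space(layout: RoomLayout, inflation: float, extra_obstacles=()):
    """Region reachable by a person centre: eroded boundary minus obstacles.

    ``extra_obstacles`` are shapely polygons (e.g. a parked cart) that are
    additionally dilated by ``inflation`` and subtracted.
    """
    if inflation < 0:
        raise ValueError("inflation must be >= 0")
    if inflation < 1e-12:
        inflation = 0.0
    region = (
        layout.polygon.buffer(-inflation, join_style="mitre")
        if inflation > 0
        else layout.polygon
    )
    blocks = [
        o.polygon.buffer(inflation, join_style="mitre") if inflation > 0 else o.polygon
        for o in layout.fixed_objects()
    ]
    for extra in extra_obstacles:
        blocks.append(extra.buffer(inflation, join_style="mitre") if inflation > 0 else extra)
    if blocks:
        region = region.difference(unary_union(blocks))
    return region


# ---------------------------------------------------------------------------
# serialization

def _coords_to_lists(coords: Sequence[Coord]) -> list[list[float]]:
    return [[float(x), float(y)] for x, y in coords]


def _lists_to_coords(data, where: str) -> tuple[Coord, ...]:
    try:
        return tuple((float(x), float(y)) for x, y in data)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{where}: expected a list of [x, y] vertex pairs") from exc


def layout_to_dict(layout: RoomLayout) -> dict:
    return {
        "layout_id": layout.layout_id,
        "boundary": _coords_to_lists(layout.boundary),
        "doorways": [
            {
                "name": dw.name,
                "start": [float(dw.start[0]), float(dw.start[1])],
                "end": [float(dw.end[0]), float(dw.end[1])],
            }
            for dw in layout.doorways
        ],
        "objects": [
            {
                "object_id": o.object_id,
                "name": o.name,
                "mobility": o.mobility,
                "interaction_radius": float(o.interaction_radius),
                "footprint": _coords_to_lists(o.footprint),
            }
            for o in layout.objects
        ],
        "interaction_points": {
            k: [float(v[0]), float(v[1])] for k, v in layout.interaction_points.items()
        },
    }


def layout_from_dict(data: dict) -> RoomLayout:
    if not isinstance(data, dict):
        raise FormatError("layout document must be a mapping")
    for key in ("layout_id", "boundary"):
        if key not in data:
            raise FormatError(f"layout document missing required field {key!r}")
    doorways = []
    for i, dw in enumerate(data.get("doorways") or []):
        try:
            doorways.append(
                Doorway(
                    name=str(dw["name"]),
                    start=(float(dw["start"][0]), float(dw["start"][1])),
                    end=(float(dw["end"][0]), float(dw["end"][1])),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"doorways[{i}]: {exc}") from exc
    objects = []
    for i, o in enumerate(data.get("objects") or []):
        try:
            objects.append(
                ObjectSpec(
                    object_id=str(o["object_id"]),
                    name=str(o.get("name", o["object_id"])),
                    mobility=str(o.get("mobility", "fixed")),
                    interaction_radius=float(o.get("interaction_radius", 0.6)),
                    footprint=_lists_to_coords(o["footprint"], f"objects[{i}].footprint"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise FormatError(f"objects[{i}]: missing or malformed field {exc}") from exc
        except ValueError as exc:
            raise FormatError(f"objects[{i}]: {exc}") from exc
    points = {
        str(k): (float(v[0]), float(v[1]))
        for k, v in (data.get("interaction_points") or {}).items()
    }
    return RoomLayout(
        layout_id=str(data["layout_id"]),
        boundary=_lists_to_coords(data["boundary"], "boundary"),
        doorways=tuple(doorways),
        objects=tuple(objects),
        interaction_points=points,
    )


def load_layout(path) -> RoomLayout:
    """Read and validate a layout file; raises FormatError / ValidationError."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: not valid YAML: {exc}") from exc
    return layout_from_dict(data)


def write_layout(layout: RoomLayout, path) -> None:
    """Canonical serialization; round-trips exactly through load_layout."""
    Path(path).write_text(
        yaml.safe_dump(layout_to_dict(layout), sort_keys=False, default_flow_style=None)
    )
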