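"""Trajectory logs: timestamped tracks plus an event-annotation channel.

The on-disk dialect is tab-delimited text: a header of ``key\\tvalue``
lines, a ``[tracks]`` section with one record per sample
(``subject_id kind role t x y``) and an ``[events]`` section
(``t type subject_id target label``).  ``write_log`` emits a canonical
ordering (tracks in declaration order, samples by time, events by time)
so canonical files round-trip byte-identically.

Interruptions are carried as first-class annotations rather than inferred
from positions: an interruption is a diversion of *attention*, which a 2-D
trace cannot witness.  The simulator (or a human coder) supplies them.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

EVENT_TYPES = ("task_start", "task_end", "interruption", "note")
SUBJECT_KINDS = ("agent", "movable_object")


@dataclass(frozen=True)
class TrackSample:
    t: float
    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.t) and self.t >= 0):
            raise ValidationError(f"sample time must be finite and >= 0, got {self.t}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"sample position must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class Track:
    """Time-ordered positions of one agent or movable object."""

    subject_id: str
    subject_kind: str
    role: str
    samples: tuple[TrackSample, ...]

    def __post_init__(self):
        problems = []
        if self.subject_kind not in SUBJECT_KINDS:
            problems.append(
                f"track {self.subject_id!r}: subject_kind must be one of {SUBJECT_KINDS}"
            )
        if len(self.samples) < 2:
            problems.append(f"track {self.subject_id!r}: needs at least 2 samples")
        ts = [s.t for s in self.samples]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            problems.append(f"track {self.subject_id!r}: sample times must strictly increase")
        if problems:
            raise ValidationError(problems)

    @property
    def t_start(self) -> float:
        return self.samples[0].t

    @property
    def t_end(self) -> float:
        return self.samples[-1].t

    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    def positions(self) -> np.ndarray:
        return np.array([[s.x, s.y] for s in self.samples])

    def position_at(self, t: float) -> tuple[float, float]:
        """Linear interpolation, clamped to the track's time span."""
        ts = self.times()
        xy = self.positions()
        return (
            float(np.interp(t, ts, xy[:, 0])),
            float(np.interp(t, ts, xy[:, 1])),
        )

    def path_length(self) -> float:
        xy = self.positions()
        return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


@dataclass(frozen=True)
class EventAnnotation:
    t: float
    type: str
    subject_id: str
    target: str = ""
    label: str = ""

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValidationError(
                f"event type must be one of {EVENT_TYPES}, got {self.type!r}"
            )
        if not math.isfinite(self.t):
            raise ValidationError(f"event time must be finite, got {self.t}")


@dataclass(frozen=True)
class TrajectoryLog:
    """One scenario enactment: all tracks plus the annotation channel."""

    scenario_id: str
    layout_id: str
    tracks: tuple[Track, ...]
    events: tuple[EventAnnotation, ...] = ()
    sample_rate: float = 10.0

    def __post_init__(self):
        problems = []
        ids = [t.subject_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            problems.append(f"duplicate subject ids: {', '.join(dupes)}")
        if self.sample_rate <= 0:
            problems.append("sample_rate must be > 0")
        if self.tracks:
            span = (self.t_start, self.t_end)
            for ev in self.events:
                if not span[0] <= ev.t <= span[1]:
                    problems.append(
                        f"event at t={ev.t} outside log time span {span}"
                    )
        if problems:
            raise ValidationError(problems)

    @property
    def t_start(self) -> float:
        return min(t.t_start for t in self.tracks)

    @property
    def t_end(self) -> float:
        return max(t.t_end for t in self.tracks)

    def track(self, subject_id: str) -> Track:
        for t in self.tracks:
            if t.subject_id == subject_id:
                return t
        raise KeyError(subject_id)

    def agent_tracks(self) -> tuple[Track, ...]:
        return tuple(t for t in self.tracks if t.subject_kind == "agent")

    def object_tracks(self) -> tuple[Track, ...]:
        return tuple(t for t in self.tracks if t.subject_kind == "movable_object")


def resample_track(track: Track, dt: float) -> Track:
    """Linear interpolation onto a uniform grid spanning the track's times.

    The grid starts at the first sample time and steps by ``dt``; the last
    original time is appended when the span is not an exact multiple, so
    both endpoints are always preserved.  Because every interpolated point
    lies on the original polyline, resampling can only shorten it.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t0, t1 = track.t_start, track.t_end
    n = int(math.floor((t1 - t0) / dt + 1e-9))
    grid = t0 + dt * np.arange(n + 1)
    if grid[-1] < t1 - 1e-12:
        grid = np.append(grid, t1)
    else:
        grid[-1] = t1
    ts = track.times()
    xy = track.positions()
    xs = np.interp(grid, ts, xy[:, 0])
    ys = np.interp(grid, ts, xy[:, 1])
    samples = tuple(TrackSample(float(t), float(x), float(y)) for t, x, y in zip(grid, xs, ys))
    return replace(track, samples=samples)


# ---------------------------------------------------------------------------
# file I/O

_MAGIC = "# mockupeval trajectory log v1"


def _fmt(v: float) -> str:
    return repr(float(v))


def write_log(log: TrajectoryLog, path) -> None:
    """Write a log in canonical form (deterministic byte-for-byte)."""
    buf = io.StringIO()
    buf.write(_MAGIC + "\n")
    buf.write(f"scenario_id\t{log.scenario_id}\n")
    buf.write(f"layout_id\t{log.layout_id}\n")
    buf.write(f"sample_rate\t{_fmt(log.sample_rate)}\n")
    buf.write("[tracks]\n")
    buf.write("subject_id\tkind\trole\tt\tx\ty\n")
    for track in log.tracks:
        for s in track.samples:
            buf.write(
                f"{track.subject_id}\t{track.subject_kind}\t{track.role}\t"
                f"{_fmt(s.t)}\t{_fmt(s.x)}\t{_fmt(s.y)}\n"
            )
    buf.write("[events]\n")
    buf.write("t\ttype\tsubject_id\ttarget\tlabel\n")
    for ev in sorted(log.events, key=lambda e: (e.t, e.subject_id, e.type)):
        buf.write(f"{_fmt(ev.t)}\t{ev.type}\t{ev.subject_id}\t{ev.target}\t{ev.label}\n")
    Path(path).write_text(buf.getvalue())


def read_log(path) -> TrajectoryLog:
    """Parse and validate a trajectory log file.

    Out-of-order samples are sorted (a declared normalization); duplicate
    (subject, t) records and malformed fields are rejected with the
    offending line number.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise FormatError(f"{path}: line 1: missing magic header {_MAGIC!r}")
    header: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].strip() != "[tracks]":
        line = lines[i].strip()
        if line:
            if "\t" not in line:
                raise FormatError(f"{path}: line {i + 1}: expected key<TAB>value")
            k, v = line.split("\t", 1)
            header[k] = v
        i += 1
    if i == len(lines):
        raise FormatError(f"{path}: missing [tracks] section")
    try:
        ev_idx = lines.index("[events]", i)
    except ValueError:
        raise FormatError(f"{path}: missing [events] section") from None

    def _read_section(start, stop, columns):
        body = "\n".join(lines[start:stop])
        df = pd.read_csv(
            io.StringIO(body), sep="\t", dtype=str, keep_default_na=False
        )
        if list(df.columns) != columns:
            raise FormatError(
                f"{path}: line {start + 1}: expected columns {columns}, got {list(df.columns)}"
            )
        return df

    tdf = _read_section(i + 1, ev_idx, ["subject_id", "kind", "role", "t", "x", "y"])
    edf = _read_section(ev_idx + 1, len(lines), ["t", "type", "subject_id", "target", "label"])

    for col in ("t", "x", "y"):
        try:
            tdf[col] = tdf[col].astype(float)
        except ValueError:
            bad = tdf[pd.to_numeric(tdf[col], errors="coerce").isna()].index[0]
            raise FormatError(
                f"{path}: line {i + 3 + bad}: non-numeric value in column {col!r}"
            ) from None

    tracks = []
    for sid, grp in tdf.groupby("subject_id", sort=False):
        grp = grp.sort_values("t", kind="stable")
        if grp["t"].duplicated().any():
            t_dup = grp.loc[grp["t"].duplicated(), "t"].iloc[0]
            raise ValidationError(
                f"track {sid!r}: duplicate sample at t={t_dup}"
            )
        tracks.append(
            Track(
                subject_id=str(sid),
                subject_kind=str(grp["kind"].iloc[0]),
                role=str(grp["role"].iloc[0]),
                samples=tuple(
                    TrackSample(float(r.t), float(r.x), float(r.y))
                    for r in grp.itertuples()
                ),
            )
        )
    try:
        edf["t"] = edf["t"].astype(float)
    except ValueError:
        raise FormatError(f"{path}: non-numeric event time in [events] section") from None
    events = tuple(
        EventAnnotation(
            t=float(r.t),
            type=str(r.type),
            subject_id=str(r.subject_id),
            target=str(r.target),
            label=str(r.label),
        )
        for r in edf.sort_values(["t", "subject_id", "type"], kind="stable").itertuples()
    )
    try:
        sample_rate = float(header.get("sample_rate", "10.0"))
    except ValueError:
        raise FormatError(f"{path}: non-numeric sample_rate in header") from None
    return TrajectoryLog(
        scenario_id=header.get("scenario_id", ""),
        layout_id=header.get("layout_id", ""),
        tracks=tuple(tracks),
        events=events,
        sample_rate=sample_rate,
    )


def samples_to_frame(log: TrajectoryLog) -> pd.DataFrame:
    """Flatten all samples to a DataFrame (CSV-export interoperability)."""
    rows = []
    for track in log.tracks:
        for s in track.samples:
            rows.append(
                (track.subject_id, track.subject_kind, track.role, s.t, s.x, s.y)
            )
    return pd.DataFrame(rows, columns=["subject_id", "kind", "role", "t", "x", "y"])
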