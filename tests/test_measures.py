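import math
import warnings

import numpy as np
import pytest

from mockupeval import (
    AnalysisConfig,
    EventAnnotation,
    ObjectSpec,
    RoomLayout,
    Track,
    TrackSample,
    TrajectoryLog,
    ValidationError,
    detect_bumps,
    detect_impediments,
    extract_interruptions,
    link_analysis,
    segment_visits,
    task_completion_times,
)
from mockupeval.layout import Doorway
from mockupeval.measures import Leg, high_traffic_near


def _track(points, sid="a1", kind="agent", role="Nurse 1", dt=0.1):
    """Track from a list of (x, y) sampled every dt."""
    samples = tuple(
        TrackSample(round(i * dt, 6), float(x), float(y)) for i, (x, y) in enumerate(points)
    )
    return Track(sid, kind, role, samples)


def _stationary(pos, seconds, sid="a1", dt=0.1, role="Nurse 1", kind="agent"):
    n = int(seconds / dt) + 1
    return _track([pos] * n, sid=sid, dt=dt, role=role, kind=kind)


def _walk(p0, p1, speed=1.2, sid="a1", dt=0.1, role="Nurse 1"):
    d = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    n = max(2, int(d / (speed * dt)) + 1)
    pts = [
        (p0[0] + (p1[0] - p0[0]) * k / (n - 1), p0[1] + (p1[1] - p0[1]) * k / (n - 1))
        for k in range(n)
    ]
    return _track(pts, sid=sid, dt=dt, role=role)


def _room(objects=(), doorways=None, size=(10.0, 10.0)):
    if doorways is None:
        doorways = (Doorway("main", (4.0, 0.0), (5.0, 0.0)),)
    return RoomLayout(
        layout_id="r",
        boundary=((0.0, 0.0), (size[0], 0.0), size, (0.0, size[1])),
        doorways=doorways,
        objects=tuple(objects),
    )


def _log(tracks, events=(), sample_rate=10.0):
    return TrajectoryLog("s", "r", tuple(tracks), tuple(events), sample_rate)


FRIDGE = ObjectSpec("fridge", "fridge", ((5.0, 5.0), (6.0, 5.0), (6.0, 6.0), (5.0, 6.0)))


# ---------------------------------------------------------------------------
# visits


def test_stationary_agent_in_zone_gets_one_visit(config):
    log = _log([_stationary((5.5, 4.6), 5.0)])
    visits = segment_visits(log, _room([FRIDGE]), config)
    assert len(visits) == 1
    v = visits[0]
    assert v.object_id == "fridge"
    assert v.t_end - v.t_start == pytest.approx(5.0, abs=0.2)


def test_walkthrough_of_zone_yields_no_visit(config):
    log = _log([_walk((3.0, 4.6), (8.0, 4.6), speed=1.2)])
    assert segment_visits(log, _room([FRIDGE]), config) == []


def test_brief_pause_below_min_duration_yields_no_visit(config):
    track = _stationary((5.5, 4.6), 1.0)
    log = _log([track])
    assert segment_visits(log, _room([FRIDGE]), config) == []


def test_overlapping_zones_tie_break_to_nearest_footprint(config):
    near = ObjectSpec("near", "a", ((4.0, 4.0), (5.0, 4.0), (5.0, 5.0), (4.0, 5.0)))
    far = ObjectSpec("far", "b", ((6.2, 4.0), (7.2, 4.0), (7.2, 5.0), (6.2, 5.0)))
    # (5.4, 4.5) is in both zones (0.6 radius): 0.4 from `near`, 0.8 from `far`
    log = _log([_stationary((5.4, 4.5), 4.0)])
    visits = segment_visits(log, _room([near, far]), config)
    assert [v.object_id for v in visits] == ["near"]


# ---------------------------------------------------------------------------
# impediments (pure-predicate examples on constructed legs)


def _leg(actual, baseline, sid="a1"):
    return Leg(
        subject_id=sid,
        from_object="a",
        to_object="b",
        t_start=0.0,
        t_end=10.0,
        actual_length=actual,
        baseline_length=baseline,
        baseline_path=((1.0, 1.0), (1.0 + baseline, 1.0)),
    )


def _intruder_log():
    """A second agent parked on the baseline corridor for the whole leg."""
    a1 = _walk((1.0, 1.0), (4.0, 1.0), sid="a1")
    a2 = _stationary((2.5, 1.2), 10.0, sid="a2", role="Nurse 2")
    return _log([a1, a2])


@pytest.mark.parametrize(
    "actual,baseline,expect",
    [
        (4.2, 3.0, True),    # ratio 1.40, excess 1.2 m -> impediment
        (11.5, 10.0, False), # excess 1.5 m but ratio 1.15 -> ratio test fails
        (2.6, 2.0, False),   # ratio 1.30 but excess 0.6 m -> length test fails
        (3.6, 3.0, False),   # ratio exactly 1.20: strict > fails
        (4.0, 3.0, True),    # excess exactly 1.0 m: >= passes (ratio 1.33)
    ],
)
def test_impediment_threshold_semantics(config, actual, baseline, expect):
    events = detect_impediments([_leg(actual, baseline)], _intruder_log(), config)
    assert (len(events) == 1) == expect
    if expect:
        assert events[0].participants == ("a1", "a2")


def test_impediment_requires_an_intruder(config):
    """Thresholds alone are not enough: without a person or movable object
    in the baseline corridor no impediment is attributed."""
    lone = _log([_walk((1.0, 1.0), (4.0, 1.0), sid="a1")])
    assert detect_impediments([_leg(4.2, 3.0)], lone, config) == []


def test_impediment_scale_invariance_of_ratio_but_not_length(config):
    """Scaling geometry by 0.5: the 20% ratio still trips, but the absolute
    1 m excess shrinks below threshold, so detection is lost."""
    k = 0.5
    assert detect_impediments([_leg(4.2, 3.0)], _intruder_log(), config)
    scaled = _leg(4.2 * k, 3.0 * k)
    assert scaled.actual_length > config.detour_ratio_threshold * scaled.baseline_length
    assert detect_impediments([scaled], _intruder_log(), config) == []


def test_excluded_leg_skipped(config):
    leg = Leg(
        subject_id="a1", from_object="a", to_object="b", t_start=0.0, t_end=10.0,
        actual_length=5.0, baseline_length=float("nan"), excluded=True,
    )
    assert detect_impediments([leg], _intruder_log(), config) == []


# ---------------------------------------------------------------------------
# bumps


def test_two_distant_stationary_agents_no_bump(config):
    log = _log(
        [_stationary((2.0, 2.0), 5.0, sid="a1"), _stationary((4.0, 2.0), 5.0, sid="a2", role="N2")]
    )
    assert detect_bumps(log, _room(), config) == []


def test_crossing_agents_within_contact_distance_one_bump(config):
    a1 = _walk((1.0, 2.0), (5.0, 2.0), sid="a1")
    a2 = _walk((5.0, 2.3), (1.0, 2.3), sid="a2", role="N2")
    log = _log([a1, a2])
    events = detect_bumps(log, _room(), config)
    assert len(events) == 1
    assert set(events[0].participants) == {"a1", "a2"}


def test_contact_gap_below_merge_window_is_one_bump(config):
    """Contact, 0.2 s apart, contact again: merged into a single event
    under the 0.5 s debounce."""
    near, away = (2.0, 2.0), (2.0, 3.0)
    pts = [near] * 5 + [away] * 2 + [near] * 5  # 0.2 s gap at 10 Hz
    a1 = _track(pts, sid="a1")
    a2 = _stationary((2.3, 2.0), 1.2, sid="a2", role="N2")
    events = detect_bumps(_log([a1, a2]), _room(), config)
    assert len(events) == 1


def test_contact_gap_above_merge_window_is_two_bumps(config):
    near, away = (2.0, 2.0), (2.0, 3.0)
    pts = [near] * 5 + [away] * 9 + [near] * 5  # 0.9 s gap
    a1 = _track(pts, sid="a1")
    a2 = _stationary((2.3, 2.0), 1.9, sid="a2", role="N2")
    events = detect_bumps(_log([a1, a2]), _room(), config)
    assert len(events) == 2


def test_bump_count_symmetric_under_relabelling(config):
    a1 = _walk((1.0, 2.0), (5.0, 2.0), sid="a1")
    a2 = _walk((5.0, 2.3), (1.0, 2.3), sid="a2", role="N2")
    n_ab = len(detect_bumps(_log([a1, a2]), _room(), config))
    n_ba = len(detect_bumps(_log([a2, a1]), _room(), config))
    assert n_ab == n_ba == 1


def test_contact_with_visit_target_not_a_bump(config):
    """Standing in contact with the fridge while visiting it is intended
    interaction, not a bump; the same contact without a visit counts."""
    visiting = _stationary((5.5, 4.8), 5.0)  # 0.2 m from fridge edge, in zone
    log = _log([visiting])
    layout = _room([FRIDGE])
    assert detect_bumps(log, layout, config) == []
    # same geometry, but visits suppressed: the contact now counts
    events = detect_bumps(log, layout, config, visits=[])
    assert len(events) == 1


# ---------------------------------------------------------------------------
# interruptions


def _task_events(sid="a1", start=0.0, end=10.0):
    return [
        EventAnnotation(start, "task_start", sid),
        EventAnnotation(end, "task_end", sid),
    ]


def test_interruptions_inside_tasks_pass_through():
    track = _stationary((2.0, 2.0), 10.0)
    anns = _task_events() + [
        EventAnnotation(t, "interruption", "a1", target="a2") for t in (1.0, 4.0, 9.0)
    ]
    events = extract_interruptions(_log([track], anns))
    assert len(events) == 3
    assert all(e.participants == ("a2", "a1") for e in events)


def test_interruption_between_tasks_dropped_with_warning():
    track = _stationary((2.0, 2.0), 20.0)
    anns = (
        _task_events(end=5.0)
        + [EventAnnotation(7.0, "interruption", "a1", target="a2")]
        + _task_events(start=10.0, end=18.0)
    )
    with pytest.warns(UserWarning, match="outside any task"):
        events = extract_interruptions(_log([track], anns))
    assert events == []


def test_empty_annotation_channel_yields_no_interruptions():
    assert extract_interruptions(_log([_stationary((2.0, 2.0), 5.0)])) == []


def test_interruption_for_unknown_subject_rejected():
    track = _stationary((2.0, 2.0), 10.0)
    anns = [EventAnnotation(1.0, "interruption", "ghost", target="a1")]
    with pytest.raises(ValidationError, match="unknown subject"):
        extract_interruptions(_log([track], anns))


# ---------------------------------------------------------------------------
# task completion times


def _in_out_track(t_in=10.0, t_out=70.0, sid="a1", dt=0.5):
    """Starts outside the door, enters at ~t_in, exits at ~t_out."""
    pts = []
    n_pre = int(t_in / dt)
    n_in = int((t_out - t_in) / dt)
    for i in range(n_pre):
        pts.append((4.5, -0.3))
    for i in range(n_in):
        pts.append((4.5, 1.5))
    pts.append((4.5, -0.3))
    pts.append((4.5, -0.3001))
    return _track(pts, sid=sid, dt=dt)


def test_entry_to_exit_time(config):
    log = _log([_in_out_track(10.0, 70.0)], sample_rate=2.0)
    times = task_completion_times(log, _room())
    assert times["a1"] == pytest.approx(60.0, abs=0.6)


def test_reentry_uses_first_entry_last_exit(config):
    dt = 0.5
    seq = [(4.5, -0.3)] * 4 + [(4.5, 1.5)] * 20 + [(4.5, -0.3)] * 10 + [(4.5, 1.5)] * 20 + [(4.5, -0.3)] * 2
    log = _log([_track(seq, dt=dt)], sample_rate=2.0)
    times = task_completion_times(log, _room())
    # first entry ~2 s, last exit ~27 s
    assert times["a1"] == pytest.approx(25.0, abs=1.0)


def test_agent_never_exiting_flagged(config):
    pts = [(4.5, -0.3)] * 4 + [(4.5, 1.5)] * 20
    log = _log([_track(pts, dt=0.5)], sample_rate=2.0)
    with pytest.warns(UserWarning, match="never exited"):
        times = task_completion_times(log, _room())
    assert times["a1"] == pytest.approx(10.0, abs=1.0)


def test_agent_never_inside_excluded(config):
    pts = [(4.5, -0.3), (4.5, -0.4)] * 5
    log = _log([_track(pts, dt=0.5)], sample_rate=2.0)
    with pytest.warns(UserWarning, match="never inside"):
        times = task_completion_times(log, _room())
    assert "a1" not in times


# ---------------------------------------------------------------------------
# link analysis


def test_occupancy_conserves_in_room_time(config):
    a1 = _walk((1.0, 1.0), (8.0, 8.0), sid="a1")
    a2 = _stationary((3.0, 3.0), 6.0, sid="a2", role="N2")
    log = _log([a1, a2])
    grid = link_analysis(log, _room(), config)
    assert grid.total_dwell() == pytest.approx(
        sum(grid.in_room_seconds.values()), rel=1e-9
    )


def test_single_dwell_cell_holds_duration_and_is_high_traffic(config):
    log = _log([_stationary((3.07, 3.07), 30.0)])
    grid = link_analysis(log, _room(), config)
    iy = int((3.07 - grid.origin[1]) / grid.cell)
    ix = int((3.07 - grid.origin[0]) / grid.cell)
    assert grid.dwell[iy, ix] == pytest.approx(30.0, abs=0.2)
    assert (iy, ix) in grid.high_traffic_cells


def test_cell_larger_than_room_rejected(config):
    log = _log([_stationary((3.0, 3.0), 5.0)])
    big = AnalysisConfig(grid_cell=20.0)
    with pytest.raises(ValueError, match="larger than the room"):
        link_analysis(log, _room(), big)


def test_high_traffic_near_helper(config):
    log = _log([_stationary((5.5, 4.55), 30.0)])
    layout = _room([FRIDGE])
    grid = link_analysis(log, layout, config)
    assert high_traffic_near(grid, layout, "fridge")
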