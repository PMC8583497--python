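import warnings

import numpy as np
import pytest
import shapely
from shapely.geometry import Point
from shapely.ops import unary_union

from mockupeval import (
    AgentScript,
    AnalysisConfig,
    DwellSpec,
    ScenarioScript,
    SimulationError,
    TaskStep,
    build_legs,
    generate_scenario,
    load_script,
    segment_visits,
    write_log,
    write_script,
)
from mockupeval.fixtures import (
    demo_script,
    existing_layout,
    recovery_layout,
    recovery_script,
)

@pytest.fixture(scope="module")
def existing():
    return existing_layout()


def _simulate(script, layout, seed=0):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_scenario(script, layout, AnalysisConfig(), seed=seed)


def test_same_seed_byte_identical_logs(tmp_path, existing):
    script = demo_script(2, scale=0.4)
    log1, _ = _simulate(script, existing, seed=7)
    log2, _ = _simulate(script, existing, seed=7)
    p1, p2 = tmp_path / "a.log", tmp_path / "b.log"
    write_log(log1, p1)
    write_log(log2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seed_differs(existing):
    script = demo_script(2, scale=0.4)
    log1, _ = _simulate(script, existing, seed=1)
    log2, _ = _simulate(script, existing, seed=2)
    assert log1 != log2


def test_four_agent_script_yields_four_agent_tracks(existing):
    log, _ = _simulate(demo_script(4, scale=0.4), existing, seed=0)
    assert len(log.agent_tracks()) == 4
    roles = {t.role for t in log.agent_tracks()}
    assert roles == {"Nurse 1", "Nurse 2", "Nurse 3", "Pharmacy Technician 1"}


def test_tracks_avoid_inflated_fixed_obstacles(existing, config):
    """No agent sample may fall inside a fixed obstacle inflated by the
    body radius; samples outside the room must sit at the doorway."""
    log, _ = _simulate(demo_script(4, scale=0.4), existing, seed=3)
    blocked = unary_union(
        [
            o.polygon.buffer(config.person_radius, join_style="mitre")
            for o in existing.fixed_objects()
        ]
    )
    room = existing.polygon
    door = existing.doorway_by_name("main").segment
    for track in log.agent_tracks():
        xy = track.positions()
        inside_obstacle = shapely.contains_xy(blocked, xy[:, 0], xy[:, 1])
        assert not inside_obstacle.any()
        outside = ~shapely.contains_xy(room, xy[:, 0], xy[:, 1])
        for p in xy[outside]:
            assert door.distance(Point(p)) < 0.8


def test_unobstructed_leg_actual_close_to_baseline(config):
    """With default noise an agent walking an empty corridor produces legs
    whose measured length is within 5% of the planned baseline."""
    layout = recovery_layout()
    script = recovery_script(with_detour=False, with_contact=False, n_interruptions=0)
    log, _ = _simulate(script, layout, seed=5)
    visits = segment_visits(log, layout, config)
    legs = build_legs(visits, log, layout, config)
    crossing_legs = [
        l for l in legs
        if l.subject_id == "nurse_1" and {l.from_object, l.to_object} == {"supply_west", "adc_east"}
    ]
    assert crossing_legs
    for leg in crossing_legs:
        assert leg.actual_length / leg.baseline_length < 1.05


def test_unreachable_target_raises_simulation_error():
    layout = recovery_layout()
    script = ScenarioScript(
        scenario_id="bad",
        agents=(
            AgentScript(
                role="Nurse 1",
                entry_time=0.0,
                entry_doorway="west_door",
                steps=(TaskStep("nonexistent", DwellSpec(3.0)),),
            ),
        ),
    )
    with pytest.raises(SimulationError, match="nonexistent"):
        _simulate(script, layout)


def test_overlapping_entries_staggered_with_warning():
    layout = recovery_layout()
    mk = lambda role: AgentScript(  # noqa: E731
        role=role, entry_time=0.0, entry_doorway="west_door",
        steps=(TaskStep("supply_west", DwellSpec(2.0)),),
    )
    script = ScenarioScript(scenario_id="clash", agents=(mk("Nurse 1"), mk("Nurse 2")))
    with pytest.warns(UserWarning, match="staggering"):
        log, _ = generate_scenario(script, layout, AnalysisConfig(), seed=0)
    starts = sorted(t.t_start for t in log.agent_tracks())
    assert starts[1] - starts[0] >= 2.0 - 1e-9


def test_planted_ground_truth_is_recorded():
    layout = recovery_layout()
    log, truth = _simulate(recovery_script(), layout, seed=11)
    assert truth.planted_interruptions == 2
    assert truth.planted_bumps == 1
    assert len(truth.planted_detour_legs) == 1
    detour = truth.planted_detour_legs[0]
    assert detour.detour_length > 1.25 * detour.baseline_length
    assert detour.detour_length - detour.baseline_length >= 1.1


def test_interruption_annotations_present_in_log():
    layout = recovery_layout()
    log, truth = _simulate(recovery_script(n_interruptions=2), layout, seed=0)
    anns = [e for e in log.events if e.type == "interruption"]
    assert len(anns) == truth.planted_interruptions == 2
    assert all(a.subject_id == "nurse_1" for a in anns)


def test_script_yaml_round_trip(tmp_path):
    script = recovery_script()
    path = tmp_path / "s.yaml"
    write_script(script, path)
    assert load_script(path) == script


def test_dwell_distributions():
    rng = np.random.default_rng(0)
    assert DwellSpec(5.0).draw(rng) == 5.0
    draws = [DwellSpec(8.0, 2.0, "lognormal").draw(rng) for _ in range(400)]
    assert np.mean(draws) == pytest.approx(8.0, rel=0.1)
    assert min(draws) > 0
    u = [DwellSpec(5.0, 1.0, "uniform").draw(rng) for _ in range(100)]
    assert all(4.0 - 1e-9 <= x <= 6.0 + 1e-9 for x in u)
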