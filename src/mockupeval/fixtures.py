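"""Bundled illustrative fixtures: two medication-room layouts and the
four-scenario enactment structure.

The two layouts follow the qualitative design story of a medication-room
mock-up study — an *existing* layout whose automated dispensing cabinet
(ADC) sits as a central island between the preparation counters and the
supplies, with the only sharps container far from the preparation area
and patient bins split over two locations; and a *proposed* layout where
the ADC moves to a wall, a sharps container sits within arm's reach of
the preparation counter and the patient bins are stored together.  All
dimensions are illustrative artifact choices (no floor-plan measurements
exist to reproduce), but the topology is what the analytics exercise.

``recovery_layout`` is a deliberately corridor-shaped room used to plant
unambiguous detours for ground-truth recovery testing: a shelving divider
splits the room into a short southern corridor and a long northern one,
so parking a cart in the southern gap forces a long, measurable detour.
"""

from __future__ import annotations

from .layout import Doorway, ObjectSpec, RoomLayout
from .simulate import AgentScript, DwellSpec, Obstruction, ScenarioScript, TaskStep


def _rect(x0, y0, x1, y1):
    return ((x0, y0), (x1, y0), (x1, y1), (x0, y1))


def existing_layout() -> RoomLayout:
    """9 x 7 m room; ADC as a central island (the congestion driver)."""
    return RoomLayout(
        layout_id="existing",
        boundary=_rect(0.0, 0.0, 9.0, 7.0),
        doorways=(Doorway(name="main", start=(4.0, 0.0), end=(5.0, 0.0)),),
        objects=(
            ObjectSpec("adc", "automated dispensing cabinet", _rect(3.8, 3.0, 5.0, 3.8)),
            ObjectSpec("prep_counter", "medication preparation counter", _rect(0.5, 6.4, 3.5, 7.0)),
            ObjectSpec("prep_counter_2", "secondary preparation counter", _rect(8.4, 3.5, 9.0, 6.0)),
            ObjectSpec("fridge", "medication fridge", _rect(0.0, 5.3, 0.7, 6.2)),
            ObjectSpec("supply_cabinet", "supply cabinet", _rect(0.0, 1.0, 0.6, 3.0)),
            ObjectSpec("sharps", "sharps container", _rect(8.6, 1.2, 9.0, 1.6)),
            ObjectSpec("bins_a", "patient bins (bank A)", _rect(6.5, 6.5, 7.5, 7.0)),
            ObjectSpec("bins_b", "patient bins (bank B)", _rect(1.2, 0.0, 2.2, 0.5)),
            ObjectSpec("wimed_cart", "Wi-Med cart", _rect(7.8, 0.3, 8.4, 0.9), mobility="movable"),
            ObjectSpec("pharmacy_cart", "pharmacy cart", _rect(6.2, 0.2, 6.9, 0.8), mobility="movable"),
        ),
    )


def proposed_layout() -> RoomLayout:
    """ADC moved to the west wall, sharps beside prep, bins consolidated."""
    return RoomLayout(
        layout_id="proposed",
        boundary=_rect(0.0, 0.0, 9.0, 7.0),
        doorways=(Doorway(name="main", start=(4.0, 0.0), end=(5.0, 0.0)),),
        objects=(
            ObjectSpec("adc", "automated dispensing cabinet", _rect(0.0, 1.0, 0.8, 2.6)),
            ObjectSpec("prep_counter", "medication preparation counter", _rect(0.5, 6.4, 3.5, 7.0)),
            ObjectSpec("prep_counter_2", "secondary preparation counter", _rect(8.4, 3.5, 9.0, 6.0)),
            ObjectSpec("fridge", "medication fridge", _rect(0.0, 5.3, 0.7, 6.2)),
            ObjectSpec("supply_cabinet", "supply cabinet", _rect(3.8, 3.0, 5.0, 3.8)),
            ObjectSpec("sharps", "sharps container", _rect(3.7, 6.6, 4.1, 7.0)),
            ObjectSpec("bins_a", "patient bins (bank A)", _rect(6.5, 6.5, 7.5, 7.0)),
            ObjectSpec("bins_b", "patient bins (bank B)", _rect(7.7, 6.5, 8.3, 7.0)),
            ObjectSpec("wimed_cart", "Wi-Med cart", _rect(7.8, 0.3, 8.4, 0.9), mobility="movable"),
            ObjectSpec("pharmacy_cart", "pharmacy cart", _rect(6.2, 0.2, 6.9, 0.8), mobility="movable"),
        ),
    )


def _nurse_pass_steps(scale: float) -> tuple[TaskStep, ...]:
    """Morning medication pass: ADC, prep, bins, fridge, prep, sharps."""
    return (
        TaskStep("adc", DwellSpec(12 * scale, 3 * scale, "lognormal")),
        TaskStep("prep_counter", DwellSpec(14 * scale, 3 * scale, "lognormal")),
        TaskStep("bins_a", DwellSpec(5 * scale, 1 * scale, "lognormal"), tag="access_patient_bin"),
        TaskStep("fridge", DwellSpec(5 * scale, 1 * scale, "lognormal"), tag="access_fridge"),
        TaskStep("prep_counter", DwellSpec(8 * scale, 2 * scale, "lognormal")),
        TaskStep("sharps", DwellSpec(3 * scale, 0.5 * scale, "lognormal"), tag="access_sharps"),
        TaskStep("bins_b", DwellSpec(4 * scale, 1 * scale, "lognormal"), tag="access_patient_bin"),
    )


def _stat_steps(scale: float) -> tuple[TaskStep, ...]:
    """Single urgent (STAT) medication preparation."""
    return (
        TaskStep("adc", DwellSpec(8 * scale, 2 * scale, "lognormal")),
        TaskStep("prep_counter_2", DwellSpec(10 * scale, 2 * scale, "lognormal")),
        TaskStep("sharps", DwellSpec(3 * scale, 0.5 * scale, "lognormal"), tag="access_sharps"),
    )


def _stocking_steps(scale: float) -> tuple[TaskStep, ...]:
    """Pharmacy technician stocking supplies, the ADC and the fridge."""
    return (
        TaskStep("supply_cabinet", DwellSpec(12 * scale, 3 * scale, "lognormal")),
        TaskStep("adc", DwellSpec(10 * scale, 2 * scale, "lognormal")),
        TaskStep("fridge", DwellSpec(6 * scale, 1 * scale, "lognormal"), tag="access_fridge"),
        TaskStep("supply_cabinet", DwellSpec(7 * scale, 2 * scale, "lognormal")),
    )


def demo_script(scenario: int, scale: float = 1.0) -> ScenarioScript:
    """The four-scenario enactment structure.

    Scenario 1: four roles working one at a time (staggered solo entries);
    2: two roles together; 3: three; 4: all four simultaneously.
    ``scale`` shrinks dwell durations (and interruption times) for fast
    test runs without changing the structure.
    """
    mk = lambda role, t, steps: AgentScript(  # noqa: E731
        role=role, entry_time=t, entry_doorway="main", steps=steps, speed=1.2
    )
    n1 = _nurse_pass_steps(scale)
    n2 = _nurse_pass_steps(scale)
    n3 = _stat_steps(scale)
    pt = _stocking_steps(scale)
    solo_gap = 90.0 * scale
    if scenario == 1:
        agents = (
            mk("Nurse 1", 0.0, n1),
            mk("Nurse 2", solo_gap, n2),
            mk("Nurse 3", 2 * solo_gap, n3),
            mk("Pharmacy Technician 1", 3 * solo_gap, pt),
        )
        plan = ()
    elif scenario == 2:
        agents = (mk("Nurse 2", 0.0, n2), mk("Pharmacy Technician 1", 4.0, pt))
        plan = ((20.0 * scale, "Pharmacy Technician 1", "Nurse 2"),)
    elif scenario == 3:
        agents = (
            mk("Nurse 1", 0.0, n1),
            mk("Nurse 3", 4.0, n3),
            mk("Pharmacy Technician 1", 8.0, pt),
        )
        plan = ((25.0 * scale, "Nurse 3", "Nurse 1"),)
    elif scenario == 4:
        agents = (
            mk("Nurse 1", 0.0, n1),
            mk("Nurse 2", 4.0, n2),
            mk("Nurse 3", 8.0, n3),
            mk("Pharmacy Technician 1", 12.0, pt),
        )
        plan = (
            (20.0 * scale, "Nurse 2", "Nurse 1"),
            (30.0 * scale, "Pharmacy Technician 1", "Nurse 3"),
        )
    else:
        raise ValueError("scenario must be 1..4")
    return ScenarioScript(
        scenario_id=f"scenario_{scenario}", agents=agents, interruption_plan=plan
    )


# ---------------------------------------------------------------------------
# ground-truth recovery fixture


def recovery_layout() -> RoomLayout:
    """10 x 8 m room with a shelving divider creating two corridors.

    The divider spans y in [1.3, 7.0] at x in [4.8, 5.4]: the southern gap
    (1.3 m) is blockable by a 0.6 m cart, the northern gap (1.0 m) stays
    open, so blocking the south forces a long detour between the low-set
    east and west targets.
    """
    return RoomLayout(
        layout_id="recovery",
        boundary=_rect(0.0, 0.0, 10.0, 8.0),
        doorways=(Doorway(name="west_door", start=(1.8, 0.0), end=(2.8, 0.0)),),
        objects=(
            ObjectSpec("divider", "shelving divider", _rect(4.8, 1.3, 5.4, 7.0)),
            ObjectSpec("supply_west", "supply cabinet", _rect(0.3, 0.6, 1.0, 1.4)),
            ObjectSpec("adc_east", "automated dispensing cabinet", _rect(9.0, 0.6, 9.7, 1.4)),
            ObjectSpec("fridge_west", "medication fridge", _rect(0.3, 6.0, 1.0, 6.6)),
            ObjectSpec(
                "block_cart", "pharmacy cart", _rect(0.3, 7.3, 0.9, 7.9), mobility="movable"
            ),
            ObjectSpec(
                "brush_cart", "Wi-Med cart", _rect(0.3, 3.4, 0.9, 4.0), mobility="movable"
            ),
        ),
    )


def recovery_script(
    with_detour: bool = True,
    with_contact: bool = True,
    n_interruptions: int = 2,
) -> ScenarioScript:
    """Two-agent script planting a detour, a contact and interruptions.

    The runner walks west -> east -> west through the southern corridor;
    during the return leg a cart blocks the southern gap, forcing the
    northern detour.  A second cart brushes the runner early in the first
    leg, and interruptions are planted while both agents are mid-task.
    """
    runner = AgentScript(
        role="Nurse 1",
        entry_time=0.0,
        entry_doorway="west_door",
        speed=1.2,
        steps=(
            TaskStep("supply_west", DwellSpec(4.0)),
            TaskStep("adc_east", DwellSpec(6.0)),
            TaskStep("supply_west", DwellSpec(4.0), tag="access_supply"),
            TaskStep("fridge_west", DwellSpec(3.0), tag="access_fridge"),
        ),
    )
    stocker = AgentScript(
        role="Pharmacy Technician 1",
        entry_time=3.0,
        entry_doorway="west_door",
        speed=1.1,
        steps=(
            TaskStep("fridge_west", DwellSpec(8.0)),
            TaskStep("supply_west", DwellSpec(8.0)),
            TaskStep("fridge_west", DwellSpec(6.0)),
        ),
    )
    obstructions = []
    if with_detour:
        # blocks the southern gap throughout the runner's return leg
        obstructions.append(
            Obstruction("block_cart", "block", t_start=16.0, t_end=60.0, location=(5.1, 0.65))
        )
    if with_contact:
        obstructions.append(
            Obstruction("brush_cart", "contact", t_start=5.0, t_end=14.0, target_role="Nurse 1")
        )
    interruptions = tuple(
        (10.0 + 6.0 * k, "Pharmacy Technician 1", "Nurse 1") for k in range(n_interruptions)
    )
    return ScenarioScript(
        scenario_id="recovery",
        agents=(runner, stocker),
        interruption_plan=interruptions,
        obstruction_plan=tuple(obstructions),
    )


def congestion_script(scale: float = 1.0) -> ScenarioScript:
    """Four agents whose tasks concentrate at the dispensing cabinet,
    used to reproduce the high-traffic-in-front-of-the-ADC finding."""
    steps = lambda: (  # noqa: E731
        TaskStep("adc", DwellSpec(10 * scale, 2 * scale, "lognormal")),
        TaskStep("prep_counter", DwellSpec(5 * scale, 1 * scale, "lognormal")),
        TaskStep("adc", DwellSpec(8 * scale, 2 * scale, "lognormal")),
    )
    agents = tuple(
        AgentScript(
            role=f"Nurse {k + 1}",
            entry_time=4.0 * k,
            entry_doorway="main",
            steps=steps(),
            speed=1.2,
        )
        for k in range(4)
    )
    return ScenarioScript(scenario_id="congestion", agents=agents)
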