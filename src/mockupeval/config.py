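"""Analysis thresholds and discretization parameters.

All lengths are metres, durations seconds, speeds m/s.  The impediment
thresholds encode the field definition of an impediment: a path between two
objects that is more than 20 per cent *and* at least one metre longer than
necessary because a person or movable object had to be circumvented.
Everything else (body radius, contact margin, dwell and grid parameters) is
an operationalization choice of this package, documented in the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .errors import ValidationError


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds used by every behavioural detector.

    Parameters
    ----------
    detour_ratio_threshold : float
        A leg is a detour only if actual length strictly exceeds this
        multiple of the baseline (default 1.20, i.e. "more than 20%").
    detour_length_threshold : float
        ... and the absolute excess is at least this many metres
        (default 1.0, i.e. "at least one metre").
    person_radius : float
        People are modelled as discs of this radius (m).
    contact_margin : float
        Extra separation still counted as contact for bump coding (m).
    bump_merge_gap : float
        Contacts of the same pair separated by gaps no longer than this
        are merged into one bump event (s).
    dwell_speed_threshold : float
        Smoothed speed below which a subject counts as dwelling (m/s).
    dwell_min_duration : float
        Minimum dwell duration that opens a visit (s).
    grid_cell : float
        Occupancy-grid cell size for link analysis (m).
    high_traffic_percentile : float
        Percentile (over positive-dwell cells) at or above which a cell
        is flagged high-traffic.
    """

    detour_ratio_threshold: float = 1.20
    detour_length_threshold: float = 1.0
    person_radius: float = 0.25
    contact_margin: float = 0.0
    bump_merge_gap: float = 0.5
    dwell_speed_threshold: float = 0.1
    dwell_min_duration: float = 1.5
    grid_cell: float = 0.25
    high_traffic_percentile: float = 90.0

    def __post_init__(self) -> None:
        problems = []
        if not self.detour_ratio_threshold > 1:
            problems.append("detour_ratio_threshold must be > 1")
        for name in (
            "detour_length_threshold",
            "person_radius",
            "contact_margin",
            "bump_merge_gap",
            "dwell_speed_threshold",
            "dwell_min_duration",
        ):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not self.grid_cell > 0:
            problems.append("grid_cell must be > 0")
        if not 0 < self.high_traffic_percentile < 100:
            problems.append("high_traffic_percentile must be in (0, 100)")
        if problems:
            raise ValidationError(problems)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
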