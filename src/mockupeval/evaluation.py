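"""Comparative analytics: layout comparison, validity deltas, surveys, ROI.

* :func:`compare_layouts` tabulates per-measure values for two candidate
  room layouts (the "existing vs proposed" table of a mock-up report).
* :func:`percent_difference` / :func:`summarize_percent_diffs` quantify
  predictive validity: how far simulated task times deviate from observed
  (post-occupancy) times, as integer percents.
* :func:`summarize_survey` / :func:`compare_survey` summarize Likert
  responses and test existing-vs-proposed perception differences with a
  Welch two-sample t-test (one-sided by default: each survey item states
  a directional design hypothesis).
* :func:`compute_roi` is the Phillips-style return on investment: net
  project benefits over project costs, with benefits taken as the *most
  conservative* renovation cost avoidance.
* :func:`count_enactment_surveys` is the survey-count bookkeeping of the
  enactment schedule (roles per scenario x layouts x days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .measures import MeasureReport

MEASURE_STATUSES = ("measured", "not_programmed", "not_possible")


def round_half_away_from_zero(x: float) -> int:
    """Commercial rounding: 0.5 rounds away from zero (so -35.53 -> -36)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# layout comparison


@dataclass(frozen=True)
class LayoutComparison:
    measure: str
    unit: str
    status: str
    value_existing: float | None = None
    value_proposed: float | None = None

    def __post_init__(self):
        if self.status not in MEASURE_STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")
        has_values = self.value_existing is not None and self.value_proposed is not None
        if (self.status == "measured") != has_values:
            raise ValidationError(
                "values must be present exactly when status == 'measured'"
            )


def _extract_measure(report: MeasureReport, label: str) -> float:
    """Resolve a measure label against a report.

    Labels: ``interruptions``, ``bumps``, ``impediments``,
    ``impediments:<subtask_tag>``, ``task_time:<subject_id>`` or
    ``task_time:mean``.
    """
    if label == "interruptions":
        return float(report.n_interruptions)
    if label == "bumps":
        return float(report.n_bumps)
    if label == "impediments":
        return float(report.n_impediments)
    if label.startswith("impediments:"):
        return float(report.n_impediments_by_subtask.get(label.split(":", 1)[1], 0))
    if label.startswith("task_time:"):
        key = label.split(":", 1)[1]
        if key == "mean":
            if not report.task_times:
                raise ValidationError("report has no task times")
            return sum(report.task_times.values()) / len(report.task_times)
        if key not in report.task_times:
            raise ValidationError(f"no task time for subject {key!r}")
        return float(report.task_times[key])
    raise ValidationError(f"unknown measure label {label!r}")


def compare_layouts(
    report_existing: MeasureReport,
    report_proposed: MeasureReport,
    measures: list[tuple[str, str, str]],
) -> list[LayoutComparison]:
    """One comparison row per requested (label, unit, status) measure.

    Rows with status ``not_programmed`` / ``not_possible`` carry no
    numbers: they document measures a study chose or failed to automate.
    Both reports must have been computed under the same thresholds,
    because the counts are threshold-sensitive.
    """
    if report_existing.config != report_proposed.config:
        raise ValidationError(
            "reports were computed with different AnalysisConfig; comparison invalid"
        )
    rows = []
    for (label, unit, status) in measures:
        if status == "measured":
            rows.append(
                LayoutComparison(
                    measure=label,
                    unit=unit,
                    status=status,
                    value_existing=_extract_measure(report_existing, label),
                    value_proposed=_extract_measure(report_proposed, label),
                )
            )
        else:
            rows.append(LayoutComparison(measure=label, unit=unit, status=status))
    return rows


# ---------------------------------------------------------------------------
# predictive-validity percent differences


@dataclass(frozen=True)
class PercentDiff:
    task: str
    reference_seconds: float
    comparison_seconds: float
    percent: int

    def __post_init__(self):
        if self.reference_seconds <= 0:
            raise ValidationError("reference_seconds must be > 0")


def percent_difference(
    reference_seconds: float, comparison_seconds: float, task: str = ""
) -> PercentDiff:
    """Integer percent difference of comparison vs reference time.

    Asymmetric by construction: the reference (observed) time is the
    denominator, so swapping arguments changes the magnitude, not just
    the sign.
    """
    if reference_seconds <= 0:
        raise ValidationError("reference_seconds must be > 0")
    pct = 100.0 * (comparison_seconds - reference_seconds) / reference_seconds
    return PercentDiff(
        task=task,
        reference_seconds=float(reference_seconds),
        comparison_seconds=float(comparison_seconds),
        percent=round_half_away_from_zero(pct),
    )


def summarize_percent_diffs(diffs: list[PercentDiff]) -> tuple[int, float]:
    """(mean %, sample SD %) over the rounded integer percents.

    The mean is reported rounded to integer and the SD (n-1 denominator,
    computed on the rounded percents) to one decimal — the reporting
    convention of validity summaries in this literature.
    """
    if len(diffs) < 2:
        raise ValidationError("need at least 2 percent differences")
    vals = [d.percent for d in diffs]
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    return round_half_away_from_zero(mean), round(math.sqrt(var), 1)


def mmss_to_seconds(text: str) -> float:
    """Parse "m:ss" / "mm:ss" task times into seconds."""
    try:
        m, s = text.split(":")
        return int(m) * 60.0 + float(s)
    except ValueError as exc:
        raise ValidationError(f"not an mm:ss time: {text!r}") from exc


# ---------------------------------------------------------------------------
# surveys


@dataclass(frozen=True)
class SurveySet:
    item: str
    cohort: str
    responses: tuple[int, ...]

    def __post_init__(self):
        if any(r not in (1, 2, 3, 4, 5) for r in self.responses):
            raise ValidationError("Likert responses must be integers in 1..5")


def summarize_survey(sets: list[SurveySet]) -> dict[tuple[str, str], float]:
    """Per-(item, cohort) arithmetic mean, to two decimals."""
    out = {}
    for s in sets:
        if not s.responses:
            raise ValidationError(f"survey item {s.item!r} has no responses")
        out[(s.item, s.cohort)] = round(sum(s.responses) / len(s.responses), 2)
    return out


def compare_survey(
    a: SurveySet, b: SurveySet, tail: str = "one_sided"
) -> tuple[float, float, float]:
    """Welch two-sample t-test between two response sets.

    Returns (t, df, p).  ``t`` is computed as mean(a) - mean(b) over the
    Welch standard error; ``df`` by the Welch-Satterthwaite formula.  The
    one-sided p is taken in the direction of the observed difference
    (survey items state directional hypotheses); ``two_sided`` doubles
    it.  Degenerate zero-variance equal-mean data returns t = 0 with
    one-sided p = 0.5 by convention.
    """
    from scipy import stats  # standard t distribution CDF

    if tail not in ("one_sided", "two_sided"):
        raise ValidationError("tail must be 'one_sided' or 'two_sided'")
    na, nb = len(a.responses), len(b.responses)
    if na < 2 or nb < 2:
        raise ValidationError("each survey set needs at least 2 responses")
    ma = sum(a.responses) / na
    mb = sum(b.responses) / nb
    va = sum((x - ma) ** 2 for x in a.responses) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b.responses) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        t = 0.0
        df = float(na + nb - 2)
        p = 0.5 if tail == "one_sided" else 1.0
        return t, df, p
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p_one = float(stats.t.sf(abs(t), df))
    p = p_one if tail == "one_sided" else 2.0 * p_one
    return float(t), float(df), p


def count_enactment_surveys(
    roles_per_scenario=(4, 2, 3, 4),
    n_layouts: int = 2,
    n_days: int = 3,
    response_rate: float = 1.0,
) -> int:
    """Surveys collected under the enactment schedule: one survey per
    enacted role, every scenario re-enacted in every layout on every day.

    Defaults model four scenarios staffed by 4, 2, 3 and 4 roles, two
    candidate layouts and three days: 13 x 2 x 3 = 78 surveys.
    """
    if not 0.0 <= response_rate <= 1.0:
        raise ValidationError("response_rate must be in [0, 1]")
    total = sum(roles_per_scenario) * n_layouts * n_days
    return round_half_away_from_zero(total * response_rate)


# ---------------------------------------------------------------------------
# return on investment


@dataclass(frozen=True)
class ROIInputs:
    """Cost and benefit components of a mock-up evaluation.

    Costs: ``hard_costs`` (mock-up construction, software, honorariums,
    travel, catering) plus soft costs ``labor_hours x (hourly_rate +
    overhead_rate)``.  ``total_cost_override`` substitutes an externally
    stated total for the component sum when a report prints one.
    Benefits: avoided renovation cost over ``n_rooms`` identical rooms;
    ``conservative`` selects the low per-room estimate (the Phillips
    convention of using the most conservative benefit).
    """

    hard_costs: float = 0.0
    labor_hours: float = 0.0
    hourly_rate: float = 0.0
    overhead_rate: float = 0.0
    n_rooms: int = 1
    per_room_cost_low: float = 0.0
    per_room_cost_high: float = 0.0
    conservative: bool = True
    total_cost_override: float | None = None

    def __post_init__(self):
        problems = []
        for name in (
            "hard_costs", "labor_hours", "hourly_rate", "overhead_rate",
            "per_room_cost_low", "per_room_cost_high",
        ):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.per_room_cost_low > self.per_room_cost_high:
            problems.append("per_room_cost_low must be <= per_room_cost_high")
        if self.n_rooms < 1:
            problems.append("n_rooms must be >= 1")
        if problems:
            raise ValidationError(problems)


@dataclass(frozen=True)
class ROIResult:
    project_costs: float
    project_benefits: float
    roi_percent: float  # exact, before rounding

    @property
    def roi_percent_rounded(self) -> int:
        return round_half_away_from_zero(self.roi_percent)


def compute_roi(inputs: ROIInputs) -> ROIResult:
    """Percent ROI = (benefits - costs) / costs x 100.

    Homogeneous of degree zero in money: scaling every monetary input by
    the same factor leaves the percentage unchanged.
    """
    if inputs.total_cost_override is not None:
        costs = float(inputs.total_cost_override)
    else:
        costs = inputs.hard_costs + inputs.labor_hours * (
            inputs.hourly_rate + inputs.overhead_rate
        )
    if costs <= 0:
        raise ValidationError("project costs must be > 0")
    per_room = (
        inputs.per_room_cost_low if inputs.conservative else inputs.per_room_cost_high
    )
    benefits = inputs.n_rooms * per_room
    roi = (benefits - costs) / costs * 100.0
    return ROIResult(project_costs=costs, project_benefits=benefits, roi_percent=roi)
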