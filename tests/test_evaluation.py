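import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mockupeval import (
    AnalysisConfig,
    ROIInputs,
    SurveySet,
    ValidationError,
    compare_layouts,
    compare_survey,
    compute_roi,
    count_enactment_surveys,
    percent_difference,
    summarize_percent_diffs,
    summarize_survey,
)
from mockupeval.evaluation import mmss_to_seconds, round_half_away_from_zero
from mockupeval.measures import MeasureReport, OccupancyGrid


# ---------------------------------------------------------------------------
# percent differences (predictive validity)


@pytest.mark.parametrize(
    "ref,cmp,expected",
    [
        ("5:39", "6:19", 12),   # medication stocking
        ("1:28", "1:51", 26),   # single STAT preparation
        ("7:50", "5:03", -36),  # morning medication pass
    ],
)
def test_observed_vs_simulated_task_time_percent(ref, cmp, expected):
    d = percent_difference(mmss_to_seconds(ref), mmss_to_seconds(cmp))
    assert d.percent == expected


def test_percent_difference_identity_is_zero():
    assert percent_difference(123.0, 123.0).percent == 0


def test_percent_difference_is_asymmetric():
    """Reference time is the denominator: 100->150 is +50% but 150->100 is
    -33%, not -50%."""
    assert percent_difference(100.0, 150.0).percent == 50
    assert percent_difference(150.0, 100.0).percent == -33


def test_percent_difference_rejects_nonpositive_reference():
    with pytest.raises(ValidationError):
        percent_difference(0.0, 10.0)


def test_summary_of_validity_percents():
    diffs = [
        percent_difference(mmss_to_seconds(a), mmss_to_seconds(b))
        for a, b in [("5:39", "6:19"), ("1:28", "1:51"), ("7:50", "5:03")]
    ]
    mean, sd = summarize_percent_diffs(diffs)
    assert mean == 1
    assert sd == 32.5


def test_summary_of_identical_percents():
    diffs = [percent_difference(100, 105) for _ in range(3)]
    mean, sd = summarize_percent_diffs(diffs)
    assert (mean, sd) == (5, 0.0)


def test_summary_needs_at_least_two():
    with pytest.raises(ValidationError):
        summarize_percent_diffs([percent_difference(100, 105)])


@settings(deadline=None, max_examples=30)
@given(
    percents=st.lists(st.integers(-80, 80), min_size=2, max_size=8),
    shift=st.integers(-20, 20),
)
def test_sd_invariant_under_constant_shift(percents, shift):
    def mk(ps):
        return [percent_difference(100.0, 100.0 + p) for p in ps]

    _, sd0 = summarize_percent_diffs(mk(percents))
    _, sd1 = summarize_percent_diffs(mk([p + shift for p in percents]))
    assert sd0 == sd1


def test_rounding_half_away_from_zero():
    assert round_half_away_from_zero(0.5) == 1
    assert round_half_away_from_zero(-0.5) == -1
    assert round_half_away_from_zero(-35.53) == -36
    assert round_half_away_from_zero(2.4) == 2


# ---------------------------------------------------------------------------
# surveys


def test_survey_mean_rounds_to_two_decimals():
    s = SurveySet("realism", "participants", (4, 5, 5))
    assert summarize_survey([s])[("realism", "participants")] == 4.67


def test_survey_mean_bounds():
    s = SurveySet("x", "c", (5, 5, 5, 5))
    assert summarize_survey([s])[("x", "c")] == 5.00
    t = SurveySet("y", "c", (1, 3, 5))
    assert 1.0 <= summarize_survey([t])[("y", "c")] <= 5.0


def test_survey_rejects_out_of_scale_response():
    with pytest.raises(ValidationError):
        SurveySet("x", "c", (0, 3))


def test_identical_samples_t_zero_p_half():
    a = SurveySet("x", "existing", (3, 3, 3))
    b = SurveySet("x", "proposed", (3, 3, 3))
    t, df, p = compare_survey(a, b, tail="one_sided")
    assert t == 0.0 and p == 0.5


def test_separated_samples_significant():
    a = SurveySet("x", "existing", (1, 1, 1, 1, 2))
    b = SurveySet("x", "proposed", (5, 5, 5, 4, 5))
    _, _, p = compare_survey(a, b, tail="one_sided")
    assert p < 0.001


def test_welch_t_matches_scipy_reference():
    """Welch statistic, df and two-sided p agree with scipy to 1e-8."""
    rng = np.random.default_rng(123)
    for _ in range(20):
        xa = rng.integers(1, 6, size=rng.integers(5, 40))
        xb = rng.integers(1, 6, size=rng.integers(5, 40))
        if np.var(xa) == 0 and np.var(xb) == 0:
            continue
        a = SurveySet("q", "a", tuple(int(v) for v in xa))
        b = SurveySet("q", "b", tuple(int(v) for v in xb))
        t, df, p = compare_survey(a, b, tail="two_sided")
        ref = stats.ttest_ind(xa, xb, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-8)
        assert df == pytest.approx(ref.df, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)


def test_one_sided_p_is_half_two_sided():
    a = SurveySet("q", "a", (1, 2, 3, 4, 5, 1, 2))
    b = SurveySet("q", "b", (3, 4, 5, 4, 5))
    _, _, p1 = compare_survey(a, b, tail="one_sided")
    _, _, p2 = compare_survey(a, b, tail="two_sided")
    assert p2 == pytest.approx(2 * p1)


def test_enactment_survey_count():
    assert count_enactment_surveys() == 78
    assert count_enactment_surveys(roles_per_scenario=(2, 2), n_layouts=1, n_days=2) == 8


# ---------------------------------------------------------------------------
# ROI


def test_roi_conservative_benefit_with_total_override():
    inputs = ROIInputs(
        hard_costs=84838.0,
        labor_hours=152.0,
        hourly_rate=72.87,
        overhead_rate=20.0,
        n_rooms=8,
        per_room_cost_low=75000.0,
        per_room_cost_high=100000.0,
        conservative=True,
        total_cost_override=99016.0,
    )
    result = compute_roi(inputs)
    assert result.project_benefits == 600000.0
    assert result.roi_percent_rounded == 506


def test_roi_component_sum_used_without_override():
    inputs = ROIInputs(
        hard_costs=84838.0, labor_hours=152.0, hourly_rate=72.87, overhead_rate=20.0,
        n_rooms=8, per_room_cost_low=75000.0, per_room_cost_high=100000.0,
    )
    assert compute_roi(inputs).project_costs == pytest.approx(84838.0 + 152 * 92.87)


def test_roi_break_even_and_doubling():
    base = dict(n_rooms=1, per_room_cost_low=50000.0, per_room_cost_high=50000.0)
    assert compute_roi(ROIInputs(total_cost_override=50000.0, **base)).roi_percent == 0.0
    assert compute_roi(ROIInputs(total_cost_override=25000.0, **base)).roi_percent == 100.0


def test_roi_zero_cost_rejected():
    with pytest.raises(ValidationError):
        compute_roi(ROIInputs(per_room_cost_low=1.0, per_room_cost_high=1.0))


@settings(deadline=None, max_examples=30)
@given(k=st.floats(0.01, 1000.0))
def test_roi_homogeneous_in_money(k):
    mk = lambda s: ROIInputs(  # noqa: E731
        hard_costs=1000.0 * s, labor_hours=10.0, hourly_rate=50.0 * s,
        overhead_rate=10.0 * s, n_rooms=3, per_room_cost_low=2000.0 * s,
        per_room_cost_high=3000.0 * s,
    )
    assert compute_roi(mk(k)).roi_percent == pytest.approx(compute_roi(mk(1.0)).roi_percent)


def test_roi_inputs_invariants():
    with pytest.raises(ValidationError):
        ROIInputs(per_room_cost_low=10.0, per_room_cost_high=5.0)
    with pytest.raises(ValidationError):
        ROIInputs(n_rooms=0)


# ---------------------------------------------------------------------------
# layout comparison


def _report(n_int=3, n_bump=5, n_imp=2, by_subtask=None, config=None):
    return MeasureReport(
        scenario_id="s",
        layout_id="l",
        n_interruptions=n_int,
        n_bumps=n_bump,
        n_impediments=n_imp,
        n_impediments_by_subtask=by_subtask or {"access_sharps": 1},
        task_times={"a1": 60.0},
        occupancy=OccupancyGrid((0, 0), 0.25, np.zeros((2, 2)), set()),
        config=config or AnalysisConfig(),
    )


MEASURES = [
    ("interruptions", "occurrences", "measured"),
    ("impediments:access_sharps", "occurrences", "measured"),
    ("searching", "occurrences", "not_possible"),
]


def test_identical_reports_zero_deltas():
    rows = compare_layouts(_report(), _report(), MEASURES)
    for row in rows:
        if row.status == "measured":
            assert row.value_existing == row.value_proposed


def test_comparison_row_values():
    rows = compare_layouts(_report(n_int=50), _report(n_int=6), MEASURES)
    assert rows[0].value_existing == 50 and rows[0].value_proposed == 6


def test_unmeasurable_row_carries_no_values():
    rows = compare_layouts(_report(), _report(), MEASURES)
    not_possible = [r for r in rows if r.status == "not_possible"]
    assert not_possible and not_possible[0].value_existing is None


def test_mismatched_config_rejected():
    other = AnalysisConfig(detour_length_threshold=0.5)
    with pytest.raises(ValidationError, match="different AnalysisConfig"):
        compare_layouts(_report(), _report(config=other), MEASURES)
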