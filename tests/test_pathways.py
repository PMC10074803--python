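"""Metric pathways: worked examples, invariants, and oracle agreement."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialwatch.errors import FilterError
from trialwatch.pathways import (
    FilterState,
    VISIT_STATUSES,
    apply_filter,
    classify_visits,
    data_quality_summary,
    medication_summary,
    percent_vector,
    reconsent_overview,
    recruitment_trajectory,
    retention_summary,
    sae_report_timeliness,
    safety_summary,
)
from trialwatch.store import (
    CentreRecord,
    FormRecord,
    ProtocolSchedule,
    ScheduledVisit,
    StockRecord,
    TrialSnapshot,
    VisitOccurrence,
)

from .conftest import D, one_visit_schedule, participant, sae
from .oracles import day_stepping_visit_status, to_date

ORIGIN = dt.date(2024, 1, 1)


def tiny_snapshot(offset=30, before=7, after=7, grace=14, rand_day=0,
                  actual_day=None, end_day=None, as_of_day=60):
    """One participant, one scheduled visit, export at as_of."""
    export = to_date(max(as_of_day, rand_day, actual_day or 0, end_day or 0))
    status = "on-study" if end_day is None else "ended-early"
    snap = TrialSnapshot(
        export_date=export,
        centres=[CentreRecord(centre_id="A", name="A", activation_date=ORIGIN,
                              target_enrolment=10, expected_rate=1.0)],
        participants=[participant(
            "P1", rand=to_date(rand_day), status=status,
            end=to_date(end_day) if end_day is not None else None,
            reason="withdrawal of consent" if end_day is not None else None,
        )],
        visit_occurrences=(
            [VisitOccurrence(participant_id="P1", visit_code="V1",
                             actual_date=to_date(actual_day))]
            if actual_day is not None else []
        ),
        schedule=one_visit_schedule(offset, before, after, grace),
    )
    return snap


def classify_one(**kw):
    as_of_day = kw.pop("as_of_day", 60)
    snap = tiny_snapshot(as_of_day=as_of_day, **kw)
    table = classify_visits(snap, to_date(as_of_day))
    assert len(table.rows) == 1
    return table.rows[0].status


# ---------------------------------------------------------------------------
# visit classification


@pytest.mark.parametrize(
    "as_of_day, expected",
    [
        (20, "pending"),    # before window opens (day 23)
        (23, "due"),        # window opens
        (25, "due"),
        (37, "due"),        # window closes
        (38, "overdue"),
        (40, "overdue"),
        (51, "overdue"),    # grace end
        (52, "missed"),
    ],
)
def test_unrecorded_visit_walks_due_overdue_missed(as_of_day, expected):
    assert classify_one(as_of_day=as_of_day) == expected


def test_recorded_visit_is_completed_regardless_of_clock():
    assert classify_one(actual_day=32, as_of_day=32) == "completed-in-window"
    assert classify_one(actual_day=32, as_of_day=200) == "completed-in-window"
    assert classify_one(actual_day=40, as_of_day=60) == "completed-out-of-window"


def test_window_opening_after_end_date_is_not_applicable():
    assert classify_one(end_day=10, as_of_day=60) == "not-applicable"
    # window already open at end date: normal clock applies
    assert classify_one(end_day=30, as_of_day=60) == "missed"


def test_as_of_before_all_randomizations_gives_empty_table():
    snap = tiny_snapshot(rand_day=10, as_of_day=30)
    assert classify_visits(snap, to_date(5)).rows == []


def test_classification_agrees_with_day_stepping_oracle():
    rng = np.random.default_rng(20240301)
    for _ in range(300):
        offset = int(rng.integers(0, 120))
        before = int(rng.integers(0, 15))
        after = int(rng.integers(0, 15))
        grace = int(rng.integers(0, 21))
        rand_day = int(rng.integers(0, 30))
        actual_day = (
            int(rng.integers(rand_day, rand_day + offset + after + grace + 3))
            if rng.random() < 0.4 else None
        )
        end_day = (
            int(rng.integers(rand_day + 1, rand_day + offset + 40))
            if actual_day is None and rng.random() < 0.3 else None
        )
        target = rand_day + offset
        boundaries = [target - before - 1, target - before, target + after,
                      target + after + 1, target + after + grace,
                      target + after + grace + 1]
        as_of = int(rng.choice(boundaries + [int(rng.integers(rand_day, target + 60))]))
        as_of = max(as_of, rand_day, actual_day or 0, end_day or 0)
        got = classify_one(offset=offset, before=before, after=after, grace=grace,
                           rand_day=rand_day, actual_day=actual_day,
                           end_day=end_day, as_of_day=as_of)
        want = day_stepping_visit_status(rand_day, offset, before, after, grace,
                                         actual_day, end_day, as_of)
        assert got == want, (offset, before, after, grace, rand_day,
                             actual_day, end_day, as_of)


def test_statuses_partition_all_participant_visit_pairs(sim_snapshot):
    table = classify_visits(sim_snapshot)
    n_participants = sum(
        1 for p in sim_snapshot.participants
        if p.randomization_date <= sim_snapshot.export_date
    )
    n_visits = len(sim_snapshot.schedule.visits)
    assert len(table.rows) == n_participants * n_visits
    seen = {(r.participant_id, r.visit_code) for r in table.rows}
    assert len(seen) == len(table.rows)
    assert sum(table.counts.values()) == len(table.rows)
    assert set(table.counts) == set(VISIT_STATUSES)


# ---------------------------------------------------------------------------
# filtering


def test_empty_filter_is_identity(hand_trial):
    assert apply_filter(hand_trial, FilterState()) == hand_trial
    assert apply_filter(hand_trial, None) == hand_trial


def test_centre_filter_preserves_referential_integrity(hand_trial):
    restricted = apply_filter(hand_trial, FilterState(centres={"A"}))
    assert {c.centre_id for c in restricted.centres} == {"A"}
    assert all(p.centre_id == "A" for p in restricted.participants)
    kept = {p.participant_id for p in restricted.participants}
    for coll in (restricted.visit_occurrences, restricted.forms,
                 restricted.adverse_events, restricted.queries):
        assert all(r.participant_id in kept for r in coll)
    assert all(s.centre_id == "A" for s in restricted.stock)


def test_disjoint_centre_filters_commute_to_empty(hand_trial):
    ab = apply_filter(apply_filter(hand_trial, FilterState(centres={"A"})),
                      FilterState(centres=set()))
    # an explicitly empty centre set keeps nothing
    assert ab.participants == []


def test_unknown_centre_or_visit_code_is_a_filter_error(hand_trial):
    with pytest.raises(FilterError, match="ghost"):
        apply_filter(hand_trial, FilterState(centres={"ghost"}))
    with pytest.raises(FilterError, match="V9"):
        apply_filter(hand_trial, FilterState(visit_codes={"V9"}))


# ---------------------------------------------------------------------------
# safety


def test_safety_hand_counts(hand_trial):
    s = safety_summary(hand_trial)
    assert s.overall.sae_count == 3
    assert s.overall.patients_with_sae == 2
    assert s.overall.randomized == 10
    assert s.overall.sae_per_randomized == pytest.approx(0.3)
    assert s.overall.outcome.levels == [
        "Continuing", "Resolved without sequel", "Resolved with sequel", "others",
    ]
    assert s.overall.outcome.counts == [2, 1, 0, 0]
    assert s.overall.outcome.percents == [66.7, 33.3, 0.0, 0.0]
    assert s.by_centre["A"].sae_count == 2
    assert s.by_centre["B"].sae_count == 1
    assert len(s.patients) == 3  # one row per serious event


def test_safety_empty_trial_all_zero():
    snap = TrialSnapshot(export_date=D(2024, 1, 1), schedule=one_visit_schedule())
    s = safety_summary(snap)
    assert s.overall.sae_count == 0
    assert s.overall.sae_per_randomized == 0.0
    assert s.overall.outcome.counts == [0, 0, 0, 0]
    assert s.overall.outcome.percents == [0.0, 0.0, 0.0, 0.0]


def test_safety_counts_respect_as_of(hand_trial):
    s = safety_summary(hand_trial, as_of=D(2024, 2, 15))
    assert s.overall.sae_count == 1  # only E1 has onset by mid-February


@given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=8))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_percent_vectors_sum_to_100(counts):
    pcts = percent_vector(counts)
    total = sum(counts)
    if total == 0:
        assert pcts == [0.0] * len(counts)
    else:
        assert sum(pcts) == pytest.approx(100.0, abs=1e-9)
        for c, p in zip(counts, pcts):
            assert abs(p - 100.0 * c / total) <= 0.1


# ---------------------------------------------------------------------------
# SAE reporting timeliness


def test_timeliness_hand_computed_hours(hand_trial):
    t = sae_report_timeliness(hand_trial, 72)
    rows = {r.event_id: r for r in t.rows}
    assert rows["E1"].elapsed_hours == 30 and rows["E1"].on_time
    # E2: awareness 03-02 00:00 -> entry 03-08 00:00 = 144 h, late
    assert rows["E2"].elapsed_hours == 144 and rows["E2"].on_time is False
    assert rows["E3"].on_time is None
    assert (t.n_on_time, t.n_late, t.n_unreported) == (1, 1, 1)


def test_entry_exactly_at_deadline_is_on_time(hand_trial):
    snap = hand_trial.model_copy(deep=True)
    snap.adverse_events[0].first_entry_timestamp = dt.datetime(2024, 2, 4, 0, 0)
    t = sae_report_timeliness(snap, 72)
    row = {r.event_id: r for r in t.rows}["E1"]
    assert row.elapsed_hours == 72 and row.on_time


def test_missing_awareness_falls_back_to_onset(hand_trial):
    snap = hand_trial.model_copy(deep=True)
    snap.adverse_events[0].awareness_date = None
    t = sae_report_timeliness(snap, 72)
    row = {r.event_id: r for r in t.rows}["E1"]
    assert row.clock_basis == "onset-fallback"
    assert row.clock_start == dt.datetime(2024, 2, 1, 0, 0)


# ---------------------------------------------------------------------------
# recruitment


def test_expected_accrual_is_linear_and_capped():
    snap = TrialSnapshot(
        export_date=to_date(90),
        centres=[CentreRecord(centre_id="A", name="A", activation_date=ORIGIN,
                              target_enrolment=100, expected_rate=2.0),
                 CentreRecord(centre_id="B", name="B", activation_date=ORIGIN,
                              target_enrolment=3, expected_rate=2.0),
                 CentreRecord(centre_id="Z", name="Z", activation_date=ORIGIN,
                              target_enrolment=100, expected_rate=0.0)],
        schedule=one_visit_schedule(),
    )
    series = recruitment_trajectory(snap, to_date(90))
    assert series.by_centre["A"].expected_cumulative[-1] == pytest.approx(6.0)
    assert series.by_centre["B"].expected_cumulative[-1] == pytest.approx(3.0)  # capped
    assert all(v == 0.0 for v in series.by_centre["Z"].expected_cumulative)
    assert all(v == 0 for v in series.by_centre["A"].actual_cumulative)


def test_actual_accrual_monotone_and_overall_is_sum(sim_snapshot):
    series = recruitment_trajectory(sim_snapshot)
    overall = np.array(series.overall.actual_cumulative)
    assert (np.diff(overall) >= 0).all()
    summed = np.sum(
        [s.actual_cumulative for s in series.by_centre.values()], axis=0
    )
    np.testing.assert_array_equal(overall, summed)
    expected_sum = np.sum(
        [s.expected_cumulative for s in series.by_centre.values()], axis=0
    )
    np.testing.assert_allclose(series.overall.expected_cumulative, expected_sum)


# ---------------------------------------------------------------------------
# retention


def test_retention_hand_counts(hand_trial):
    r = retention_summary(hand_trial)
    assert r.overall.randomized == 10
    assert r.overall.status_counts["ended-early"] == 2
    assert r.overall.retention == pytest.approx(0.8)
    assert r.overall.outcome_available_among_ended == 1
    assert r.overall.ended_early_reasons == {
        "lost to follow-up": 1, "withdrawal of consent": 1,
    }


def test_retention_undefined_with_zero_randomized():
    snap = TrialSnapshot(export_date=D(2024, 1, 1), schedule=one_visit_schedule())
    assert retention_summary(snap).overall.retention is None


# ---------------------------------------------------------------------------
# data quality


def test_completeness_and_entry_lag_hand_computed(hand_trial):
    dq = data_quality_summary(hand_trial, lag_limit_days=7)
    q = dq.overall.by_form_type["primary-endpoint"]
    assert q.completeness == pytest.approx(0.75)  # 3 of 4 fields
    assert q.fully_complete == 0
    # form entered day 13 for a visit on day 10 -> lag 3, within limit
    assert dq.overall.entry_lag.median_days == pytest.approx(3.0)
    assert dq.overall.entry_lag.n_exceeding_limit == 0


def test_query_colour_thresholds(hand_trial):
    dq = data_quality_summary(hand_trial, amber_threshold=5)
    assert dq.by_centre["A"].queries.colour == "amber"  # one open query
    assert dq.by_centre["B"].queries.colour == "green"
    snap = hand_trial.model_copy(deep=True)
    for i in range(6):
        snap.queries.append(snap.queries[0].model_copy(
            update={"query_id": f"QX{i}"}
        ))
    dq = data_quality_summary(snap, amber_threshold=5)
    assert dq.by_centre["A"].queries.colour == "red"


def test_absent_form_type_reports_missing_completeness(hand_trial):
    snap = apply_filter(hand_trial, FilterState(centres={"B"}))
    dq = data_quality_summary(snap)
    # centre B has no forms at all: no form types tabulated
    assert dq.overall.by_form_type == {}
    assert dq.overall.entry_lag.n == 0
    assert dq.overall.entry_lag.median_days is None


# ---------------------------------------------------------------------------
# medication


def test_stock_reconciliation_hand_computed(hand_trial):
    # centre A: 5 completed visits x 1 kit, 10 delivered -> 5 remaining
    m = medication_summary(hand_trial, restock_threshold=4)
    a = m.by_centre["A"]
    assert (a.kits_consumed, a.units_remaining) == (5, 5)
    assert not a.restock_alert
    assert a.discrepancy == 0  # counted 5 == remaining 5
    b = m.by_centre["B"]
    assert (b.kits_consumed, b.units_remaining) == (0, 3)
    assert b.restock_alert  # 3 < 4


def test_missing_stock_suppresses_alert_with_warning(hand_trial):
    snap = hand_trial.model_copy(update={"stock": []})
    m = medication_summary(snap, restock_threshold=4)
    a = m.by_centre["A"]
    assert a.units_remaining is None and not a.restock_alert
    assert any("no stock record" in w for w in a.warnings)
    assert m.total_delivered is None


def test_negative_remaining_is_reported_not_clamped(hand_trial):
    snap = hand_trial.model_copy(deep=True)
    snap.stock = [StockRecord(centre_id="A", units_delivered=2,
                              as_of=snap.export_date)]
    m = medication_summary(snap, restock_threshold=1)
    a = m.by_centre["A"]
    assert a.units_remaining == -3
    assert any("negative" in w for w in a.warnings)


# ---------------------------------------------------------------------------
# re-consent


def test_reconsent_list_pending_only_sorted(hand_trial):
    snap = hand_trial.model_copy(deep=True)
    for pid, done in (("B-2", None), ("A-2", False), ("A-3", True)):
        p = next(x for x in snap.participants if x.participant_id == pid)
        p.reconsent_required = True
        p.reconsent_done = done
    rows = reconsent_overview(snap)
    assert [r.participant_id for r in rows] == ["A-2", "B-2"]


def test_reconsent_includes_off_study_participants_flagged(hand_trial):
    snap = hand_trial.model_copy(deep=True)
    p = next(x for x in snap.participants if x.participant_id == "A-5")
    p.reconsent_required = True
    rows = reconsent_overview(snap)
    assert [(r.participant_id, r.off_study) for r in rows] == [("A-5", True)]
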