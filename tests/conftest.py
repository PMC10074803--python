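"""Shared fixtures: a hand-built minimal trial and a seeded simulation."""

import datetime as dt

import pytest

from trialwatch.store import (
    AdverseEventRecord,
    CentreRecord,
    FormRecord,
    ParticipantRecord,
    ProtocolSchedule,
    QueryRecord,
    ScheduledVisit,
    StockRecord,
    TrialSnapshot,
    VisitOccurrence,
)
from trialwatch.synthetic import generate_trial

D = dt.date


def one_visit_schedule(offset=30, before=7, after=7, grace=14, kits=1,
                       primary=True) -> ProtocolSchedule:
    return ProtocolSchedule(
        visits=[
            ScheduledVisit(
                visit_code="V1",
                label="follow-up",
                target_offset_days=offset,
                window_before_days=before,
                window_after_days=after,
                grace_days=grace,
                carries_primary_outcome=primary,
                kits_dispensed=kits,
            )
        ]
    )


def participant(pid, centre="A", rand=D(2024, 1, 1), status="on-study",
                end=None, reason=None, outcome_avail=False, arm="intervention",
                **extra) -> ParticipantRecord:
    return ParticipantRecord(
        participant_id=pid,
        centre_id=centre,
        randomization_date=rand,
        arm=arm,
        status=status,
        end_date=end,
        end_reason=reason,
        primary_outcome_available=outcome_avail,
        **extra,
    )


def sae(event_id, pid, onset, outcome="Continuing", awareness=None, entry=None,
        severity="moderate", causality="possible", serious=True):
    return AdverseEventRecord(
        event_id=event_id,
        participant_id=pid,
        serious=serious,
        onset_date=onset,
        awareness_date=awareness,
        first_entry_timestamp=entry,
        severity=severity,
        causality=causality,
        outcome=outcome,
        status="ongoing" if outcome == "Continuing" else "closed",
        description="event",
    )


@pytest.fixture
def hand_trial() -> TrialSnapshot:
    """Ten participants in two centres with hand-countable safety, visit,
    data-quality and stock facts (export day = 2024-06-30)."""
    export = D(2024, 6, 30)
    centres = [
        CentreRecord(centre_id="A", name="Centre A", activation_date=D(2024, 1, 1),
                     target_enrolment=100, expected_rate=2.0),
        CentreRecord(centre_id="B", name="Centre B", activation_date=D(2024, 1, 1),
                     target_enrolment=100, expected_rate=2.0),
    ]
    participants = [
        participant("A-1"), participant("A-2"), participant("A-3"),
        participant("A-4"),
        participant("A-5", status="ended-early", end=D(2024, 3, 1),
                    reason="withdrawal of consent", outcome_avail=True),
        participant("B-1", centre="B"), participant("B-2", centre="B"),
        participant("B-3", centre="B"), participant("B-4", centre="B"),
        participant("B-5", centre="B", status="ended-early", end=D(2024, 2, 1),
                    reason="lost to follow-up"),
    ]
    # 3 SAEs in 2 participants; outcomes Continuing, Continuing, Resolved w/o
    events = [
        sae("E1", "A-1", D(2024, 2, 1), "Continuing", awareness=D(2024, 2, 1),
            entry=dt.datetime(2024, 2, 2, 6, 0)),
        sae("E2", "A-1", D(2024, 3, 1), "Continuing", awareness=D(2024, 3, 2),
            entry=dt.datetime(2024, 3, 8, 0, 0)),
        sae("E3", "B-1", D(2024, 4, 1), "Resolved without sequel",
            awareness=D(2024, 4, 1), entry=None),
    ]
    # visits: 5 participants of centre A completed V1 (1 kit each)
    visits = [
        VisitOccurrence(participant_id=f"A-{i}", visit_code="V1",
                        actual_date=D(2024, 2, 1), entry_date=D(2024, 2, 4))
        for i in range(1, 6)
    ]
    forms = [
        FormRecord(participant_id="A-1", form_type="primary-endpoint",
                   visit_code="V1", fields_required=4, fields_completed=3,
                   entry_date=D(2024, 2, 4)),
    ]
    queries = [
        QueryRecord(query_id="Q1", participant_id="A-1",
                    form_type="primary-endpoint", opened_date=D(2024, 2, 10),
                    status="open"),
        QueryRecord(query_id="Q2", participant_id="B-1",
                    form_type="primary-endpoint", opened_date=D(2024, 2, 10),
                    status="resolved", resolved_date=D(2024, 2, 20)),
    ]
    stock = [
        StockRecord(centre_id="A", units_delivered=10, units_counted=5,
                    as_of=export),
        StockRecord(centre_id="B", units_delivered=3, units_counted=None,
                    as_of=export),
    ]
    return TrialSnapshot(
        export_date=export,
        centres=centres,
        participants=participants,
        visit_occurrences=visits,
        forms=forms,
        adverse_events=events,
        queries=queries,
        stock=stock,
        schedule=one_visit_schedule(),
    )


@pytest.fixture(scope="session")
def sim():
    """One mid-size simulated trial (default study conditions, seed 11)."""
    return generate_trial(seed=11)


@pytest.fixture(scope="session")
def sim_snapshot(sim):
    return sim[0]


@pytest.fixture(scope="session")
def sim_truth(sim):
    return sim[1]
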