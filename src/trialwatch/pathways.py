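"""Metric pathways: the per-tab computations over a trial snapshot.

Each operation consumes a :class:`~trialwatch.store.TrialSnapshot`
(optionally pre-restricted with :func:`apply_filter`) and returns a typed
summary carrying the overall values, per-centre breakdowns, and the
actionable participant lists the dashboard renders.

Shared conventions:

* the observation clock is ``as_of`` (defaulting to the export date);
  events dated after it are ignored;
* ratios over an empty denominator are reported as missing (``None``),
  never as zero — except the SAE-per-randomized ratio, which is defined
  as 0 when nobody is randomized;
* percentage vectors are apportioned to one decimal by largest remainder,
  so every vector sums to exactly 100.0 while raw counts are always
  carried alongside.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Literal, Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .errors import FilterError
from .store import (
    AE_CAUSALITIES,
    AE_OUTCOMES,
    AE_SEVERITIES,
    QUERY_STATUSES,
    ParticipantRecord,
    TrialSnapshot,
)

VISIT_STATUSES = (
    "completed-in-window",
    "completed-out-of-window",
    "pending",
    "due",
    "overdue",
    "missed",
    "not-applicable",
)

VisitStatus = Literal[
    "completed-in-window",
    "completed-out-of-window",
    "pending",
    "due",
    "overdue",
    "missed",
    "not-applicable",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


def percent_vector(counts: list[int]) -> list[float]:
    """Apportion counts to percentages with one decimal, summing to 100.

    Largest-remainder allocation at 0.1 % resolution; an all-zero count
    vector yields all-zero percentages.
    """
    total = sum(counts)
    if total == 0:
        return [0.0 for _ in counts]
    exact = [1000.0 * c / total for c in counts]
    floors = [math.floor(e) for e in exact]
    shortfall = 1000 - sum(floors)
    by_remainder = sorted(
        range(len(counts)), key=lambda i: (-(exact[i] - floors[i]), i)
    )
    for i in by_remainder[:shortfall]:
        floors[i] += 1
    return [f / 10.0 for f in floors]


class Distribution(_Model):
    """Counts and percentages over a fixed, ordered set of levels."""

    levels: list[str]
    counts: list[int]
    percents: list[float]

    @classmethod
    def from_counts(cls, levels, counts) -> "Distribution":
        return cls(levels=list(levels), counts=list(counts), percents=percent_vector(list(counts)))

    @classmethod
    def tally(cls, levels, values) -> "Distribution":
        levels = list(levels)
        counts = [0] * len(levels)
        index = {lv: i for i, lv in enumerate(levels)}
        for v in values:
            counts[index[v]] += 1
        return cls.from_counts(levels, counts)


# ---------------------------------------------------------------------------
# filtering


class FilterState(_Model):
    """Restriction of a snapshot to centres / a date range / visit codes.

    The empty filter is the identity.  The date range (closed) restricts
    participants by randomization date; dependent records follow their
    participant.
    """

    centres: Optional[set[str]] = None
    date_from: Optional[dt.date] = None
    date_to: Optional[dt.date] = None
    visit_codes: Optional[set[str]] = None

    def is_empty(self) -> bool:
        return (
            self.centres is None
            and self.date_from is None
            and self.date_to is None
            and self.visit_codes is None
        )


def apply_filter(snapshot: TrialSnapshot, flt: Optional[FilterState]) -> TrialSnapshot:
    """Return the snapshot restricted by ``flt``, preserving referential
    integrity (dropping a participant drops all dependent records)."""
    if flt is None or flt.is_empty():
        return snapshot.model_copy(deep=True)

    known_centres = {c.centre_id for c in snapshot.centres}
    known_codes = set(snapshot.schedule.codes())
    if flt.centres is not None:
        unknown = flt.centres - known_centres
        if unknown:
            raise FilterError(f"unknown centre(s) in filter: {sorted(unknown)}")
    if flt.visit_codes is not None:
        unknown = flt.visit_codes - known_codes
        if unknown:
            raise FilterError(f"unknown visit code(s) in filter: {sorted(unknown)}")

    def keep_participant(p: ParticipantRecord) -> bool:
        if flt.centres is not None and p.centre_id not in flt.centres:
            return False
        if flt.date_from is not None and p.randomization_date < flt.date_from:
            return False
        if flt.date_to is not None and p.randomization_date > flt.date_to:
            return False
        return True

    centres = [
        c for c in snapshot.centres
        if flt.centres is None or c.centre_id in flt.centres
    ]
    participants = [p for p in snapshot.participants if keep_participant(p)]
    kept = {p.participant_id for p in participants}

    def code_ok(code: Optional[str]) -> bool:
        return flt.visit_codes is None or code is None or code in flt.visit_codes

    schedule = snapshot.schedule
    if flt.visit_codes is not None:
        schedule = schedule.model_copy(
            update={"visits": [v for v in schedule.visits if v.visit_code in flt.visit_codes]}
        )

    return snapshot.model_copy(
        update={
            "centres": centres,
            "participants": participants,
            "visit_occurrences": [
                v for v in snapshot.visit_occurrences
                if v.participant_id in kept and code_ok(v.visit_code)
            ],
            "forms": [
                f for f in snapshot.forms
                if f.participant_id in kept and code_ok(f.visit_code)
            ],
            "adverse_events": [
                a for a in snapshot.adverse_events if a.participant_id in kept
            ],
            "queries": [q for q in snapshot.queries if q.participant_id in kept],
            "stock": [
                s for s in snapshot.stock
                if flt.centres is None or s.centre_id in flt.centres
            ],
            "schedule": schedule,
        }
    )


# ---------------------------------------------------------------------------
# visit classification


class VisitRow(_Model):
    participant_id: str
    centre_id: str
    visit_code: str
    status: VisitStatus
    window_open: dt.date
    window_close: dt.date
    grace_end: dt.date
    record_link: str


class VisitStatusTable(_Model):
    as_of: dt.date
    rows: list[VisitRow]
    counts: dict[str, int]
    counts_by_centre: dict[str, dict[str, int]]


def _status_counts(rows: list[VisitRow]) -> dict[str, int]:
    counts = {s: 0 for s in VISIT_STATUSES}
    for r in rows:
        counts[r.status] += 1
    return counts


def classify_visits(
    snapshot: TrialSnapshot,
    as_of: Optional[dt.date] = None,
    url_template: str = "#ecrf/{participant_id}/{record}",
) -> VisitStatusTable:
    """Classify every scheduled visit of every randomized participant.

    For target ``t = randomization + offset`` the window is the closed
    interval ``[t − before, t + after]`` and the grace end ``t + after +
    grace``.  A recorded visit (actual date ≤ as_of) is completed in or out
    of window; an unrecorded one is pending / due / overdue / missed as the
    clock passes window open, window close, and grace end (all bounds
    inclusive).  Unrecorded visits whose window opens after a participant's
    end date are not-applicable.  Participants randomized after ``as_of``
    are excluded, so an ``as_of`` before all randomizations yields an
    empty table.
    """
    as_of = as_of or snapshot.export_date
    day = dt.timedelta(days=1)

    recorded: dict[tuple[str, str], dt.date] = {}
    for v in snapshot.visit_occurrences:
        if v.actual_date is not None and v.actual_date <= as_of:
            key = (v.participant_id, v.visit_code)
            # keep the earliest performance if duplicated
            if key not in recorded or v.actual_date < recorded[key]:
                recorded[key] = v.actual_date

    rows: list[VisitRow] = []
    for p in snapshot.participants:
        if p.randomization_date > as_of:
            continue
        for sv in snapshot.schedule.visits:
            target = p.randomization_date + dt.timedelta(days=sv.target_offset_days)
            window_open = target - dt.timedelta(days=sv.window_before_days)
            window_close = target + dt.timedelta(days=sv.window_after_days)
            grace_end = window_close + dt.timedelta(days=sv.grace_days)

            actual = recorded.get((p.participant_id, sv.visit_code))
            if actual is not None:
                status = (
                    "completed-in-window"
                    if window_open <= actual <= window_close
                    else "completed-out-of-window"
                )
            elif p.end_date is not None and window_open > p.end_date:
                status = "not-applicable"
            elif as_of < window_open:
                status = "pending"
            elif as_of <= window_close:
                status = "due"
            elif as_of <= grace_end:
                status = "overdue"
            else:
                status = "missed"

            rows.append(
                VisitRow(
                    participant_id=p.participant_id,
                    centre_id=p.centre_id,
                    visit_code=sv.visit_code,
                    status=status,
                    window_open=window_open,
                    window_close=window_close,
                    grace_end=grace_end,
                    record_link=url_template.format(
                        participant_id=p.participant_id, record=sv.visit_code
                    ),
                )
            )

    by_centre: dict[str, dict[str, int]] = {}
    for c in snapshot.centres:
        by_centre[c.centre_id] = _status_counts(
            [r for r in rows if r.centre_id == c.centre_id]
        )
    return VisitStatusTable(
        as_of=as_of, rows=rows, counts=_status_counts(rows), counts_by_centre=by_centre
    )


# ---------------------------------------------------------------------------
# safety


class SafetyBreakdown(_Model):
    randomized: int
    sae_count: int
    ae_count: int
    patients_with_sae: int
    sae_per_randomized: float
    severity: Distribution
    causality: Distribution
    outcome: Distribution


class SafetyPatientRow(_Model):
    participant_id: str
    centre_id: str
    event_id: str
    status: str
    description: str
    record_link: str


class SafetySummary(_Model):
    as_of: dt.date
    overall: SafetyBreakdown
    by_centre: dict[str, SafetyBreakdown]
    by_arm: dict[str, SafetyBreakdown]
    patients: list[SafetyPatientRow]


def _safety_breakdown(events, randomized: int) -> SafetyBreakdown:
    saes = [e for e in events if e.serious]
    sae_count = len(saes)
    return SafetyBreakdown(
        randomized=randomized,
        sae_count=sae_count,
        ae_count=len(events),
        patients_with_sae=len({e.participant_id for e in saes}),
        sae_per_randomized=(sae_count / randomized) if randomized else 0.0,
        severity=Distribution.tally(AE_SEVERITIES, [e.severity for e in saes]),
        causality=Distribution.tally(AE_CAUSALITIES, [e.causality for e in saes]),
        outcome=Distribution.tally(AE_OUTCOMES, [e.outcome for e in saes]),
    )


def safety_summary(
    snapshot: TrialSnapshot,
    as_of: Optional[dt.date] = None,
    url_template: str = "#ecrf/{participant_id}/{record}",
) -> SafetySummary:
    """Summarize adverse events with onset on or before ``as_of``.

    Serious events drive the SAE panels (severity / causality / outcome
    distributions, patients-with-SAE, SAE-per-randomized ratio); the AE
    count covers all events.  The ratio denominator is the number of
    participants randomized by ``as_of``; with none randomized the ratio
    is reported as 0.
    """
    as_of = as_of or snapshot.export_date
    centre_of = snapshot.centre_of()
    arm_of = {p.participant_id: p.arm for p in snapshot.participants}
    randomized = [p for p in snapshot.participants if p.randomization_date <= as_of]
    events = [e for e in snapshot.adverse_events if e.onset_date <= as_of]

    by_centre = {}
    for c in snapshot.centres:
        cev = [e for e in events if centre_of.get(e.participant_id) == c.centre_id]
        n = sum(1 for p in randomized if p.centre_id == c.centre_id)
        by_centre[c.centre_id] = _safety_breakdown(cev, n)

    by_arm = {}
    for arm in sorted({p.arm for p in snapshot.participants}):
        aev = [e for e in events if arm_of.get(e.participant_id) == arm]
        n = sum(1 for p in randomized if p.arm == arm)
        by_arm[arm] = _safety_breakdown(aev, n)

    patients = [
        SafetyPatientRow(
            participant_id=e.participant_id,
            centre_id=centre_of.get(e.participant_id, ""),
            event_id=e.event_id,
            status=e.status,
            description=e.description,
            record_link=url_template.format(
                participant_id=e.participant_id, record=e.event_id
            ),
        )
        for e in sorted(events, key=lambda e: (e.participant_id, e.event_id))
        if e.serious
    ]
    return SafetySummary(
        as_of=as_of,
        overall=_safety_breakdown(events, len(randomized)),
        by_centre=by_centre,
        by_arm=by_arm,
        patients=patients,
    )


# ---------------------------------------------------------------------------
# SAE reporting timeliness


class TimelinessRow(_Model):
    event_id: str
    participant_id: str
    centre_id: str
    clock_start: dt.datetime
    first_entry_timestamp: Optional[dt.datetime]
    elapsed_hours: Optional[int]
    on_time: Optional[bool]
    clock_basis: Literal["awareness", "onset-fallback"]


class TimelinessTable(_Model):
    deadline_hours: int
    rows: list[TimelinessRow]
    n_on_time: int
    n_late: int
    n_unreported: int
    counts_by_centre: dict[str, dict[str, int]]


def sae_report_timeliness(snapshot: TrialSnapshot, deadline_hours: int) -> TimelinessTable:
    """Check each SAE's first data entry against the reporting deadline.

    The clock starts at midnight of the awareness date (falling back to
    the onset date when awareness is missing, flagged as such); elapsed
    time is whole hours to the first-entry timestamp, and an entry exactly
    at the deadline is on time (closed bound).  Serious events without a
    first-entry timestamp are counted unreported and excluded from the
    elapsed statistics.
    """
    if deadline_hours <= 0:
        raise ValueError("deadline_hours must be positive")
    centre_of = snapshot.centre_of()
    rows: list[TimelinessRow] = []
    for e in sorted(snapshot.adverse_events, key=lambda e: e.event_id):
        if not e.serious:
            continue
        basis = "awareness" if e.awareness_date is not None else "onset-fallback"
        start_day = e.awareness_date if e.awareness_date is not None else e.onset_date
        clock_start = dt.datetime.combine(start_day, dt.time.min)
        if e.first_entry_timestamp is None:
            elapsed = None
            on_time = None
        else:
            elapsed = int(
                (e.first_entry_timestamp - clock_start).total_seconds() // 3600
            )
            on_time = elapsed <= deadline_hours
        rows.append(
            TimelinessRow(
                event_id=e.event_id,
                participant_id=e.participant_id,
                centre_id=centre_of.get(e.participant_id, ""),
                clock_start=clock_start,
                first_entry_timestamp=e.first_entry_timestamp,
                elapsed_hours=elapsed,
                on_time=on_time,
                clock_basis=basis,
            )
        )

    def tally(rs):
        return {
            "on_time": sum(1 for r in rs if r.on_time is True),
            "late": sum(1 for r in rs if r.on_time is False),
            "unreported": sum(1 for r in rs if r.on_time is None),
        }

    by_centre = {
        c.centre_id: tally([r for r in rows if r.centre_id == c.centre_id])
        for c in snapshot.centres
    }
    overall = tally(rows)
    return TimelinessTable(
        deadline_hours=deadline_hours,
        rows=rows,
        n_on_time=overall["on_time"],
        n_late=overall["late"],
        n_unreported=overall["unreported"],
        counts_by_centre=by_centre,
    )


# ---------------------------------------------------------------------------
# recruitment


class AccrualSeries(_Model):
    dates: list[dt.date]
    actual_cumulative: list[int]
    expected_cumulative: list[float]


class RecruitmentSeries(_Model):
    as_of: dt.date
    overall: AccrualSeries
    by_centre: dict[str, AccrualSeries]
    total_actual: int
    total_expected: float


def recruitment_trajectory(
    snapshot: TrialSnapshot, as_of: Optional[dt.date] = None
) -> RecruitmentSeries:
    """Daily cumulative actual vs expected accrual, per centre and overall.

    Expected accrual at a centre is linear from its activation date at
    ``expected_rate`` participants per 30 days, capped at its enrolment
    target; the overall series is the pointwise sum over centres.
    """
    as_of = as_of or snapshot.export_date
    starts = [c.activation_date for c in snapshot.centres]
    rand_dates = [p.randomization_date for p in snapshot.participants
                  if p.randomization_date <= as_of]
    if starts or rand_dates:
        first = min(starts + rand_dates)
    else:
        first = as_of
    n_days = max((as_of - first).days, 0) + 1
    dates = [first + dt.timedelta(days=i) for i in range(n_days)]

    by_centre: dict[str, AccrualSeries] = {}
    overall_actual = np.zeros(n_days, dtype=int)
    overall_expected = np.zeros(n_days, dtype=float)
    for c in snapshot.centres:
        actual = np.zeros(n_days, dtype=int)
        for p in snapshot.participants:
            if p.centre_id == c.centre_id and p.randomization_date <= as_of:
                actual[(p.randomization_date - first).days :] += 1
        elapsed = np.array([(d - c.activation_date).days for d in dates], dtype=float)
        expected = np.minimum(
            float(c.target_enrolment),
            c.expected_rate * np.maximum(elapsed, 0.0) / 30.0,
        )
        by_centre[c.centre_id] = AccrualSeries(
            dates=dates,
            actual_cumulative=actual.tolist(),
            expected_cumulative=expected.tolist(),
        )
        overall_actual += actual
        overall_expected += expected

    overall = AccrualSeries(
        dates=dates,
        actual_cumulative=overall_actual.tolist(),
        expected_cumulative=overall_expected.tolist(),
    )
    return RecruitmentSeries(
        as_of=as_of,
        overall=overall,
        by_centre=by_centre,
        total_actual=int(overall_actual[-1]) if n_days else 0,
        total_expected=float(overall_expected[-1]) if n_days else 0.0,
    )


# ---------------------------------------------------------------------------
# retention


class RetentionBreakdown(_Model):
    randomized: int
    status_counts: dict[str, int]
    ended_early_reasons: dict[str, int]
    outcome_available_among_ended: int
    retention: Optional[float]


class RetentionSummary(_Model):
    as_of: dt.date
    overall: RetentionBreakdown
    by_centre: dict[str, RetentionBreakdown]


def _retention_breakdown(participants: list[ParticipantRecord]) -> RetentionBreakdown:
    statuses = {"on-study": 0, "ended-early": 0, "completed": 0}
    reasons: dict[str, int] = {}
    outcome_avail = 0
    for p in participants:
        statuses[p.status] += 1
        if p.status == "ended-early":
            reasons[p.end_reason or "unspecified"] = (
                reasons.get(p.end_reason or "unspecified", 0) + 1
            )
            if p.primary_outcome_available:
                outcome_avail += 1
    n = len(participants)
    return RetentionBreakdown(
        randomized=n,
        status_counts=statuses,
        ended_early_reasons=dict(sorted(reasons.items())),
        outcome_available_among_ended=outcome_avail,
        retention=(1.0 - statuses["ended-early"] / n) if n else None,
    )


def retention_summary(
    snapshot: TrialSnapshot, as_of: Optional[dt.date] = None
) -> RetentionSummary:
    """Participant status counts, early-exit reasons, and the retention
    proportion (1 − ended-early / randomized; missing when nobody is
    randomized)."""
    as_of = as_of or snapshot.export_date
    randomized = [p for p in snapshot.participants if p.randomization_date <= as_of]
    by_centre = {
        c.centre_id: _retention_breakdown(
            [p for p in randomized if p.centre_id == c.centre_id]
        )
        for c in snapshot.centres
    }
    return RetentionSummary(
        as_of=as_of, overall=_retention_breakdown(randomized), by_centre=by_centre
    )


# ---------------------------------------------------------------------------
# data quality


class FormTypeQuality(_Model):
    n_forms: int
    fields_required: int
    fields_completed: int
    completeness: Optional[float]
    fully_complete: int


class EntryLagStats(_Model):
    n: int
    median_days: Optional[float]
    p90_days: Optional[float]
    n_exceeding_limit: int


class QueryStats(_Model):
    counts: dict[str, int]
    open_queries: int
    colour: Literal["green", "amber", "red"]


class DataQualityBreakdown(_Model):
    by_form_type: dict[str, FormTypeQuality]
    entry_lag: EntryLagStats
    queries: QueryStats


class DataQualitySummary(_Model):
    as_of: dt.date
    lag_limit_days: int
    overall: DataQualityBreakdown
    by_centre: dict[str, DataQualityBreakdown]


def _query_colour(open_queries: int, amber_threshold: int) -> str:
    if open_queries == 0:
        return "green"
    if open_queries <= amber_threshold:
        return "amber"
    return "red"


def _dq_breakdown(forms, lags, queries, lag_limit_days, amber_threshold, form_types):
    by_type: dict[str, FormTypeQuality] = {}
    for ft in form_types:
        fs = [f for f in forms if f.form_type == ft]
        req = sum(f.fields_required for f in fs)
        comp = sum(f.fields_completed for f in fs)
        by_type[ft] = FormTypeQuality(
            n_forms=len(fs),
            fields_required=req,
            fields_completed=comp,
            completeness=(comp / req) if req else None,
            fully_complete=sum(1 for f in fs if f.fields_completed == f.fields_required),
        )
    lag_arr = np.asarray(lags, dtype=float)
    entry_lag = EntryLagStats(
        n=len(lags),
        median_days=float(np.median(lag_arr)) if len(lags) else None,
        p90_days=float(np.percentile(lag_arr, 90)) if len(lags) else None,
        n_exceeding_limit=int(np.sum(lag_arr > lag_limit_days)) if len(lags) else 0,
    )
    counts = {s: sum(1 for q in queries if q.status == s) for s in QUERY_STATUSES}
    open_q = counts["open"]
    return DataQualityBreakdown(
        by_form_type=by_type,
        entry_lag=entry_lag,
        queries=QueryStats(
            counts=counts, open_queries=open_q, colour=_query_colour(open_q, amber_threshold)
        ),
    )


def data_quality_summary(
    snapshot: TrialSnapshot,
    as_of: Optional[dt.date] = None,
    lag_limit_days: int = 7,
    amber_threshold: int = 5,
) -> DataQualitySummary:
    """Form completeness, entry-lag distribution, and query status.

    Completeness per form type pools completed over required fields; the
    entry lag of a visit-linked form is its entry date minus the visit's
    actual date in days; query colour per centre is green with no open
    queries, amber with at most ``amber_threshold``, red beyond.
    """
    if lag_limit_days < 0:
        raise ValueError("lag_limit_days must be >= 0")
    as_of = as_of or snapshot.export_date
    centre_of = snapshot.centre_of()
    form_types = sorted({f.form_type for f in snapshot.forms})

    visit_date = {
        (v.participant_id, v.visit_code): v.actual_date
        for v in snapshot.visit_occurrences
        if v.actual_date is not None
    }
    forms = [f for f in snapshot.forms if f.entry_date is None or f.entry_date <= as_of]

    def lags_for(fs):
        out = []
        for f in fs:
            if f.visit_code is None or f.entry_date is None:
                continue
            actual = visit_date.get((f.participant_id, f.visit_code))
            if actual is not None:
                out.append((f.entry_date - actual).days)
        return out

    queries = [q for q in snapshot.queries if q.opened_date <= as_of]

    overall = _dq_breakdown(
        forms, lags_for(forms), queries, lag_limit_days, amber_threshold, form_types
    )
    by_centre = {}
    for c in snapshot.centres:
        cf = [f for f in forms if centre_of.get(f.participant_id) == c.centre_id]
        cq = [q for q in queries if centre_of.get(q.participant_id) == c.centre_id]
        by_centre[c.centre_id] = _dq_breakdown(
            cf, lags_for(cf), cq, lag_limit_days, amber_threshold, form_types
        )
    return DataQualitySummary(
        as_of=as_of, lag_limit_days=lag_limit_days, overall=overall, by_centre=by_centre
    )


# ---------------------------------------------------------------------------
# medication / stock


class CentreMedication(_Model):
    centre_id: str
    kits_consumed: int
    units_delivered: Optional[int]
    units_remaining: Optional[int]
    units_counted: Optional[int]
    discrepancy: Optional[int]
    restock_alert: bool
    warnings: list[str]


class MedicationSummary(_Model):
    as_of: dt.date
    restock_threshold: int
    by_centre: dict[str, CentreMedication]
    total_consumed: int
    total_delivered: Optional[int]


def medication_summary(
    snapshot: TrialSnapshot,
    as_of: Optional[dt.date] = None,
    restock_threshold: int = 5,
) -> MedicationSummary:
    """Kit consumption vs delivered stock per centre.

    Consumption sums the protocol's kits-dispensed over completed visits;
    remaining stock is the latest cumulative delivery minus consumption
    (negative values are reported with a warning, not clamped); a restock
    alert fires when remaining falls below the threshold.  Centres without
    stock records get a missing remaining value, a suppressed alert, and a
    warning.
    """
    as_of = as_of or snapshot.export_date
    kits = {v.visit_code: v.kits_dispensed for v in snapshot.schedule.visits}
    centre_of = snapshot.centre_of()

    consumed: dict[str, int] = {c.centre_id: 0 for c in snapshot.centres}
    for v in snapshot.visit_occurrences:
        if v.actual_date is not None and v.actual_date <= as_of:
            centre = centre_of.get(v.participant_id)
            if centre in consumed:
                consumed[centre] += kits.get(v.visit_code, 0)

    latest_stock: dict[str, object] = {}
    for s in snapshot.stock:
        if s.as_of <= as_of:
            prev = latest_stock.get(s.centre_id)
            if prev is None or s.as_of > prev.as_of:
                latest_stock[s.centre_id] = s

    by_centre: dict[str, CentreMedication] = {}
    total_delivered = 0
    any_delivered = False
    for c in snapshot.centres:
        warnings: list[str] = []
        stock = latest_stock.get(c.centre_id)
        if stock is None:
            delivered = remaining = counted = discrepancy = None
            alert = False
            warnings.append("no stock record; restock alert suppressed")
        else:
            any_delivered = True
            delivered = stock.units_delivered
            total_delivered += delivered
            remaining = delivered - consumed[c.centre_id]
            if remaining < 0:
                warnings.append(
                    f"negative remaining stock ({remaining}): consumption exceeds deliveries"
                )
            counted = stock.units_counted
            discrepancy = (counted - remaining) if counted is not None else None
            if discrepancy:
                warnings.append(
                    f"counted stock differs from computed remaining by {discrepancy}"
                )
            alert = remaining < restock_threshold
        by_centre[c.centre_id] = CentreMedication(
            centre_id=c.centre_id,
            kits_consumed=consumed[c.centre_id],
            units_delivered=delivered,
            units_remaining=remaining,
            units_counted=counted,
            discrepancy=discrepancy,
            restock_alert=alert,
            warnings=warnings,
        )
    return MedicationSummary(
        as_of=as_of,
        restock_threshold=restock_threshold,
        by_centre=by_centre,
        total_consumed=sum(consumed.values()),
        total_delivered=total_delivered if any_delivered else None,
    )


# ---------------------------------------------------------------------------
# re-consent


class ReconsentRow(_Model):
    participant_id: str
    centre_id: str
    reconsent_done: Optional[bool]
    off_study: bool
    record_link: str


def reconsent_overview(
    snapshot: TrialSnapshot,
    as_of: Optional[dt.date] = None,
    url_template: str = "#ecrf/{participant_id}/{record}",
) -> list[ReconsentRow]:
    """Participants still needing a re-consent, sorted by centre then id.

    Participants no longer on study are kept in the list but flagged
    ``off_study`` so sites can document rather than chase them.
    """
    as_of = as_of or snapshot.export_date
    rows = [
        ReconsentRow(
            participant_id=p.participant_id,
            centre_id=p.centre_id,
            reconsent_done=p.reconsent_done,
            off_study=p.status != "on-study",
            record_link=url_template.format(
                participant_id=p.participant_id, record="consent"
            ),
        )
        for p in snapshot.participants
        if p.randomization_date <= as_of
        and p.reconsent_required
        and not p.reconsent_done
    ]
    rows.sort(key=lambda r: (r.centre_id, r.participant_id))
    return rows
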