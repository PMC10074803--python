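"""Seeded simulation of a multicentre randomized controlled trial.

The generator emulates the accumulating daily export of an ongoing
two-arm trial: per-centre Poisson accrual from staggered activation
dates, a geometric (constant daily hazard) dropout process, exposure-
scaled Poisson adverse events with categorical severity/causality/
outcome, protocol visits performed inside their windows except for a
configurable noncompliance fraction, geometric data-entry lags, field
missingness, and an open/answered/resolved query process.  Every emitted
snapshot passes the full integrity validator by construction, and the
realized ground truth (true dropout proportion, SAE rate, mean entry
lag, per-centre exposure) is returned alongside for parameter-recovery
testing.

Randomness: one integer master seed; each stochastic process draws from
its own named stream (``SeedSequence([seed, crc32(name)])``), so adding
a new process never perturbs the draws of existing ones.
"""

from __future__ import annotations

import datetime as dt
import zlib
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .errors import FaultSpecError, TrialWatchError
from .store import (
    AE_CAUSALITIES,
    AE_OUTCOMES,
    AE_SEVERITIES,
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


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CentreParams(_Model):
    centre_id: str
    name: str = ""
    activation_day: int = Field(ge=0, description="days after trial start")
    accrual_rate: float = Field(ge=0, description="expected participants per 30 days")
    target: int = Field(ge=0)


def default_schedule() -> ProtocolSchedule:
    """A four-visit schedule typical of a 6-month outcome trial:
    baseline, one-month, three-month, and the primary-outcome visit at
    six months, with ±7/±14-day windows and a 14-day grace period."""
    return ProtocolSchedule(
        visits=[
            ScheduledVisit(
                visit_code="V0", label="baseline", target_offset_days=0,
                window_before_days=0, window_after_days=3, grace_days=7,
                kits_dispensed=1,
            ),
            ScheduledVisit(
                visit_code="V1", label="month 1", target_offset_days=30,
                window_before_days=7, window_after_days=7, grace_days=14,
                kits_dispensed=1,
            ),
            ScheduledVisit(
                visit_code="V2", label="month 3", target_offset_days=90,
                window_before_days=14, window_after_days=14, grace_days=14,
                kits_dispensed=1,
            ),
            ScheduledVisit(
                visit_code="V3", label="month 6 (primary outcome)",
                target_offset_days=180, window_before_days=14,
                window_after_days=14, grace_days=14,
                carries_primary_outcome=True,
            ),
        ]
    )


def default_centres(n: int = 5) -> list[CentreParams]:
    """Five sites activating one month apart, each expecting four
    participants per 30 days toward a 60-participant target."""
    return [
        CentreParams(
            centre_id=f"C{i + 1:02d}",
            name=f"Centre {i + 1}",
            activation_day=30 * i,
            accrual_rate=4.0,
            target=60,
        )
        for i in range(n)
    ]


class SyntheticTrialParams(_Model):
    """Generator configuration; defaults describe a mid-size academic
    multicentre trial observed mid-conduct (day 540 of follow-up)."""

    start_date: dt.date = dt.date(2024, 1, 1)
    trial_days: int = Field(default=540, gt=0)
    centres: list[CentreParams] = Field(default_factory=default_centres)
    schedule: ProtocolSchedule = Field(default_factory=default_schedule)
    arms: list[str] = Field(default_factory=lambda: ["intervention", "control"])
    allocation: list[float] = Field(default_factory=lambda: [0.5, 0.5])
    dropout_hazard_per_day: float = Field(default=5e-4, ge=0, lt=1)
    sae_rate_per_90d: float = Field(default=0.08, ge=0)
    ae_rate_multiplier: float = Field(default=3.0, ge=0)
    severity_probs: list[float] = Field(default_factory=lambda: [0.50, 0.35, 0.15])
    causality_probs: list[float] = Field(default_factory=lambda: [0.45, 0.30, 0.18, 0.07])
    outcome_probs: list[float] = Field(default_factory=lambda: [0.30, 0.45, 0.15, 0.10])
    entry_lag_p: float = Field(default=0.4, gt=0, le=1,
                               description="geometric parameter; lag days = G(p) - 1")
    awareness_delay_max_days: int = Field(default=2, ge=0)
    visit_noncompliance: float = Field(default=0.08, ge=0, le=1)
    out_of_window_prob: float = Field(default=0.05, ge=0, le=1)
    missing_field_prob: float = Field(default=0.05, ge=0, le=1)
    query_prob: float = Field(default=0.15, ge=0, le=1)
    query_resolution_daily: float = Field(default=0.10, ge=0, le=1)
    reconsent_required_prob: float = Field(default=0.10, ge=0, le=1)
    reconsent_done_prob: float = Field(default=0.5, ge=0, le=1)
    fields_required: dict[str, int] = Field(
        default_factory=lambda: {
            "primary-endpoint": 12,
            "secondary-endpoint": 8,
            "sae-form": 10,
        }
    )
    sae_form_complete_prob: float = Field(default=0.9, ge=0, le=1)
    seed: int = 0


class GroundTruth(_Model):
    """Configured parameters plus the realized totals of one simulation."""

    params: SyntheticTrialParams
    n_randomized: int
    n_dropouts: int
    true_dropout_proportion: Optional[float]
    expected_dropouts: float
    dropout_variance: float
    n_saes: int
    total_exposure_days: int
    true_sae_rate_per_90d: Optional[float]
    n_entry_lags: int
    true_mean_entry_lag: Optional[float]
    expected_accrual_by_centre: dict[str, float]
    actual_accrual_by_centre: dict[str, int]


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _geometric_days(rng: np.random.Generator, p: float) -> int:
    """Support {1, 2, ...}; guarded for p == 0 (event never happens)."""
    if p <= 0:
        return 10**9
    return int(rng.geometric(p))


def generate_trial(params: Optional[SyntheticTrialParams] = None,
                   seed: Optional[int] = None) -> tuple[TrialSnapshot, GroundTruth]:
    """Simulate one trial and return the snapshot with its ground truth.

    Identical ``params`` (including the seed) reproduce the snapshot
    exactly.  ``seed``, if given, overrides ``params.seed``.
    """
    params = params or SyntheticTrialParams()
    if seed is not None:
        params = params.model_copy(update={"seed": int(seed)})
    if len(params.arms) != len(params.allocation):
        raise TrialWatchError("arms and allocation must have equal length")
    if abs(sum(params.allocation) - 1.0) > 1e-9:
        raise TrialWatchError("allocation must sum to 1")
    for name, probs, levels in (
        ("severity_probs", params.severity_probs, AE_SEVERITIES),
        ("causality_probs", params.causality_probs, AE_CAUSALITIES),
        ("outcome_probs", params.outcome_probs, AE_OUTCOMES),
    ):
        if len(probs) != len(levels) or abs(sum(probs) - 1.0) > 1e-9:
            raise TrialWatchError(f"{name} must be a probability vector over {levels}")

    start = params.start_date
    export_date = start + dt.timedelta(days=params.trial_days)
    rng_accrual = _stream(params.seed, "accrual")
    rng_part = _stream(params.seed, "participant")
    rng_visit = _stream(params.seed, "visits")
    rng_ae = _stream(params.seed, "adverse-events")
    rng_query = _stream(params.seed, "queries")
    rng_stock = _stream(params.seed, "stock")

    centres = [
        CentreRecord(
            centre_id=c.centre_id,
            name=c.name or c.centre_id,
            activation_date=start + dt.timedelta(days=c.activation_day),
            target_enrolment=c.target,
            expected_rate=c.accrual_rate,
        )
        for c in params.centres
    ]

    # --- accrual: per-centre daily Poisson, truncated at the target -------
    recruits: list[tuple[dt.date, str]] = []
    expected_accrual: dict[str, float] = {}
    for c in params.centres:
        active_days = max(params.trial_days - c.activation_day, 0)
        daily = c.accrual_rate / 30.0
        expected_accrual[c.centre_id] = min(float(c.target), daily * active_days)
        count = 0
        for d in range(active_days):
            if count >= c.target:
                break
            n = int(rng_accrual.poisson(daily))
            n = min(n, c.target - count)
            day = start + dt.timedelta(days=c.activation_day + d)
            recruits.extend((day, c.centre_id) for _ in range(n))
            count += n
    recruits.sort(key=lambda t: (t[0], t[1]))

    participants: list[ParticipantRecord] = []
    visit_rows: list[VisitOccurrence] = []
    form_rows: list[FormRecord] = []
    ae_rows: list[AdverseEventRecord] = []
    query_rows: list[QueryRecord] = []

    n_dropouts = 0
    expected_dropouts = 0.0
    dropout_variance = 0.0
    total_exposure = 0
    n_saes = 0
    entry_lags: list[int] = []
    seq_by_centre: dict[str, int] = {}
    visit_defs = params.schedule.visits
    last_visit = visit_defs[-1] if visit_defs else None
    form_seq = 0
    query_seq = 0
    ae_seq = 0

    def entry_lag() -> int:
        lag = _geometric_days(rng_visit, params.entry_lag_p) - 1
        entry_lags.append(lag)
        return lag

    for rand_date, centre_id in recruits:
        seq = seq_by_centre.get(centre_id, 0) + 1
        seq_by_centre[centre_id] = seq
        pid = f"{centre_id}-{seq:04d}"
        arm = params.arms[int(rng_part.choice(len(params.arms), p=params.allocation))]
        age = int(np.clip(round(rng_part.normal(62, 12)), 18, 95))
        sex = "F" if rng_part.random() < 0.5 else "M"

        max_followup = (export_date - rand_date).days
        dropout_after = _geometric_days(rng_part, params.dropout_hazard_per_day)

        # per-participant expected dropout probability under the configured
        # hazard over the at-risk window (for the recovery oracle)
        h = params.dropout_hazard_per_day
        horizon = max_followup
        if last_visit is not None:
            horizon = min(horizon, last_visit.target_offset_days
                          + last_visit.window_after_days)
        p_drop = 1.0 - (1.0 - h) ** horizon if h > 0 else 0.0
        expected_dropouts += p_drop
        dropout_variance += p_drop * (1.0 - p_drop)

        end_date: Optional[dt.date] = None
        status = "on-study"
        if dropout_after <= min(max_followup, horizon):
            status = "ended-early"
            end_date = rand_date + dt.timedelta(days=dropout_after)
            n_dropouts += 1

        # --- visits ---------------------------------------------------
        performed: dict[str, dt.date] = {}
        primary_done = False
        for sv in visit_defs:
            target = rand_date + dt.timedelta(days=sv.target_offset_days)
            window_open = target - dt.timedelta(days=sv.window_before_days)
            window_close = target + dt.timedelta(days=sv.window_after_days)
            skip = rng_visit.random() < params.visit_noncompliance
            out_of_window = (not skip) and rng_visit.random() < params.out_of_window_prob
            if out_of_window:
                actual = window_close + dt.timedelta(
                    days=int(rng_visit.integers(1, sv.grace_days + 2))
                )
            else:
                span = (window_close - window_open).days
                actual = window_open + dt.timedelta(
                    days=int(rng_visit.integers(0, span + 1))
                )
            if skip:
                continue
            if actual < rand_date:
                actual = rand_date
            if end_date is not None and actual >= end_date:
                continue
            if actual > export_date:
                continue
            performed[sv.visit_code] = actual
            entry = actual + dt.timedelta(days=entry_lag())
            visit_rows.append(
                VisitOccurrence(
                    participant_id=pid,
                    visit_code=sv.visit_code,
                    actual_date=actual,
                    entry_date=None if entry > export_date else entry,
                )
            )
            if sv.carries_primary_outcome and actual is not None:
                primary_done = True

            form_type = ("primary-endpoint" if sv.carries_primary_outcome
                         else "secondary-endpoint")
            required = params.fields_required.get(form_type, 8)
            completed = required - int(
                rng_visit.binomial(required, params.missing_field_prob)
            )
            form_seq += 1
            form_rows.append(
                FormRecord(
                    participant_id=pid,
                    form_type=form_type,
                    visit_code=sv.visit_code,
                    fields_required=required,
                    fields_completed=completed,
                    entry_date=None if entry > export_date else entry,
                )
            )

        if (status == "on-study" and last_visit is not None
                and last_visit.visit_code in performed):
            status = "completed"
            end_date = performed[last_visit.visit_code]

        exposure = ((end_date or export_date) - rand_date).days
        total_exposure += exposure

        reconsent_required = rng_part.random() < params.reconsent_required_prob
        reconsent_done = (
            bool(rng_part.random() < params.reconsent_done_prob)
            if reconsent_required else None
        )
        participants.append(
            ParticipantRecord(
                participant_id=pid,
                centre_id=centre_id,
                randomization_date=rand_date,
                arm=arm,
                status=status,
                end_date=end_date,
                end_reason=(
                    str(rng_part.choice([
                        "withdrawal of consent", "lost to follow-up",
                        "adverse event", "physician decision",
                    ]))
                    if status == "ended-early" else None
                ),
                primary_outcome_available=primary_done,
                reconsent_required=reconsent_required,
                reconsent_done=reconsent_done,
                characteristics={"age": age, "sex": sex},
            )
        )

        # --- adverse events -------------------------------------------
        lam_sae = params.sae_rate_per_90d * exposure / 90.0
        lam_ae = lam_sae * params.ae_rate_multiplier
        for serious, lam in ((True, lam_sae), (False, lam_ae)):
            for _ in range(int(rng_ae.poisson(lam)) if lam > 0 else 0):
                onset = rand_date + dt.timedelta(
                    days=int(rng_ae.integers(0, max(exposure, 1)))
                )
                ae_seq += 1
                severity = str(rng_ae.choice(AE_SEVERITIES, p=params.severity_probs))
                causality = str(rng_ae.choice(AE_CAUSALITIES, p=params.causality_probs))
                outcome = str(rng_ae.choice(AE_OUTCOMES, p=params.outcome_probs))
                awareness = first_entry = None
                form_complete = True
                if serious:
                    n_saes += 1
                    awareness = onset + dt.timedelta(
                        days=int(rng_ae.integers(0, params.awareness_delay_max_days + 1))
                    )
                    awareness = min(awareness, export_date)
                    lag = _geometric_days(rng_ae, params.entry_lag_p) - 1
                    entry_day = awareness + dt.timedelta(days=lag)
                    hour = int(rng_ae.integers(0, 24))
                    minute = int(rng_ae.integers(0, 60))
                    if entry_day <= export_date:
                        first_entry = dt.datetime.combine(
                            entry_day, dt.time(hour, minute)
                        )
                    form_complete = bool(
                        rng_ae.random() < params.sae_form_complete_prob
                    )
                    required = params.fields_required.get("sae-form", 10)
                    completed = required if form_complete else required - int(
                        rng_ae.integers(1, max(required // 2, 2))
                    )
                    form_seq += 1
                    form_rows.append(
                        FormRecord(
                            participant_id=pid,
                            form_type="sae-form",
                            visit_code=None,
                            fields_required=required,
                            fields_completed=completed,
                            entry_date=(first_entry.date() if first_entry else None),
                        )
                    )
                ae_rows.append(
                    AdverseEventRecord(
                        event_id=f"AE{ae_seq:05d}",
                        participant_id=pid,
                        serious=serious,
                        onset_date=onset,
                        awareness_date=awareness,
                        first_entry_timestamp=first_entry,
                        severity=severity,
                        causality=causality,
                        outcome=outcome,
                        status="ongoing" if outcome == "Continuing" else "closed",
                        description=("serious adverse event" if serious
                                     else "adverse event"),
                        form_complete=form_complete,
                    )
                )

    # --- queries -----------------------------------------------------
    for f in form_rows:
        if f.entry_date is None or rng_query.random() >= params.query_prob:
            continue
        opened = f.entry_date + dt.timedelta(days=int(rng_query.integers(0, 6)))
        if opened > export_date:
            continue
        query_seq += 1
        resolve_after = _geometric_days(rng_query, params.query_resolution_daily)
        resolved = opened + dt.timedelta(days=resolve_after)
        if resolved <= export_date:
            status_q, resolved_date = "resolved", resolved
        else:
            status_q = "answered" if rng_query.random() < 0.3 else "open"
            resolved_date = None
        query_rows.append(
            QueryRecord(
                query_id=f"Q{query_seq:05d}",
                participant_id=f.participant_id,
                form_type=f.form_type,
                opened_date=opened,
                status=status_q,
                resolved_date=resolved_date,
            )
        )

    # --- stock --------------------------------------------------------
    kits = {v.visit_code: v.kits_dispensed for v in visit_defs}
    centre_of = {p.participant_id: p.centre_id for p in participants}
    consumed: dict[str, int] = {c.centre_id: 0 for c in centres}
    for v in visit_rows:
        if v.actual_date is not None:
            consumed[centre_of[v.participant_id]] += kits.get(v.visit_code, 0)
    stock_rows = [
        StockRecord(
            centre_id=c.centre_id,
            units_delivered=consumed[c.centre_id] + int(rng_stock.integers(6, 21)),
            units_counted=None,
            as_of=export_date,
        )
        for c in centres
    ]
    for s in stock_rows:
        s.units_counted = s.units_delivered - consumed[s.centre_id]

    snapshot = TrialSnapshot(
        export_date=export_date,
        centres=centres,
        participants=participants,
        visit_occurrences=visit_rows,
        forms=form_rows,
        adverse_events=ae_rows,
        queries=query_rows,
        stock=stock_rows,
        schedule=params.schedule,
    )

    n = len(participants)
    truth = GroundTruth(
        params=params,
        n_randomized=n,
        n_dropouts=n_dropouts,
        true_dropout_proportion=(n_dropouts / n) if n else None,
        expected_dropouts=expected_dropouts,
        dropout_variance=dropout_variance,
        n_saes=n_saes,
        total_exposure_days=total_exposure,
        true_sae_rate_per_90d=(
            n_saes * 90.0 / total_exposure if total_exposure else None
        ),
        n_entry_lags=len(entry_lags),
        true_mean_entry_lag=(
            float(np.mean(entry_lags)) if entry_lags else None
        ),
        expected_accrual_by_centre=expected_accrual,
        actual_accrual_by_centre={
            c.centre_id: sum(1 for p in participants if p.centre_id == c.centre_id)
            for c in centres
        },
    )
    return snapshot, truth


# ---------------------------------------------------------------------------
# fault injection


class FaultSpec(_Model):
    """A named perturbation with its parameters.

    Supported faults:

    * ``delayed-sae-entry`` (``hours``): shift every SAE first-entry
      timestamp later by the given number of hours (the export date is
      advanced if a shifted timestamp would fall past it, keeping the
      snapshot internally consistent);
    * ``slow-centre`` (``centre_id``, ``factor``, optional ``after``):
      thin the centre's recruits randomized after the cut date, keeping
      each with probability ``factor`` (0 = recruitment stops);
    * ``missing-fields`` (``form_type``, ``prob``): knock out each
      completed field of that form type independently with the given
      probability;
    * ``stalled-queries`` (``centre_id``): reopen every query of that
      centre's participants.
    """

    name: str
    hours: Optional[int] = None
    centre_id: Optional[str] = None
    factor: Optional[float] = None
    after: Optional[dt.date] = None
    form_type: Optional[str] = None
    prob: Optional[float] = None
    seed: int = 0


SUPPORTED_FAULTS = (
    "delayed-sae-entry", "slow-centre", "missing-fields", "stalled-queries",
)


def perturb_trial(snapshot: TrialSnapshot, fault: FaultSpec) -> TrialSnapshot:
    """Return a copy of the snapshot with one fault scenario injected."""
    if fault.name not in SUPPORTED_FAULTS:
        raise FaultSpecError(
            f"unknown fault {fault.name!r}; supported: {', '.join(SUPPORTED_FAULTS)}"
        )
    snap = snapshot.model_copy(deep=True)
    rng = _stream(fault.seed, f"fault:{fault.name}")

    if fault.name == "delayed-sae-entry":
        if fault.hours is None or fault.hours <= 0:
            raise FaultSpecError("delayed-sae-entry needs positive 'hours'")
        delta = dt.timedelta(hours=fault.hours)
        latest = snap.export_date
        for a in snap.adverse_events:
            if a.serious and a.first_entry_timestamp is not None:
                a.first_entry_timestamp = a.first_entry_timestamp + delta
                latest = max(latest, a.first_entry_timestamp.date())
        snap = snap.model_copy(update={"export_date": latest})
        return snap

    if fault.name == "slow-centre":
        if fault.centre_id is None or fault.factor is None:
            raise FaultSpecError("slow-centre needs 'centre_id' and 'factor'")
        if not any(c.centre_id == fault.centre_id for c in snap.centres):
            raise FaultSpecError(f"unknown centre {fault.centre_id!r}")
        rands = [p.randomization_date for p in snap.participants
                 if p.centre_id == fault.centre_id]
        cut = fault.after
        if cut is None:
            first = min(rands) if rands else snap.export_date
            cut = first + (snap.export_date - first) / 2
        drop = {
            p.participant_id
            for p in snap.participants
            if p.centre_id == fault.centre_id
            and p.randomization_date > cut
            and rng.random() >= (fault.factor or 0.0)
        }
        return snap.model_copy(
            update={
                "participants": [p for p in snap.participants
                                 if p.participant_id not in drop],
                "visit_occurrences": [v for v in snap.visit_occurrences
                                      if v.participant_id not in drop],
                "forms": [f for f in snap.forms if f.participant_id not in drop],
                "adverse_events": [a for a in snap.adverse_events
                                   if a.participant_id not in drop],
                "queries": [q for q in snap.queries if q.participant_id not in drop],
            }
        )

    if fault.name == "missing-fields":
        if fault.form_type is None or fault.prob is None:
            raise FaultSpecError("missing-fields needs 'form_type' and 'prob'")
        for f in snap.forms:
            if f.form_type == fault.form_type and f.fields_completed > 0:
                f.fields_completed -= int(
                    rng.binomial(f.fields_completed, fault.prob)
                )
        return snap

    # stalled-queries
    if fault.centre_id is None:
        raise FaultSpecError("stalled-queries needs 'centre_id'")
    if not any(c.centre_id == fault.centre_id for c in snap.centres):
        raise FaultSpecError(f"unknown centre {fault.centre_id!r}")
    centre_of = snap.centre_of()
    for q in snap.queries:
        if centre_of.get(q.participant_id) == fault.centre_id:
            q.status = "open"
            q.resolved_date = None
    return snap
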