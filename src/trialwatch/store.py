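"""Domain types and bundle I/O for daily trial-data exports.

An export bundle is a directory of seven CSV tables — ``centres.csv``,
``participants.csv``, ``visits.csv``, ``forms.csv``, ``adverse_events.csv``,
``queries.csv``, ``stock.csv`` — plus a ``trial_config.yaml`` carrying the
export date and the protocol visit schedule.  The bundle stands in for the
daily export of an electronic data capture (EDC) system and is the single
input format of every metric pathway.

Conventions (fixed so that write → read → write is byte-stable):

* dates are ISO-8601 ``YYYY-MM-DD``; the single sub-day quantity, the SAE
  first-entry timestamp, is ``YYYY-MM-DDTHH:MM`` (reporting deadlines are
  stated in hours);
* CSV dialect: UTF-8, comma separator, one header row, ``\\n`` line ends,
  empty string encodes a missing value, minimal quoting;
* rows are written in canonical order (sorted by primary identifier) and
  re-sorted on read, so equality of snapshots is insensitive to row order;
* day intervals are closed on both ends.

Cross-field and cross-table invariants are *not* enforced at model
construction: :func:`validate_snapshot` reports them as findings, so an
inconsistent snapshot can be represented, inspected and repaired.  The
writer refuses snapshots with error findings; the reader raises on them.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import BundleError, IntegrityError, SchemaError

Scalar = Union[int, float, str]

PARTICIPANT_STATUSES = ("on-study", "ended-early", "completed")
AE_OUTCOMES = (
    "Continuing",
    "Resolved without sequel",
    "Resolved with sequel",
    "others",
)
AE_SEVERITIES = ("mild", "moderate", "severe")
AE_CAUSALITIES = ("unrelated", "possible", "probable", "definite")
QUERY_STATUSES = ("open", "answered", "resolved")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CentreRecord(_Model):
    """A participating trial site."""

    centre_id: str
    name: str
    activation_date: dt.date
    target_enrolment: int = Field(ge=0)
    expected_rate: float = Field(ge=0, description="expected participants per 30 days")


class ParticipantRecord(_Model):
    """One randomized participant.

    ``characteristics`` holds named baseline covariates (age, sex, ...);
    keys and string values must avoid ``|`` and ``=`` (the CSV pair
    encoding's separators).
    """

    participant_id: str
    centre_id: str
    randomization_date: dt.date
    arm: str
    status: Literal["on-study", "ended-early", "completed"]
    end_date: Optional[dt.date] = None
    end_reason: Optional[str] = None
    primary_outcome_available: bool = False
    reconsent_required: bool = False
    reconsent_done: Optional[bool] = None
    characteristics: dict[str, Scalar] = Field(default_factory=dict)


class VisitOccurrence(_Model):
    """A protocol visit for one participant; absent ``actual_date`` means
    the visit has not (yet) been performed."""

    participant_id: str
    visit_code: str
    actual_date: Optional[dt.date] = None
    entry_date: Optional[dt.date] = None


class FormRecord(_Model):
    """One case-report form instance with its completion state."""

    participant_id: str
    form_type: str
    visit_code: Optional[str] = None
    fields_required: int = Field(gt=0)
    fields_completed: int = Field(ge=0)
    entry_date: Optional[dt.date] = None


class AdverseEventRecord(_Model):
    """An (serious) adverse event with its safety-reporting metadata."""

    event_id: str
    participant_id: str
    serious: bool
    onset_date: dt.date
    awareness_date: Optional[dt.date] = None
    first_entry_timestamp: Optional[dt.datetime] = None
    severity: Literal["mild", "moderate", "severe"]
    causality: Literal["unrelated", "possible", "probable", "definite"]
    outcome: Literal[
        "Continuing", "Resolved without sequel", "Resolved with sequel", "others"
    ]
    status: Literal["ongoing", "closed"]
    description: str = ""
    form_complete: bool = True


class QueryRecord(_Model):
    """A data-clarification query with its open/answered/resolved lifecycle."""

    query_id: str
    participant_id: str
    form_type: str
    opened_date: dt.date
    status: Literal["open", "answered", "resolved"]
    resolved_date: Optional[dt.date] = None


class StockRecord(_Model):
    """Investigational-product stock at one centre as of one date.

    ``units_delivered`` is the cumulative number of kits delivered to the
    site; ``units_counted`` is an optional physical count.
    """

    centre_id: str
    units_delivered: int = Field(ge=0)
    units_counted: Optional[int] = Field(default=None, ge=0)
    as_of: dt.date


class ScheduledVisit(_Model):
    """One protocol visit definition.

    The visit window is the closed day interval
    ``[target − window_before_days, target + window_after_days]`` around
    ``target = randomization_date + target_offset_days``; ``grace_days``
    extend the window before an unperformed visit counts as missed.
    """

    visit_code: str
    label: str = ""
    target_offset_days: int = Field(ge=0)
    window_before_days: int = Field(ge=0)
    window_after_days: int = Field(ge=0)
    grace_days: int = Field(ge=0)
    carries_primary_outcome: bool = False
    kits_dispensed: int = Field(default=0, ge=0)


class ProtocolSchedule(_Model):
    """Ordered protocol visit schedule (structural validity enforced here:
    unique codes, strictly increasing target offsets)."""

    visits: list[ScheduledVisit] = Field(default_factory=list)

    @field_validator("visits")
    @classmethod
    def _check_visits(cls, visits: list[ScheduledVisit]) -> list[ScheduledVisit]:
        codes = [v.visit_code for v in visits]
        if len(set(codes)) != len(codes):
            raise ValueError("visit codes must be unique")
        offsets = [v.target_offset_days for v in visits]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("target offsets must be strictly increasing")
        return visits

    def codes(self) -> list[str]:
        return [v.visit_code for v in self.visits]

    def by_code(self) -> dict[str, ScheduledVisit]:
        return {v.visit_code: v for v in self.visits}


class TrialSnapshot(_Model):
    """The full state of a trial at one export date."""

    export_date: dt.date
    centres: list[CentreRecord] = Field(default_factory=list)
    participants: list[ParticipantRecord] = Field(default_factory=list)
    visit_occurrences: list[VisitOccurrence] = Field(default_factory=list)
    forms: list[FormRecord] = Field(default_factory=list)
    adverse_events: list[AdverseEventRecord] = Field(default_factory=list)
    queries: list[QueryRecord] = Field(default_factory=list)
    stock: list[StockRecord] = Field(default_factory=list)
    schedule: ProtocolSchedule = Field(default_factory=ProtocolSchedule)

    def centre_of(self) -> dict[str, str]:
        """participant_id → centre_id map."""
        return {p.participant_id: p.centre_id for p in self.participants}


class TrialConfig(_Model):
    """Trial-level monitoring configuration (thresholds and link template).

    Defaults reflect common academic-trial practice: a 72-hour SAE
    first-entry deadline, a 7-day data-entry lag limit, restocking when
    fewer than 5 kits remain, and an amber query flag at ≤ 5 open queries.
    """

    trial_id: str = "trial"
    sae_deadline_hours: int = Field(default=72, gt=0)
    entry_lag_limit_days: int = Field(default=7, ge=0)
    restock_threshold: int = Field(default=5, ge=0)
    amber_open_queries: int = Field(default=5, ge=0)
    completeness_alert_threshold: float = Field(default=0.8, ge=0, le=1)
    ecrf_url_template: str = "#ecrf/{participant_id}/{record}"


class IntegrityFinding(_Model):
    """One violated snapshot invariant."""

    severity: Literal["error", "warning"]
    table: str
    row_id: str
    message: str


# ---------------------------------------------------------------------------
# scalar (de)serialization


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, dt.datetime):
        return value.strftime("%Y-%m-%dT%H:%M")
    if isinstance(value, dt.date):
        return value.isoformat()
    return str(value)


def _parse_date(text: str) -> Optional[dt.date]:
    return dt.date.fromisoformat(text) if text else None


def _parse_dt(text: str) -> Optional[dt.datetime]:
    return dt.datetime.strptime(text, "%Y-%m-%dT%H:%M") if text else None


def _parse_bool(text: str) -> Optional[bool]:
    if text == "":
        return None
    if text in ("true", "false"):
        return text == "true"
    raise ValueError(f"not a boolean: {text!r}")


def _parse_int(text: str) -> Optional[int]:
    return int(text) if text else None


def _fmt_characteristics(chars: dict[str, Scalar]) -> str:
    return "|".join(f"{k}={_fmt(v)}" for k, v in sorted(chars.items()))


def _parse_characteristics(text: str) -> dict[str, Scalar]:
    out: dict[str, Scalar] = {}
    if not text:
        return out
    for pair in text.split("|"):
        key, _, raw = pair.partition("=")
        try:
            out[key] = int(raw)
        except ValueError:
            try:
                out[key] = float(raw)
            except ValueError:
                out[key] = raw
    return out


# ---------------------------------------------------------------------------
# table schemas: column order, encoder, decoder

_TABLES: dict[str, dict] = {
    "centres": {
        "file": "centres.csv",
        "columns": ["centre_id", "name", "activation_date", "target_enrolment", "expected_rate"],
        "attr": "centres",
    },
    "participants": {
        "file": "participants.csv",
        "columns": [
            "participant_id", "centre_id", "randomization_date", "arm", "status",
            "end_date", "end_reason", "primary_outcome_available",
            "reconsent_required", "reconsent_done", "characteristics",
        ],
        "attr": "participants",
    },
    "visits": {
        "file": "visits.csv",
        "columns": ["participant_id", "visit_code", "actual_date", "entry_date"],
        "attr": "visit_occurrences",
    },
    "forms": {
        "file": "forms.csv",
        "columns": [
            "participant_id", "form_type", "visit_code",
            "fields_required", "fields_completed", "entry_date",
        ],
        "attr": "forms",
    },
    "adverse_events": {
        "file": "adverse_events.csv",
        "columns": [
            "event_id", "participant_id", "serious", "onset_date", "awareness_date",
            "first_entry_timestamp", "severity", "causality", "outcome", "status",
            "description", "form_complete",
        ],
        "attr": "adverse_events",
    },
    "queries": {
        "file": "queries.csv",
        "columns": ["query_id", "participant_id", "form_type", "opened_date", "status", "resolved_date"],
        "attr": "queries",
    },
    "stock": {
        "file": "stock.csv",
        "columns": ["centre_id", "units_delivered", "units_counted", "as_of"],
        "attr": "stock",
    },
}

OPTIONAL_TABLES = {"stock"}


def _encode_row(record: _Model, columns: list[str]) -> list[str]:
    out = []
    for col in columns:
        value = getattr(record, col)
        if col == "characteristics":
            out.append(_fmt_characteristics(value))
        else:
            out.append(_fmt(value))
    return out


def _decode_row(table: str, row: dict[str, str]) -> _Model:
    if table == "centres":
        return CentreRecord(
            centre_id=row["centre_id"],
            name=row["name"],
            activation_date=_parse_date(row["activation_date"]),
            target_enrolment=int(row["target_enrolment"]),
            expected_rate=float(row["expected_rate"]),
        )
    if table == "participants":
        return ParticipantRecord(
            participant_id=row["participant_id"],
            centre_id=row["centre_id"],
            randomization_date=_parse_date(row["randomization_date"]),
            arm=row["arm"],
            status=row["status"],
            end_date=_parse_date(row["end_date"]),
            end_reason=row["end_reason"] or None,
            primary_outcome_available=_parse_bool(row["primary_outcome_available"]) or False,
            reconsent_required=_parse_bool(row["reconsent_required"]) or False,
            reconsent_done=_parse_bool(row["reconsent_done"]),
            characteristics=_parse_characteristics(row["characteristics"]),
        )
    if table == "visits":
        return VisitOccurrence(
            participant_id=row["participant_id"],
            visit_code=row["visit_code"],
            actual_date=_parse_date(row["actual_date"]),
            entry_date=_parse_date(row["entry_date"]),
        )
    if table == "forms":
        return FormRecord(
            participant_id=row["participant_id"],
            form_type=row["form_type"],
            visit_code=row["visit_code"] or None,
            fields_required=int(row["fields_required"]),
            fields_completed=int(row["fields_completed"]),
            entry_date=_parse_date(row["entry_date"]),
        )
    if table == "adverse_events":
        return AdverseEventRecord(
            event_id=row["event_id"],
            participant_id=row["participant_id"],
            serious=_parse_bool(row["serious"]),
            onset_date=_parse_date(row["onset_date"]),
            awareness_date=_parse_date(row["awareness_date"]),
            first_entry_timestamp=_parse_dt(row["first_entry_timestamp"]),
            severity=row["severity"],
            causality=row["causality"],
            outcome=row["outcome"],
            status=row["status"],
            description=row["description"],
            form_complete=_parse_bool(row["form_complete"]),
        )
    if table == "queries":
        return QueryRecord(
            query_id=row["query_id"],
            participant_id=row["participant_id"],
            form_type=row["form_type"],
            opened_date=_parse_date(row["opened_date"]),
            status=row["status"],
            resolved_date=_parse_date(row["resolved_date"]),
        )
    if table == "stock":
        return StockRecord(
            centre_id=row["centre_id"],
            units_delivered=int(row["units_delivered"]),
            units_counted=_parse_int(row["units_counted"]),
            as_of=_parse_date(row["as_of"]),
        )
    raise KeyError(table)


def _sort_key(table: str, columns: list[str]):
    def key(record: _Model):
        return tuple(_encode_row(record, columns))

    return key


def canonicalize(snapshot: TrialSnapshot) -> TrialSnapshot:
    """Return a copy with every table in canonical (serialized-row) order."""
    updates = {}
    for table, meta in _TABLES.items():
        rows = list(getattr(snapshot, meta["attr"]))
        rows.sort(key=_sort_key(table, meta["columns"]))
        updates[meta["attr"]] = rows
    return snapshot.model_copy(update=updates)


# ---------------------------------------------------------------------------
# validation


def validate_snapshot(snapshot: TrialSnapshot) -> list[IntegrityFinding]:
    """Check every cross-field and cross-table invariant.

    Total: returns findings, never raises on a constructible snapshot.
    """
    findings: list[IntegrityFinding] = []

    def err(table, row_id, message):
        findings.append(
            IntegrityFinding(severity="error", table=table, row_id=str(row_id), message=message)
        )

    export = snapshot.export_date
    schedule_codes = set(snapshot.schedule.codes())
    centre_ids = [c.centre_id for c in snapshot.centres]
    centres = set(centre_ids)
    if len(centres) != len(centre_ids):
        dupes = sorted({c for c in centre_ids if centre_ids.count(c) > 1})
        for c in dupes:
            err("centres", c, "duplicate centre_id")

    pids = [p.participant_id for p in snapshot.participants]
    participants = set(pids)
    if len(participants) != len(pids):
        for p in sorted({x for x in pids if pids.count(x) > 1}):
            err("participants", p, "duplicate participant_id")

    def late(table, row_id, label, d):
        if d is None:
            return
        day = d.date() if isinstance(d, dt.datetime) else d
        if day > export:
            err(table, row_id, f"{label} {day.isoformat()} is after export_date")

    for c in snapshot.centres:
        late("centres", c.centre_id, "activation_date", c.activation_date)

    for p in snapshot.participants:
        rid = p.participant_id
        if p.centre_id not in centres:
            err("participants", rid, f"unknown centre_id {p.centre_id}")
        if (p.end_date is not None) != (p.status != "on-study"):
            err("participants", rid, "end_date must be present iff status is not on-study")
        if p.end_date is not None and p.end_date < p.randomization_date:
            err("participants", rid, "end_date before randomization_date")
        late("participants", rid, "randomization_date", p.randomization_date)
        late("participants", rid, "end_date", p.end_date)

    for i, v in enumerate(snapshot.visit_occurrences):
        rid = f"{v.participant_id}/{v.visit_code}"
        if v.participant_id not in participants:
            err("visits", rid, f"unknown participant_id {v.participant_id}")
        if v.visit_code not in schedule_codes:
            err("visits", rid, f"visit_code {v.visit_code} not in protocol schedule")
        if v.actual_date and v.entry_date and v.entry_date < v.actual_date:
            err("visits", rid, "entry_date before actual_date")
        late("visits", rid, "actual_date", v.actual_date)
        late("visits", rid, "entry_date", v.entry_date)

    for i, f in enumerate(snapshot.forms):
        rid = f"{f.participant_id}/{f.form_type}#{i}"
        if f.participant_id not in participants:
            err("forms", rid, f"unknown participant_id {f.participant_id}")
        if f.visit_code is not None and f.visit_code not in schedule_codes:
            err("forms", rid, f"visit_code {f.visit_code} not in protocol schedule")
        if f.fields_completed > f.fields_required:
            err("forms", rid, "fields_completed exceeds fields_required")
        late("forms", rid, "entry_date", f.entry_date)

    event_ids = [a.event_id for a in snapshot.adverse_events]
    for e in sorted({x for x in event_ids if event_ids.count(x) > 1}):
        err("adverse_events", e, "duplicate event_id")
    for a in snapshot.adverse_events:
        rid = a.event_id
        if a.participant_id not in participants:
            err("adverse_events", rid, f"unknown participant_id {a.participant_id}")
        if a.awareness_date is not None and a.awareness_date < a.onset_date:
            err("adverse_events", rid, "awareness_date before onset_date")
        if a.outcome == "Continuing" and a.status != "ongoing":
            err("adverse_events", rid, "outcome Continuing requires status ongoing")
        late("adverse_events", rid, "onset_date", a.onset_date)
        late("adverse_events", rid, "awareness_date", a.awareness_date)
        late("adverse_events", rid, "first_entry_timestamp", a.first_entry_timestamp)

    query_ids = [q.query_id for q in snapshot.queries]
    for qd in sorted({x for x in query_ids if query_ids.count(x) > 1}):
        err("queries", qd, "duplicate query_id")
    for q in snapshot.queries:
        rid = q.query_id
        if q.participant_id not in participants:
            err("queries", rid, f"unknown participant_id {q.participant_id}")
        if (q.resolved_date is not None) != (q.status == "resolved"):
            err("queries", rid, "resolved_date must be present iff status is resolved")
        if q.resolved_date is not None and q.resolved_date < q.opened_date:
            err("queries", rid, "resolved_date before opened_date")
        late("queries", rid, "opened_date", q.opened_date)
        late("queries", rid, "resolved_date", q.resolved_date)

    seen_stock: set[tuple[str, dt.date]] = set()
    for s in snapshot.stock:
        rid = f"{s.centre_id}@{s.as_of.isoformat()}"
        if s.centre_id not in centres:
            err("stock", rid, f"unknown centre_id {s.centre_id}")
        if (s.centre_id, s.as_of) in seen_stock:
            err("stock", rid, "more than one stock record for centre and date")
        seen_stock.add((s.centre_id, s.as_of))
        late("stock", rid, "as_of", s.as_of)

    return findings


# ---------------------------------------------------------------------------
# bundle I/O

CONFIG_FILE = "trial_config.yaml"


def _schedule_to_plain(schedule: ProtocolSchedule) -> list[dict]:
    return [v.model_dump() for v in schedule.visits]


def _schedule_from_plain(data) -> ProtocolSchedule:
    try:
        return ProtocolSchedule(visits=data)
    except Exception as exc:  # pydantic ValidationError
        raise SchemaError(f"invalid protocol schedule: {exc}") from exc


def write_export_bundle(snapshot: TrialSnapshot, directory) -> None:
    """Write the seven CSV tables plus ``trial_config.yaml``.

    Refuses (raising :class:`IntegrityError`, writing nothing) if the
    snapshot has any error finding.  Output is deterministic: canonical
    row order, fixed column order, fixed scalar formatting.
    """
    findings = [f for f in validate_snapshot(snapshot) if f.severity == "error"]
    if findings:
        ids = ", ".join(f"{f.table}:{f.row_id}" for f in findings[:10])
        raise IntegrityError(f"snapshot fails validation ({ids})", findings)

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    snap = canonicalize(snapshot)
    for table, meta in _TABLES.items():
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(meta["columns"])
        for record in getattr(snap, meta["attr"]):
            writer.writerow(_encode_row(record, meta["columns"]))
        (directory / meta["file"]).write_text(buf.getvalue(), encoding="utf-8")

    config = {
        "export_date": snap.export_date.isoformat(),
        "schedule": _schedule_to_plain(snap.schedule),
    }
    (directory / CONFIG_FILE).write_text(
        yaml.safe_dump(config, sort_keys=True), encoding="utf-8"
    )


def read_export_bundle(directory, config_path=None) -> TrialSnapshot:
    """Read a bundle directory into a validated :class:`TrialSnapshot`.

    ``stock.csv`` is optional (an empty collection if absent); every other
    table and the config file are mandatory.  Raises :class:`BundleError`
    for missing files, :class:`SchemaError` for a malformed config, and
    :class:`IntegrityError` (listing offending row ids) if the parsed
    snapshot violates referential or temporal integrity.
    """
    directory = Path(directory)
    config_file = Path(config_path) if config_path else directory / CONFIG_FILE
    if not config_file.exists():
        raise BundleError(f"missing config file: {config_file.name}")
    try:
        raw = yaml.safe_load(config_file.read_text(encoding="utf-8"))
        export_date = dt.date.fromisoformat(str(raw["export_date"]))
        schedule = _schedule_from_plain(raw["schedule"])
    except SchemaError:
        raise
    except Exception as exc:
        raise SchemaError(f"malformed trial config {config_file}: {exc}") from exc

    tables: dict[str, list] = {}
    for table, meta in _TABLES.items():
        path = directory / meta["file"]
        if not path.exists():
            if table in OPTIONAL_TABLES:
                tables[meta["attr"]] = []
                continue
            raise BundleError(f"missing mandatory table: {meta['file']}")
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(meta["columns"]) - set(reader.fieldnames or [])
            if missing:
                raise BundleError(
                    f"{meta['file']}: missing columns {sorted(missing)}"
                )
            try:
                rows = [_decode_row(table, row) for row in reader]
            except Exception as exc:
                raise BundleError(f"{meta['file']}: unparseable row ({exc})") from exc
        tables[meta["attr"]] = rows

    snapshot = TrialSnapshot(export_date=export_date, schedule=schedule, **tables)
    snapshot = canonicalize(snapshot)
    findings = [f for f in validate_snapshot(snapshot) if f.severity == "error"]
    if findings:
        ids = ", ".join(f"{f.table}:{f.row_id}" for f in findings[:20])
        raise IntegrityError(f"bundle fails integrity checks ({ids})", findings)
    return snapshot


def load_trial_config(path=None, **overrides) -> TrialConfig:
    """Load monitoring thresholds from a YAML/JSON mapping (or defaults)."""
    data: dict = {}
    if path is not None:
        try:
            data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        except Exception as exc:
            raise SchemaError(f"malformed config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise SchemaError(f"config {path} must be a mapping")
    known = set(TrialConfig.model_fields)
    data = {k: v for k, v in data.items() if k in known}
    data.update(overrides)
    try:
        return TrialConfig(**data)
    except Exception as exc:
        raise SchemaError(f"invalid trial config: {exc}") from exc
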