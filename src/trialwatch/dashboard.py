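"""Dashboard assembly and rendering.

:func:`build_dashboard` applies each active tab's pathway to the
(filtered) snapshot and lays the results out as typed panels — value
boxes, per-centre series, level distributions, patient lists, alert
lists.  The model renders deterministically to JSON (lossless round
trip) or to a single self-contained static HTML file with one section
per active tab.  A pathway failure on one tab degrades to an error panel
rather than aborting the build: a partial dashboard is still a valid
daily report.

E-mail reminders are modelled as :class:`Alert` records
(:func:`collect_alerts`); dispatch is deliberately out of scope.
"""

from __future__ import annotations

import datetime as dt
import html as html_mod
from typing import Annotated, Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field

from . import pathways as pw
from .errors import TrialWatchError
from .risk import TabPlan
from .store import TrialConfig, TrialSnapshot

Cell = Union[str, int, float, bool, None]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Alert(_Model):
    kind: str
    source_tab: str
    centre_id: Optional[str] = None
    participant_id: Optional[str] = None
    message: str


class ValueBox(_Model):
    kind: Literal["value_box"] = "value_box"
    label: str
    value: Cell
    unit: Optional[str] = None


class SeriesPanel(_Model):
    kind: Literal["series"] = "series"
    label: str
    overall: pw.AccrualSeries
    by_centre: dict[str, pw.AccrualSeries]


class DistributionPanel(_Model):
    kind: Literal["distribution"] = "distribution"
    label: str
    levels: list[str]
    counts: list[int]
    percents: list[float]


class PatientListPanel(_Model):
    kind: Literal["patient_list"] = "patient_list"
    label: str
    columns: list[str]
    rows: list[dict[str, Cell]]


class AlertListPanel(_Model):
    kind: Literal["alert_list"] = "alert_list"
    label: str
    alerts: list[Alert]


class ErrorPanel(_Model):
    kind: Literal["error"] = "error"
    label: str
    message: str


Panel = Annotated[
    Union[ValueBox, SeriesPanel, DistributionPanel, PatientListPanel,
          AlertListPanel, ErrorPanel],
    Field(discriminator="kind"),
]


class DashboardTab(_Model):
    tab_name: str
    panels: list[Panel]


class DashboardModel(_Model):
    trial_id: str
    export_date: dt.date
    filter_state: pw.FilterState
    tabs: list[DashboardTab]


def record_link(config: TrialConfig, participant_id: str, record: str = "") -> str:
    """Deterministic eCRF deep link from the configured template."""
    return config.ecrf_url_template.format(participant_id=participant_id, record=record)


def _dist_panel(label: str, d: pw.Distribution) -> DistributionPanel:
    return DistributionPanel(
        label=label, levels=d.levels, counts=d.counts, percents=d.percents
    )


def _round(x: Optional[float], nd: int = 3) -> Optional[float]:
    return None if x is None else round(x, nd)


# ---------------------------------------------------------------------------
# per-tab builders


def _tab_recruitment(snap, config):
    series = pw.recruitment_trajectory(snap)
    alerts = []
    for cid, s in sorted(series.by_centre.items()):
        actual, expected = s.actual_cumulative[-1], s.expected_cumulative[-1]
        if expected >= 5 and actual < 0.7 * expected:
            alerts.append(
                Alert(
                    kind="slow-recruitment",
                    source_tab="recruitment",
                    centre_id=cid,
                    message=(
                        f"centre {cid}: {actual} recruited vs {expected:.1f} expected"
                    ),
                )
            )
    return [
        ValueBox(label="Randomized", value=series.total_actual),
        ValueBox(label="Expected by today", value=round(series.total_expected, 1)),
        SeriesPanel(
            label="Cumulative recruitment (actual vs expected)",
            overall=series.overall,
            by_centre=series.by_centre,
        ),
        AlertListPanel(label="Recruitment alerts", alerts=alerts),
    ]


def _tab_patient_characteristics(snap, config):
    participants = snap.participants
    panels: list[Panel] = [ValueBox(label="Participants", value=len(participants))]
    arms = sorted({p.arm for p in participants})
    if arms:
        panels.append(
            _dist_panel("Arm", pw.Distribution.tally(arms, [p.arm for p in participants]))
        )
    cat_values: dict[str, list[str]] = {}
    numeric: dict[str, list[float]] = {}
    for p in participants:
        for key, value in p.characteristics.items():
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                numeric.setdefault(key, []).append(float(value))
            else:
                cat_values.setdefault(key, []).append(str(value))
    for key in sorted(cat_values):
        values = cat_values[key]
        panels.append(
            _dist_panel(key, pw.Distribution.tally(sorted(set(values)), values))
        )
    for key in sorted(numeric):
        values = sorted(numeric[key])
        median = values[len(values) // 2] if len(values) % 2 else (
            (values[len(values) // 2 - 1] + values[len(values) // 2]) / 2
        )
        panels.append(ValueBox(label=f"{key} (median)", value=_round(median, 1)))
    return panels


def _tab_retention(snap, config):
    summary = pw.retention_summary(snap)
    ov = summary.overall
    reasons = ov.ended_early_reasons
    rows = [
        {
            "participant_id": p.participant_id,
            "centre_id": p.centre_id,
            "end_date": p.end_date.isoformat() if p.end_date else None,
            "end_reason": p.end_reason,
            "primary_outcome_available": p.primary_outcome_available,
            "record_link": record_link(config, p.participant_id, "end-of-study"),
        }
        for p in snap.participants
        if p.status == "ended-early"
    ]
    rows.sort(key=lambda r: (r["centre_id"], r["participant_id"]))
    panels: list[Panel] = [
        ValueBox(label="Randomized", value=ov.randomized),
        ValueBox(label="On study", value=ov.status_counts["on-study"]),
        ValueBox(label="Completed", value=ov.status_counts["completed"]),
        ValueBox(label="Ended early", value=ov.status_counts["ended-early"]),
        ValueBox(label="Retention", value=_round(ov.retention)),
        ValueBox(
            label="Primary outcome available among early exits",
            value=ov.outcome_available_among_ended,
        ),
    ]
    if reasons:
        panels.append(
            DistributionPanel(
                label="Reasons for leaving the study",
                levels=list(reasons.keys()),
                counts=list(reasons.values()),
                percents=pw.percent_vector(list(reasons.values())),
            )
        )
    panels.append(
        PatientListPanel(
            label="Participants who ended the study early",
            columns=["participant_id", "centre_id", "end_date", "end_reason",
                     "primary_outcome_available", "record_link"],
            rows=rows,
        )
    )
    return panels


def _tab_ae_sae(snap, config):
    timeliness = pw.sae_report_timeliness(snap, config.sae_deadline_hours)
    incomplete = [a for a in snap.adverse_events if a.serious and not a.form_complete]
    rows = [
        {
            "event_id": r.event_id,
            "participant_id": r.participant_id,
            "centre_id": r.centre_id,
            "elapsed_hours": r.elapsed_hours,
            "on_time": r.on_time,
            "clock_basis": r.clock_basis,
            "record_link": record_link(config, r.participant_id, r.event_id),
        }
        for r in timeliness.rows
        if r.on_time is not True
    ]
    return [
        ValueBox(label="SAE reports on time", value=timeliness.n_on_time),
        ValueBox(label="SAE reports late", value=timeliness.n_late),
        ValueBox(label="SAEs not yet reported", value=timeliness.n_unreported),
        ValueBox(label="Incomplete SAE forms", value=len(incomplete)),
        ValueBox(label="Reporting deadline", value=timeliness.deadline_hours, unit="h"),
        PatientListPanel(
            label="Late or unreported SAEs",
            columns=["event_id", "participant_id", "centre_id", "elapsed_hours",
                     "on_time", "clock_basis", "record_link"],
            rows=rows,
        ),
    ]


def _tab_safety_management(snap, config):
    summary = pw.safety_summary(snap, url_template=config.ecrf_url_template)
    ov = summary.overall
    rows = [
        {
            "participant_id": r.participant_id,
            "centre_id": r.centre_id,
            "event_id": r.event_id,
            "status": r.status,
            "description": r.description,
            "record_link": r.record_link,
        }
        for r in summary.patients
    ]
    return [
        ValueBox(label="SAEs", value=ov.sae_count),
        ValueBox(label="AEs", value=ov.ae_count),
        ValueBox(label="Patients with SAE", value=ov.patients_with_sae),
        ValueBox(label="SAEs per patient randomized",
                 value=_round(ov.sae_per_randomized)),
        _dist_panel("SAE severity", ov.severity),
        _dist_panel("SAE causality", ov.causality),
        _dist_panel("SAE outcome", ov.outcome),
        PatientListPanel(
            label="Patients with SAE",
            columns=["participant_id", "centre_id", "event_id", "status",
                     "description", "record_link"],
            rows=rows,
        ),
    ]


def _tab_follow_up_visits(snap, config):
    table = pw.classify_visits(snap, url_template=config.ecrf_url_template)
    counts = table.counts
    actionable = [
        {
            "participant_id": r.participant_id,
            "centre_id": r.centre_id,
            "visit_code": r.visit_code,
            "status": r.status,
            "window_open": r.window_open.isoformat(),
            "window_close": r.window_close.isoformat(),
            "record_link": r.record_link,
        }
        for r in table.rows
        if r.status in ("due", "overdue", "missed")
    ]
    actionable.sort(key=lambda r: (r["centre_id"], r["participant_id"], r["visit_code"]))
    return [
        ValueBox(label="Due visits", value=counts["due"]),
        ValueBox(label="Overdue visits", value=counts["overdue"]),
        ValueBox(label="Missed visits", value=counts["missed"]),
        ValueBox(label="Completed in window", value=counts["completed-in-window"]),
        ValueBox(label="Completed out of window",
                 value=counts["completed-out-of-window"]),
        PatientListPanel(
            label="Due, overdue and missed visits",
            columns=["participant_id", "centre_id", "visit_code", "status",
                     "window_open", "window_close", "record_link"],
            rows=actionable,
        ),
    ]


def _tab_informed_consent(snap, config):
    rows = [
        {
            "participant_id": r.participant_id,
            "centre_id": r.centre_id,
            "off_study": r.off_study,
            "record_link": r.record_link,
        }
        for r in pw.reconsent_overview(snap, url_template=config.ecrf_url_template)
    ]
    return [
        ValueBox(label="Re-consents pending", value=len(rows)),
        PatientListPanel(
            label="Participants still needing re-consent",
            columns=["participant_id", "centre_id", "off_study", "record_link"],
            rows=rows,
        ),
    ]


def _tab_inclusion_exclusion(snap, config):
    # Safety-relevant eligibility checks are protocol-specific; without
    # configured criteria the tab reports the verifiable denominator only.
    n = len(snap.participants)
    with_chars = sum(1 for p in snap.participants if p.characteristics)
    return [
        ValueBox(label="Participants randomized", value=n),
        ValueBox(label="With baseline characteristics recorded", value=with_chars),
    ]


def _tab_medication(snap, config):
    summary = pw.medication_summary(snap, restock_threshold=config.restock_threshold)
    alerts = [
        Alert(
            kind="restock",
            source_tab="medication",
            centre_id=cid,
            message=(
                f"centre {cid}: {cm.units_remaining} kits remaining "
                f"(threshold {summary.restock_threshold})"
            ),
        )
        for cid, cm in sorted(summary.by_centre.items())
        if cm.restock_alert
    ]
    boxes = [
        ValueBox(label="Kits consumed", value=summary.total_consumed),
        ValueBox(label="Kits delivered", value=summary.total_delivered),
    ]
    for cid, cm in sorted(summary.by_centre.items()):
        boxes.append(
            ValueBox(
                label=f"{cid} remaining",
                value=cm.units_remaining,
                unit="kits",
            )
        )
    return boxes + [AlertListPanel(label="Restock alerts", alerts=alerts)]


def _tab_data_quality(snap, config):
    summary = pw.data_quality_summary(
        snap,
        lag_limit_days=config.entry_lag_limit_days,
        amber_threshold=config.amber_open_queries,
    )
    ov = summary.overall
    panels: list[Panel] = []
    for ft, q in sorted(ov.by_form_type.items()):
        panels.append(
            ValueBox(
                label=f"Completeness: {ft}",
                value=_round(q.completeness),
            )
        )
    panels.append(ValueBox(label="Median entry lag", value=ov.entry_lag.median_days,
                           unit="days"))
    panels.append(
        ValueBox(
            label=f"Entries later than {summary.lag_limit_days} days",
            value=ov.entry_lag.n_exceeding_limit,
        )
    )
    panels.append(
        DistributionPanel(
            label="Query status",
            levels=list(ov.queries.counts.keys()),
            counts=list(ov.queries.counts.values()),
            percents=pw.percent_vector(list(ov.queries.counts.values())),
        )
    )
    alerts = [
        Alert(
            kind="query-backlog",
            source_tab="data-quality",
            centre_id=cid,
            message=(
                f"centre {cid}: {bd.queries.open_queries} open queries (red)"
            ),
        )
        for cid, bd in sorted(summary.by_centre.items())
        if bd.queries.colour == "red"
    ]
    for ft, q in sorted(ov.by_form_type.items()):
        if q.completeness is not None and q.completeness < config.completeness_alert_threshold:
            alerts.append(
                Alert(
                    kind="low-completeness",
                    source_tab="data-quality",
                    message=(
                        f"{ft}: completeness {q.completeness:.2f} below "
                        f"{config.completeness_alert_threshold:.2f}"
                    ),
                )
            )
    panels.append(AlertListPanel(label="Data quality alerts", alerts=alerts))
    return panels


_TAB_BUILDERS = {
    "recruitment": _tab_recruitment,
    "patient-characteristics": _tab_patient_characteristics,
    "retention": _tab_retention,
    "ae-sae": _tab_ae_sae,
    "safety-management": _tab_safety_management,
    "follow-up-visits": _tab_follow_up_visits,
    "informed-consent": _tab_informed_consent,
    "inclusion-exclusion": _tab_inclusion_exclusion,
    "medication": _tab_medication,
    "data-quality": _tab_data_quality,
}


def build_dashboard(
    snapshot: TrialSnapshot,
    tab_plan: TabPlan,
    config: Optional[TrialConfig] = None,
    filter_state: Optional[pw.FilterState] = None,
    tab_order: Optional[list[str]] = None,
) -> DashboardModel:
    """Assemble the dashboard for the active tabs of a compiled plan.

    Only active tabs appear, in plan order (overridable via
    ``tab_order``).  A failing pathway yields an error panel for its tab;
    the remaining tabs are still built.
    """
    config = config or TrialConfig()
    filter_state = filter_state or pw.FilterState()
    snap = pw.apply_filter(snapshot, filter_state)

    active = [t.tab_name for t in tab_plan.active_tabs()]
    if tab_order is not None:
        ordered = [t for t in tab_order if t in active]
        ordered += [t for t in active if t not in ordered]
        active = ordered

    tabs = []
    for name in active:
        builder = _TAB_BUILDERS.get(name)
        if builder is None:
            tabs.append(
                DashboardTab(
                    tab_name=name,
                    panels=[ErrorPanel(label=name, message="no builder for tab")],
                )
            )
            continue
        try:
            panels = builder(snap, config)
        except Exception as exc:  # partial dashboards are valid
            panels = [ErrorPanel(label=name, message=f"{type(exc).__name__}: {exc}")]
        tabs.append(DashboardTab(tab_name=name, panels=panels))
    return DashboardModel(
        trial_id=config.trial_id,
        export_date=snap.export_date,
        filter_state=filter_state,
        tabs=tabs,
    )


# ---------------------------------------------------------------------------
# alerts


def collect_alerts(model: DashboardModel, config: Optional[TrialConfig] = None) -> list[Alert]:
    """Derive the actionable alert list from the dashboard panels.

    One alert per alert-generating row: due/overdue visits, late or
    unreported SAEs, pending re-consents, plus every entry of the
    dedicated alert-list panels (restock, query backlog, slow
    recruitment).  Deduplicated on (kind, tab, centre, participant,
    message).
    """
    alerts: list[Alert] = []
    for tab in model.tabs:
        for panel in tab.panels:
            if isinstance(panel, AlertListPanel):
                alerts.extend(panel.alerts)
            elif isinstance(panel, PatientListPanel):
                for row in panel.rows:
                    if tab.tab_name == "follow-up-visits" and row.get("status") in (
                        "due", "overdue",
                    ):
                        alerts.append(
                            Alert(
                                kind=f"visit-{row['status']}",
                                source_tab=tab.tab_name,
                                centre_id=str(row.get("centre_id")),
                                participant_id=str(row.get("participant_id")),
                                message=(
                                    f"visit {row.get('visit_code')} {row.get('status')} "
                                    f"(window {row.get('window_open')}"
                                    f"..{row.get('window_close')})"
                                ),
                            )
                        )
                    elif tab.tab_name == "ae-sae":
                        state = ("late" if row.get("on_time") is False
                                 else "unreported")
                        alerts.append(
                            Alert(
                                kind=f"sae-{state}",
                                source_tab=tab.tab_name,
                                centre_id=str(row.get("centre_id")),
                                participant_id=str(row.get("participant_id")),
                                message=f"SAE {row.get('event_id')} {state}",
                            )
                        )
                    elif tab.tab_name == "informed-consent":
                        alerts.append(
                            Alert(
                                kind="reconsent-pending",
                                source_tab=tab.tab_name,
                                centre_id=str(row.get("centre_id")),
                                participant_id=str(row.get("participant_id")),
                                message="re-consent pending",
                            )
                        )
    seen = set()
    unique = []
    for a in alerts:
        key = (a.kind, a.source_tab, a.centre_id, a.participant_id, a.message)
        if key not in seen:
            seen.add(key)
            unique.append(a)
    return unique


# ---------------------------------------------------------------------------
# rendering


def render(model: DashboardModel, format: str) -> str:
    """Render the model to ``json`` (lossless) or static ``html``."""
    if format == "json":
        return model.model_dump_json(indent=2)
    if format == "html":
        return _render_html(model)
    raise TrialWatchError(f"unknown render format {format!r} (use json or html)")


def parse_dashboard_json(text: str) -> DashboardModel:
    return DashboardModel.model_validate_json(text)


_CSS = """
body{font-family:sans-serif;margin:1.5em;color:#1a1a2e}
h1{font-size:1.4em}h2{border-bottom:2px solid #4a6fa5;padding-bottom:.2em}
.boxes{display:flex;flex-wrap:wrap;gap:.6em;margin:.6em 0}
.box{border:1px solid #ccd;border-radius:6px;padding:.5em .9em;background:#f4f6fb;min-width:8em}
.box .v{font-size:1.3em;font-weight:bold}.box .l{font-size:.8em;color:#555}
table{border-collapse:collapse;margin:.6em 0;font-size:.85em}
td,th{border:1px solid #ccd;padding:.25em .6em;text-align:left}
th{background:#e8ecf5}
.alert{color:#8a1f11;background:#fbe3e4;border:1px solid #fbc2c4;
 padding:.3em .6em;margin:.2em 0;border-radius:4px}
.error{color:#8a1f11;font-weight:bold}
.empty{color:#777;font-style:italic}
""".strip()


def _esc(value) -> str:
    return html_mod.escape("" if value is None else str(value))


def _render_panel(panel) -> str:
    if isinstance(panel, ValueBox):
        unit = f" {_esc(panel.unit)}" if panel.unit else ""
        value = "—" if panel.value is None else _esc(panel.value)
        return (
            f'<div class="box"><div class="v">{value}{unit}</div>'
            f'<div class="l">{_esc(panel.label)}</div></div>'
        )
    if isinstance(panel, DistributionPanel):
        head = "".join(f"<th>{_esc(lv)}</th>" for lv in panel.levels)
        counts = "".join(f"<td>{c}</td>" for c in panel.counts)
        pcts = "".join(f"<td>{p:.1f}%</td>" for p in panel.percents)
        return (
            f"<h3>{_esc(panel.label)}</h3><table><tr><th></th>{head}</tr>"
            f"<tr><th>n</th>{counts}</tr><tr><th>%</th>{pcts}</tr></table>"
        )
    if isinstance(panel, PatientListPanel):
        if not panel.rows:
            return (
                f"<h3>{_esc(panel.label)}</h3>"
                '<p class="empty">no entries</p>'
            )
        head = "".join(f"<th>{_esc(c)}</th>" for c in panel.columns)
        body = []
        for row in panel.rows:
            cells = []
            for col in panel.columns:
                value = row.get(col)
                if col == "record_link" and value:
                    cells.append(f'<td><a href="{_esc(value)}">open</a></td>')
                else:
                    cells.append(f"<td>{_esc(value)}</td>")
            body.append("<tr>" + "".join(cells) + "</tr>")
        return (
            f"<h3>{_esc(panel.label)}</h3><table><tr>{head}</tr>"
            + "".join(body)
            + "</table>"
        )
    if isinstance(panel, AlertListPanel):
        if not panel.alerts:
            return (
                f"<h3>{_esc(panel.label)}</h3>"
                '<p class="empty">no alerts</p>'
            )
        items = "".join(
            f'<div class="alert">{_esc(a.kind)}: {_esc(a.message)}</div>'
            for a in panel.alerts
        )
        return f"<h3>{_esc(panel.label)}</h3>{items}"
    if isinstance(panel, SeriesPanel):
        # last value per centre; full series stays in the JSON render
        rows = "".join(
            f"<tr><td>{_esc(cid)}</td><td>{s.actual_cumulative[-1] if s.actual_cumulative else 0}</td>"
            f"<td>{(s.expected_cumulative[-1] if s.expected_cumulative else 0):.1f}</td></tr>"
            for cid, s in sorted(panel.by_centre.items())
        )
        total_a = panel.overall.actual_cumulative[-1] if panel.overall.actual_cumulative else 0
        total_e = panel.overall.expected_cumulative[-1] if panel.overall.expected_cumulative else 0.0
        return (
            f"<h3>{_esc(panel.label)}</h3>"
            f"<table><tr><th>centre</th><th>actual</th><th>expected</th></tr>{rows}"
            f"<tr><th>overall</th><th>{total_a}</th><th>{total_e:.1f}</th></tr></table>"
        )
    if isinstance(panel, ErrorPanel):
        return (
            f'<p class="error">{_esc(panel.label)}: {_esc(panel.message)}</p>'
        )
    raise TrialWatchError(f"unknown panel type {type(panel).__name__}")


def _render_html(model: DashboardModel) -> str:
    sections = []
    for tab in model.tabs:
        boxes = [p for p in tab.panels if isinstance(p, ValueBox)]
        others = [p for p in tab.panels if not isinstance(p, ValueBox)]
        body = ""
        if boxes:
            body += '<div class="boxes">' + "".join(_render_panel(b) for b in boxes) + "</div>"
        body += "".join(_render_panel(p) for p in others)
        sections.append(
            f'<section id="tab-{_esc(tab.tab_name)}">'
            f"<h2>{_esc(tab.tab_name)}</h2>{body}</section>"
        )
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>{_esc(model.trial_id)} — trial dashboard</title>"
        f"<style>{_CSS}</style></head><body>"
        f"<h1>{_esc(model.trial_id)} — trial dashboard "
        f"(export {model.export_date.isoformat()})</h1>"
        + "".join(sections)
        + "</body></html>\n"
    )
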