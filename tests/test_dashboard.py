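"""Dashboard assembly, rendering round trips, and alert derivation."""

import datetime as dt

import pytest

from trialwatch.dashboard import (
    AlertListPanel,
    ErrorPanel,
    PatientListPanel,
    build_dashboard,
    collect_alerts,
    parse_dashboard_json,
    render,
)
from trialwatch.errors import TrialWatchError
from trialwatch.pathways import FilterState
from trialwatch.risk import (
    RiskAssessment,
    compile_tab_plan,
    load_instrument,
    rate_risk,
)
from trialwatch.store import TrialConfig, TrialSnapshot
from trialwatch.synthetic import FaultSpec, perturb_trial

from .conftest import D, one_visit_schedule


@pytest.fixture(scope="module")
def full_plan():
    inst = load_instrument()
    ratings = [
        rate_risk(inst, "participant schedule", 3, 2),
        rate_risk(inst, "informed consent", 2, 2),
        rate_risk(inst, "accountability/storage", 2, 2),
        rate_risk(inst, "inclusion/exclusion", 2, 2),
    ]
    assessment = RiskAssessment(
        trial_id="demo", assessed_on=D(2024, 1, 1), ratings=ratings
    )
    return compile_tab_plan(inst, assessment)


@pytest.fixture(scope="module")
def generic_plan():
    inst = load_instrument()
    return compile_tab_plan(
        inst, RiskAssessment(trial_id="demo", assessed_on=D(2024, 1, 1))
    )


def test_empty_trial_generic_plan_has_six_zeroed_tabs(generic_plan):
    snap = TrialSnapshot(export_date=D(2024, 1, 1), schedule=one_visit_schedule())
    model = build_dashboard(snap, generic_plan)
    assert len(model.tabs) == 6
    for tab in model.tabs:
        for panel in tab.panels:
            if isinstance(panel, PatientListPanel):
                assert panel.rows == []
    assert collect_alerts(model) == []


def test_only_active_tabs_appear_in_plan_order(sim_snapshot, full_plan):
    model = build_dashboard(sim_snapshot, full_plan)
    active = [t.tab_name for t in full_plan.active_tabs()]
    assert [t.tab_name for t in model.tabs] == active
    assert "medication" in active and "inclusion-exclusion" in active


def test_json_render_round_trips_to_equal_model(sim_snapshot, full_plan):
    model = build_dashboard(sim_snapshot, full_plan)
    text = render(model, "json")
    assert parse_dashboard_json(text) == model


def test_repeated_renders_are_byte_identical(sim_snapshot, full_plan):
    model = build_dashboard(sim_snapshot, full_plan)
    assert render(model, "json") == render(model, "json")
    assert render(model, "html") == render(model, "html")


def test_html_has_one_section_per_active_tab_in_order(sim_snapshot, full_plan):
    model = build_dashboard(sim_snapshot, full_plan)
    html = render(model, "html")
    positions = [html.index(f'id="tab-{t.tab_name}"') for t in model.tabs]
    assert positions == sorted(positions)
    assert html.count("<section") == len(model.tabs)


def test_unknown_render_format_rejected(sim_snapshot, generic_plan):
    model = build_dashboard(sim_snapshot, generic_plan)
    with pytest.raises(TrialWatchError, match="format"):
        render(model, "pdf")


def test_centre_filter_restricts_patient_lists(sim_snapshot, full_plan):
    model = build_dashboard(
        sim_snapshot, full_plan, filter_state=FilterState(centres={"C02"})
    )
    for tab in model.tabs:
        for panel in tab.panels:
            if isinstance(panel, PatientListPanel):
                assert all(
                    row.get("centre_id") in (None, "C02") for row in panel.rows
                )


def test_every_patient_list_row_carries_a_record_link(sim_snapshot, full_plan):
    model = build_dashboard(sim_snapshot, full_plan)
    found_rows = 0
    for tab in model.tabs:
        for panel in tab.panels:
            if isinstance(panel, PatientListPanel) and "record_link" in panel.columns:
                for row in panel.rows:
                    assert row["record_link"]
                    found_rows += 1
    assert found_rows > 0


def test_failing_pathway_degrades_to_error_panel(sim_snapshot, full_plan):
    broken = sim_snapshot.model_copy(update={"stock": None})
    model = build_dashboard(broken, full_plan)
    med = next(t for t in model.tabs if t.tab_name == "medication")
    assert any(isinstance(p, ErrorPanel) for p in med.panels)
    # other tabs still built normally
    other = next(t for t in model.tabs if t.tab_name == "retention")
    assert not any(isinstance(p, ErrorPanel) for p in other.panels)
    html = render(model, "html")
    assert 'class="error"' in html


def test_alert_count_matches_alert_generating_rows(sim_snapshot, full_plan):
    model = build_dashboard(sim_snapshot, full_plan)
    alerts = collect_alerts(model)
    expected = 0
    for tab in model.tabs:
        for panel in tab.panels:
            if isinstance(panel, AlertListPanel):
                expected += len(panel.alerts)
            elif isinstance(panel, PatientListPanel):
                if tab.tab_name == "follow-up-visits":
                    expected += sum(
                        1 for r in panel.rows if r.get("status") in ("due", "overdue")
                    )
                elif tab.tab_name in ("ae-sae", "informed-consent"):
                    expected += len(panel.rows)
    assert len(alerts) == expected
    assert len({(a.kind, a.source_tab, a.centre_id, a.participant_id, a.message)
                for a in alerts}) == len(alerts)


def test_restock_alert_names_only_the_low_centre(hand_trial, full_plan):
    config = TrialConfig(restock_threshold=4)
    model = build_dashboard(hand_trial, full_plan, config)
    stock_alerts = [a for a in collect_alerts(model, config) if a.kind == "restock"]
    assert [a.centre_id for a in stock_alerts] == ["B"]


def test_each_fault_surfaces_as_an_alert(sim_snapshot, full_plan):
    cases = [
        (FaultSpec(name="delayed-sae-entry", hours=96), "sae-late"),
        (FaultSpec(name="slow-centre", centre_id="C01", factor=0.0,
                   after=dt.date(2024, 8, 1)), "slow-recruitment"),
        (FaultSpec(name="missing-fields", form_type="primary-endpoint", prob=0.6),
         "low-completeness"),
        (FaultSpec(name="stalled-queries", centre_id="C01"), "query-backlog"),
    ]
    for fault, kind in cases:
        faulty = perturb_trial(sim_snapshot, fault)
        alerts = collect_alerts(build_dashboard(faulty, full_plan))
        assert any(a.kind == kind for a in alerts), fault.name
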