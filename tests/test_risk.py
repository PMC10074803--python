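"""Risk instrument, severity×likelihood grading, and tab-plan compilation."""

import datetime as dt

import pytest
import yaml

from trialwatch.errors import SchemaError, TrialWatchError
from trialwatch.risk import (
    ACTIVATION_GRADE,
    TAB_CATALOGUE,
    RiskAssessment,
    compile_tab_plan,
    grade_for_score,
    load_assessment,
    load_instrument,
    rate_risk,
)

EXPECTED_ELEMENTS = {
    "Participant Safety and Rights": [
        "informed consent", "AE/SAE reporting and documentation",
        "inclusion/exclusion",
    ],
    "Overall Study Management": [
        "recruitment", "retention", "study procedures and endpoint assessment",
        "participant schedule", "AE/SAE management",
    ],
    "Device/Medication Management": ["administration", "accountability/storage"],
    "Study Data": ["data quality", "documentation/storage"],
}


def test_default_instrument_has_four_domains_and_twelve_elements():
    inst = load_instrument()
    assert len(inst.domains) == 4
    by_domain = {d.domain_name: [e.element_name for e in d.elements]
                 for d in inst.domains}
    assert by_domain == EXPECTED_ELEMENTS
    assert len(inst.element_names()) == 12


def test_every_element_carries_assets_and_sae_asset_is_universal():
    inst = load_instrument()
    for domain in inst.domains:
        for element in domain.elements:
            assert element.assets, element.element_name
            for asset in element.assets:
                assert asset.scenarios
    sae_el = inst.find_element("AE/SAE reporting and documentation")
    assert any(a.universal for a in sae_el.assets)
    schedule_el = inst.find_element("participant schedule")
    texts = [a.asset_text for a in schedule_el.assets]
    assert "Visits/Phone calls must be within the given timeframe" in texts


def test_instrument_config_with_unknown_domain_is_schema_error(tmp_path):
    cfg = tmp_path / "instrument.yaml"
    cfg.write_text(yaml.safe_dump({
        "domains": ["Study Data"],
        "elements": [{"name": "data quality", "domain": "Unknown Domain"}],
    }))
    with pytest.raises(SchemaError, match="Unknown Domain"):
        load_instrument(cfg)


@pytest.mark.parametrize(
    "severity, likelihood, score, grade",
    [
        (1, 1, 1, "low"), (1, 2, 2, "low"), (2, 1, 2, "low"),
        (1, 3, 3, "medium"), (3, 1, 3, "medium"), (2, 2, 4, "medium"),
        (2, 3, 6, "high"), (3, 2, 6, "high"), (3, 3, 9, "high"),
    ],
)
def test_rating_score_and_grade(severity, likelihood, score, grade):
    inst = load_instrument()
    rating = rate_risk(inst, "recruitment", severity, likelihood)
    assert rating.score == score == severity * likelihood
    assert rating.grade == grade


def test_grade_is_monotone_in_severity_and_likelihood():
    order = {"low": 0, "medium": 1, "high": 2}
    for s in (1, 2, 3):
        for l in (1, 2):
            assert order[grade_for_score(s * l)] <= order[grade_for_score(s * (l + 1))]
            assert order[grade_for_score(l * s)] <= order[grade_for_score((l + 1) * s)]


def test_rating_rejects_unknown_element_and_out_of_range_ordinals():
    inst = load_instrument()
    with pytest.raises(TrialWatchError, match="unknown risk element"):
        rate_risk(inst, "nonexistent", 1, 1)
    with pytest.raises(TrialWatchError, match="severity"):
        rate_risk(inst, "recruitment", 4, 1)
    with pytest.raises(TrialWatchError, match="likelihood"):
        rate_risk(inst, "recruitment", 1, 0)


GENERIC_TABS = {
    "recruitment", "patient-characteristics", "retention", "ae-sae",
    "safety-management", "data-quality",
}


def _assessment(inst, *ratings):
    return RiskAssessment(
        trial_id="demo",
        assessed_on=dt.date(2024, 1, 1),
        ratings=[rate_risk(inst, el, s, l) for el, s, l in ratings],
    )


def test_catalogue_generic_set_matches_fixed_listing():
    assert {name for name, cls, _ in TAB_CATALOGUE if cls == "generic"} == GENERIC_TABS


def test_empty_assessment_activates_exactly_the_generic_tabs():
    inst = load_instrument()
    plan = compile_tab_plan(inst, _assessment(inst))
    active = {t.tab_name for t in plan.active_tabs()}
    assert active == GENERIC_TABS
    assert all(t.classification == "optional" for t in plan.tabs if not t.active)


def test_high_schedule_risk_activates_follow_up_visits_tab():
    inst = load_instrument()
    plan = compile_tab_plan(inst, _assessment(inst, ("participant schedule", 3, 3)))
    tab = {t.tab_name: t for t in plan.tabs}["follow-up-visits"]
    assert tab.active and tab.classification == "optional"
    assert "participant schedule" in tab.source_elements


def test_low_accountability_risk_leaves_medication_tab_inactive():
    inst = load_instrument()
    plan = compile_tab_plan(inst, _assessment(inst, ("accountability/storage", 1, 1)))
    assert not {t.tab_name: t for t in plan.tabs}["medication"].active
    # medium grade crosses the activation threshold
    plan = compile_tab_plan(inst, _assessment(inst, ("accountability/storage", 2, 2)))
    assert {t.tab_name: t for t in plan.tabs}["medication"].active
    assert ACTIVATION_GRADE == "medium"


def test_tab_plan_is_idempotent_and_rating_order_independent():
    inst = load_instrument()
    ratings = [("participant schedule", 3, 2), ("informed consent", 2, 2),
               ("data quality", 1, 1)]
    a = compile_tab_plan(inst, _assessment(inst, *ratings))
    b = compile_tab_plan(inst, _assessment(inst, *ratings[::-1]))
    assert a == b
    assert compile_tab_plan(inst, _assessment(inst, *ratings)) == a


def test_assessment_file_round_trip(tmp_path):
    inst = load_instrument()
    path = tmp_path / "ratings.yaml"
    path.write_text(yaml.safe_dump({
        "trial_id": "demo",
        "assessed_on": "2024-02-01",
        "assessor_roles": ["trial manager", "monitor"],
        "ratings": [
            {"element": "participant schedule", "severity": 3, "likelihood": 2,
             "rationale": "narrow endpoint window, many follow-up visits"},
        ],
    }))
    assessment = load_assessment(path, inst)
    assert assessment.ratings[0].grade == "high"
    assert compile_tab_plan(inst, assessment).active_tabs()
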