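"""Structured pre-trial risk assessment and dashboard tab planning.

The instrument is a catalogue of four risk domains, each holding risk
*elements* (aspects of trial conduct to monitor).  Every element carries
one or more *assets* — conditions essential for successful conduct, e.g.
"visits must take place within the protocol timeframe" — and each asset
lists concrete *risk scenarios*, the ways it can fail.  Assets flagged
``universal`` apply to virtually every trial (SAE reporting being the
canonical case).

A trial team rates each identified risk element on two 3-level ordinals,
severity and likelihood; the product score maps to a low/medium/high
grade.  Compiling an assessment against the instrument yields a
:class:`TabPlan`: the *generic* dashboard tabs are always active, and each
*optional* tab activates when one of its source elements is graded medium
or worse.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import SchemaError, TrialWatchError


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RiskAsset(_Model):
    asset_text: str
    scenarios: list[str] = Field(default_factory=list)
    universal: bool = False
    provenance: Literal["catalogue", "synthesized"] = "catalogue"


class RiskElement(_Model):
    element_name: str
    assets: list[RiskAsset] = Field(default_factory=list)


class RiskDomain(_Model):
    domain_name: str
    elements: list[RiskElement] = Field(default_factory=list)


class RiskInstrument(_Model):
    domains: list[RiskDomain]

    def element_names(self) -> list[str]:
        return [e.element_name for d in self.domains for e in d.elements]

    def find_element(self, name: str) -> Optional[RiskElement]:
        for d in self.domains:
            for e in d.elements:
                if e.element_name == name:
                    return e
        return None


class RiskRating(_Model):
    element_name: str
    severity: int = Field(ge=1)
    likelihood: int = Field(ge=1)
    score: int
    grade: Literal["low", "medium", "high"]
    rationale: str = ""


class RiskAssessment(_Model):
    trial_id: str
    assessed_on: dt.date
    ratings: list[RiskRating] = Field(default_factory=list)
    assessor_roles: list[str] = Field(default_factory=list)


class PlannedTab(_Model):
    tab_name: str
    classification: Literal["generic", "optional"]
    source_elements: list[str]
    active: bool


class TabPlan(_Model):
    tabs: list[PlannedTab]

    def active_tabs(self) -> list[PlannedTab]:
        return [t for t in self.tabs if t.active]


# ---------------------------------------------------------------------------
# the default instrument
#
# Four domains and twelve elements; the participant-schedule and SAE assets
# are the instrument's worked catalogue entries, the remainder are
# synthesized one-liners distilled from each element's monitoring purpose
# (tagged provenance="synthesized").

_D_SAFETY = "Participant Safety and Rights"
_D_MANAGEMENT = "Overall Study Management"
_D_MEDICATION = "Device/Medication Management"
_D_DATA = "Study Data"

E_INFORMED_CONSENT = "informed consent"
E_AE_SAE_REPORTING = "AE/SAE reporting and documentation"
E_INCLUSION_EXCLUSION = "inclusion/exclusion"
E_RECRUITMENT = "recruitment"
E_RETENTION = "retention"
E_STUDY_PROCEDURES = "study procedures and endpoint assessment"
E_PARTICIPANT_SCHEDULE = "participant schedule"
E_AE_SAE_MANAGEMENT = "AE/SAE management"
E_ADMINISTRATION = "administration"
E_ACCOUNTABILITY = "accountability/storage"
E_DATA_QUALITY = "data quality"
E_DOCUMENTATION = "documentation/storage"


def _syn(text: str, scenarios: list[str]) -> dict:
    return {"asset_text": text, "scenarios": scenarios, "provenance": "synthesized"}


_DEFAULT_INSTRUMENT: list[dict] = [
    {
        "domain_name": _D_SAFETY,
        "elements": [
            {
                "element_name": E_INFORMED_CONSENT,
                "assets": [
                    _syn(
                        "Every participant has valid informed consent; re-consent is "
                        "obtained when participants could not previously consent themselves",
                        ["Participants remain on study without a required re-consent"],
                    )
                ],
            },
            {
                "element_name": E_AE_SAE_REPORTING,
                "assets": [
                    {
                        "asset_text": "SAEs have to be reported and documented correctly "
                        "in the required timeframe",
                        "scenarios": [
                            "Complexity of CRF or missing SOPs for SAE reporting leads to "
                            "incorrect documentation",
                            "Complexity of CRF or missing SOPs for SAE reporting leads to "
                            "delayed reporting of SAEs",
                        ],
                        "universal": True,
                    }
                ],
            },
            {
                "element_name": E_INCLUSION_EXCLUSION,
                "assets": [
                    _syn(
                        "Safety-relevant inclusion and exclusion criteria are verifiable "
                        "in the database",
                        ["Ineligible participants are randomized because a safety-relevant "
                         "criterion was not checked"],
                    )
                ],
            },
        ],
    },
    {
        "domain_name": _D_MANAGEMENT,
        "elements": [
            {
                "element_name": E_RECRUITMENT,
                "assets": [
                    _syn(
                        "Actual recruitment keeps pace with the expected trajectory in "
                        "total and per centre",
                        ["Slow recruitment delays the trial and inflates costs"],
                    )
                ],
            },
            {
                "element_name": E_RETENTION,
                "assets": [
                    _syn(
                        "Participants remain on study until outcome data are collected",
                        ["Early study exits leave primary outcome data missing"],
                    )
                ],
            },
            {
                "element_name": E_STUDY_PROCEDURES,
                "assets": [
                    _syn(
                        "Protocol procedures (bio-sampling, imaging, endpoint assessment) "
                        "are performed and analysable",
                        ["Low-quality or missing procedure data cannot support the endpoint"],
                    )
                ],
            },
            {
                "element_name": E_PARTICIPANT_SCHEDULE,
                "assets": [
                    {
                        "asset_text": "Visits/Phone calls must be within the given timeframe",
                        "scenarios": [
                            "Time point of visit is critical for the endpoint assessment "
                            "of the study",
                            "Large number of visits are difficult to organize and "
                            "coordinate between centres and patients",
                        ],
                    }
                ],
            },
            {
                "element_name": E_AE_SAE_MANAGEMENT,
                "assets": [
                    _syn(
                        "Reported SAEs/AEs are followed up and their distribution across "
                        "arms and centres is kept under review",
                        ["A safety signal (e.g. SAEs clustering in one arm) is noticed late"],
                    )
                ],
            },
        ],
    },
    {
        "domain_name": _D_MEDICATION,
        "elements": [
            {
                "element_name": E_ADMINISTRATION,
                "assets": [
                    _syn(
                        "The investigational product is administered per the medication plan",
                        ["Dosing deviations compromise the intervention contrast"],
                    )
                ],
            },
            {
                "element_name": E_ACCOUNTABILITY,
                "assets": [
                    _syn(
                        "Site stock of the investigational product is accounted for and "
                        "sufficient for upcoming visits",
                        ["A site runs out of kits and visits must be postponed"],
                    )
                ],
            },
        ],
    },
    {
        "domain_name": _D_DATA,
        "elements": [
            {
                "element_name": E_DATA_QUALITY,
                "assets": [
                    _syn(
                        "CRF data are complete, consistent and entered in a timely manner",
                        ["Incomplete or late data entry hides problems and wastes "
                         "monitoring effort"],
                    )
                ],
            },
            {
                "element_name": E_DOCUMENTATION,
                "assets": [
                    _syn(
                        "Essential trial documentation is filed and retrievable",
                        ["Missing documentation fails audit or inspection"],
                    )
                ],
            },
        ],
    },
]


def load_instrument(config_path=None) -> RiskInstrument:
    """Return the default instrument, or load one from a YAML/JSON file.

    A config file uses a flat layout::

        domains: [name, ...]
        elements:
          - name: ...
            domain: ...
            assets: [{asset_text, scenarios, universal}, ...]

    so that an element citing an unknown domain is a schema error.
    """
    if config_path is None:
        return RiskInstrument(domains=_DEFAULT_INSTRUMENT)

    path = Path(config_path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except Exception as exc:
        raise SchemaError(f"unreadable instrument file {path}: {exc}") from exc
    if not isinstance(raw, dict) or "domains" not in raw or "elements" not in raw:
        raise SchemaError(f"{path}: instrument file needs 'domains' and 'elements'")
    domain_names = list(raw["domains"])
    buckets: dict[str, list[RiskElement]] = {d: [] for d in domain_names}
    for entry in raw["elements"]:
        domain = entry.get("domain")
        if domain not in buckets:
            raise SchemaError(
                f"{path}: element {entry.get('name')!r} cites unknown domain {domain!r}"
            )
        try:
            buckets[domain].append(
                RiskElement(
                    element_name=entry["name"],
                    assets=[RiskAsset(**a) for a in entry.get("assets", [])],
                )
            )
        except Exception as exc:
            raise SchemaError(f"{path}: invalid element {entry.get('name')!r}: {exc}") from exc
    return RiskInstrument(
        domains=[RiskDomain(domain_name=d, elements=buckets[d]) for d in domain_names]
    )


# ---------------------------------------------------------------------------
# rating

#: grade cut-points on the severity × likelihood product
GRADE_LOW_MAX = 2
GRADE_MEDIUM_MAX = 4

#: ordinal scale size (3-level by default; configurable at call site)
DEFAULT_SCALE_LEVELS = 3


def grade_for_score(score: int) -> str:
    if score <= GRADE_LOW_MAX:
        return "low"
    if score <= GRADE_MEDIUM_MAX:
        return "medium"
    return "high"


def rate_risk(
    instrument: RiskInstrument,
    element_name: str,
    severity: int,
    likelihood: int,
    rationale: str = "",
    scale_levels: int = DEFAULT_SCALE_LEVELS,
) -> RiskRating:
    """Rate one risk element; score = severity × likelihood.

    Grade thresholds: low ≤ 2, medium 3–4, high ≥ 6 — the smallest matrix
    that separates a "wide window, many visits" narrative (lower severity)
    from a genuinely critical one.
    """
    if instrument.find_element(element_name) is None:
        raise TrialWatchError(f"unknown risk element: {element_name!r}")
    for label, value in (("severity", severity), ("likelihood", likelihood)):
        if not isinstance(value, int) or not 1 <= value <= scale_levels:
            raise TrialWatchError(f"{label} must be an integer in 1..{scale_levels}")
    score = severity * likelihood
    return RiskRating(
        element_name=element_name,
        severity=severity,
        likelihood=likelihood,
        score=score,
        grade=grade_for_score(score),
        rationale=rationale,
    )


# ---------------------------------------------------------------------------
# tab plan

#: dashboard tab catalogue: (tab_name, classification, source elements).
#: Order: study-management tabs first, then oversight/progress tabs; the
#: dashboard layer may override the order via config.
TAB_CATALOGUE: list[tuple[str, str, list[str]]] = [
    ("ae-sae", "generic", [E_AE_SAE_REPORTING]),
    ("safety-management", "generic", [E_AE_SAE_MANAGEMENT]),
    ("follow-up-visits", "optional", [E_PARTICIPANT_SCHEDULE]),
    ("informed-consent", "optional", [E_INFORMED_CONSENT]),
    ("inclusion-exclusion", "optional", [E_INCLUSION_EXCLUSION]),
    ("medication", "optional", [E_ADMINISTRATION, E_ACCOUNTABILITY]),
    ("data-quality", "generic", [E_DATA_QUALITY, E_DOCUMENTATION]),
    ("recruitment", "generic", [E_RECRUITMENT]),
    ("patient-characteristics", "generic", [E_RECRUITMENT, E_INCLUSION_EXCLUSION]),
    ("retention", "generic", [E_RETENTION]),
]

#: lowest grade that activates an optional tab
ACTIVATION_GRADE = "medium"

_GRADE_ORDER = {"low": 0, "medium": 1, "high": 2}


def compile_tab_plan(instrument: RiskInstrument, assessment: RiskAssessment) -> TabPlan:
    """Compile an assessment into the trial's dashboard tab plan.

    Generic tabs are active unconditionally.  An optional tab activates iff
    one of its source elements is rated at or above :data:`ACTIVATION_GRADE`.
    Idempotent and independent of the order of the ratings list.
    """
    known = set(instrument.element_names())
    for rating in assessment.ratings:
        if rating.element_name not in known:
            raise TrialWatchError(
                f"assessment rates unknown element {rating.element_name!r}"
            )
    grade_of: dict[str, int] = {}
    for rating in assessment.ratings:
        level = _GRADE_ORDER[rating.grade]
        grade_of[rating.element_name] = max(grade_of.get(rating.element_name, -1), level)

    threshold = _GRADE_ORDER[ACTIVATION_GRADE]
    tabs = []
    for tab_name, classification, sources in TAB_CATALOGUE:
        if classification == "generic":
            active = True
        else:
            active = any(grade_of.get(el, -1) >= threshold for el in sources)
        tabs.append(
            PlannedTab(
                tab_name=tab_name,
                classification=classification,
                source_elements=list(sources),
                active=active,
            )
        )
    return TabPlan(tabs=tabs)


def load_assessment(path, instrument: RiskInstrument) -> RiskAssessment:
    """Read trial ratings from a YAML/JSON file and grade them.

    Expected layout::

        trial_id: ...
        assessed_on: YYYY-MM-DD
        assessor_roles: [trial manager, monitor, ...]
        ratings:
          - element: participant schedule
            severity: 3
            likelihood: 2
            rationale: ...
    """
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except Exception as exc:
        raise SchemaError(f"unreadable assessment file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: assessment file must be a mapping")
    try:
        ratings = [
            rate_risk(
                instrument,
                entry["element"],
                int(entry["severity"]),
                int(entry["likelihood"]),
                entry.get("rationale", ""),
            )
            for entry in raw.get("ratings", [])
        ]
        return RiskAssessment(
            trial_id=str(raw.get("trial_id", "trial")),
            assessed_on=dt.date.fromisoformat(str(raw.get("assessed_on", dt.date.today()))),
            ratings=ratings,
            assessor_roles=[str(r) for r in raw.get("assessor_roles", [])],
        )
    except TrialWatchError:
        raise
    except Exception as exc:
        raise SchemaError(f"{path}: invalid assessment: {exc}") from exc
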