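# Methods

This note documents the models, conventions and design choices behind
`trialwatch`: what each pathway computes, what the simulator emulates,
and where the genuinely open decisions were made.

## Data model and conventions

A trial's state at one export date is a `TrialSnapshot`: seven record
tables (centres, participants, visit occurrences, forms, adverse events,
queries, product stock) plus the protocol visit schedule. Conventions,
fixed once so that bundles are bit-reproducible:

* Dates are ISO-8601 calendar days with closed intervals and whole-day
  arithmetic; no timezones. The single sub-day quantity is the SAE
  first-entry timestamp (`YYYY-MM-DDTHH:MM`), because safety reporting
  deadlines are stated in hours.
* CSV dialect: UTF-8, comma separated, one header row, empty string for
  missing, `\n` line ends, canonical row order (sorted serialized rows).
  Reading is therefore insensitive to input row order, and
  write → read → write is byte-stable.
* The protocol schedule lives in `trial_config.yaml`, not a CSV: it is
  protocol metadata, not accumulating data.
* Cross-field/cross-table invariants (foreign keys, date ordering, "no
  recorded date after the export date", completed ≤ required fields, …)
  are checked by `validate_snapshot`, which returns findings rather than
  raising, so inconsistent data can be inspected and repaired. The
  writer refuses snapshots with error findings; the reader raises on
  them, naming the offending rows.

## Risk assessment

The instrument has four domains and twelve risk elements. Severity and
likelihood are 3-level ordinals (the scale size is an argument of
`rate_risk` for teams that prefer finer scales); the score is their
product and the grade is low (≤ 2), medium (3–4) or high (≥ 6). This is
the smallest matrix that separates, say, a trial with many visits but a
wide endpoint window (severity down-rated) from one with a narrow
critical window. Two catalogue entries — the participant-schedule asset
("Visits/Phone calls must be within the given timeframe") and the
universal SAE-reporting asset — are worked in full; the remaining
elements carry one synthesized asset each, distilled from the element's
monitoring purpose and tagged `provenance="synthesized"` so they can be
replaced by a site's own catalogue.

Optional tabs activate at grade **medium** or above: activation is meant
to respond to "identified risks", and medium is the lowest non-trivial
grade. The tab→element mapping is fixed in `TAB_CATALOGUE`; the tab
order places study-management tabs before oversight/progress tabs and
can be overridden when building the dashboard.

## Pathways

**Visit classification.** For a scheduled visit with target offset *d*,
window (−*b*, +*a*) and grace *g*, and a participant randomized on day
*r*: the window is the closed interval [*r*+*d*−*b*, *r*+*d*+*a*] and
the grace end is *r*+*d*+*a*+*g*. A recorded visit is completed in or
out of window; an unrecorded one is *pending* before the window opens,
*due* from the opening day through the closing day, *overdue* through
the grace end, and *missed* after. Unrecorded visits whose window opens
after a participant's end date are *not-applicable*; windows already
open at the end date keep the normal clock (a visit the participant left
without attending stays missed). The statuses partition every
participant × visit pair, which the tests verify both against a
day-stepping oracle and by count reconciliation.

**SAE timeliness.** The reporting clock starts at midnight of the
awareness date, falling back to the onset date (flagged
`onset-fallback`) when awareness is unrecorded. Elapsed time is whole
hours to the first-entry timestamp; an entry exactly at the deadline is
on time (closed bound). Serious events without a first entry are counted
*unreported* and excluded from elapsed statistics.

**Recruitment.** Expected accrual per centre is linear from its
activation date at `expected_rate` participants per 30 days, capped at
the centre's enrolment target; the curve is evaluated daily and the
overall series is the pointwise sum. Linearity is the simplest curve
consistent with a per-centre expected rate as the instrument's input;
`recruitment_trajectory` is the single place to swap in another curve.

**Retention.** Retention = 1 − ended-early/randomized, with early-exit
reasons tabulated and the count of dropouts whose primary outcome is
still available reported separately (it determines how much data remains
analysable). Ratios over zero denominators are reported as missing, not
zero — except SAEs-per-randomized, defined as 0 for an empty trial.

**Data quality.** Completeness per form type pools completed over
required fields (per centre and overall — pooled ratios, not averages of
ratios, so per-centre values reconcile exactly with the overall value).
Entry lag of a visit-linked form is entry date minus the visit's actual
date; the summary reports median, 90th percentile and the count beyond
the configured limit (default 7 days). Query status maps to a traffic
light per centre: green with no open queries, amber with at most 5
(configurable), red beyond.

**Medication.** Kit consumption sums the schedule's per-visit
`kits_dispensed` over completed visits; remaining stock is the latest
cumulative delivery minus consumption. Negative remaining stock is
reported with a warning, never clamped — it is exactly the discrepancy a
monitor must see. A restock alert fires below the threshold (default 5
kits); centres without stock records get a suppressed alert plus a
warning.

**Percentages.** All percentage vectors are apportioned to one decimal
by largest remainder, so each vector sums to exactly 100.0 while the raw
counts are always carried alongside. Plain per-level rounding cannot
guarantee that sum for three or more levels; largest-remainder agrees
with conventional rounding in the typical case (e.g. counts 2:1:0:0 →
66.7/33.3/0/0) and makes the sum-to-100 invariant unconditional.

## Synthetic trials

The generator emulates a two-arm multicentre RCT as seen through daily
EDC exports. Default study conditions: five centres activating one month
apart, each expecting 4 participants per 30 days toward a target of 60;
a four-visit schedule (baseline, months 1, 3 and 6, the last carrying
the primary outcome); dropout hazard 5·10⁻⁴ per day; 0.08 SAEs per
participant per 90 days of exposure with three non-serious AEs per SAE;
data-entry lag one less than a geometric draw with p = 0.4 (mean 1.5
days); 8 % visit noncompliance and 5 % out-of-window visits; 5 % field
missingness; queries raised on 15 % of forms and resolved at 10 % per
day; observation at day 540. These magnitudes are typical of mid-size
academic trials and produce a dashboard in which every panel has
content.

Processes are simulated day by day. Accrual is a per-day Poisson process
truncated at the centre's target; dropout is geometric in days
(constant hazard), censored at the end of the scheduled follow-up; SAE
counts are Poisson with exposure-scaled rate, with onset uniform over
exposure, awareness 0–2 days later, and a first-entry timestamp at a
uniform hour of the entry day. Randomness uses one master seed with a
named `SeedSequence` stream per process, so adding a new process never
perturbs existing draws and identical parameters reproduce bundles
byte-for-byte.

The `GroundTruth` record carries both the configured parameters and the
realized totals (dropout count with its expected value and variance
under the configured hazard, SAE count with total exposure, mean entry
lag), enabling 3-standard-error parameter-recovery checks at ~2,000
participants without re-deriving expectations in the tests.

What the simulator deliberately does **not** emulate: correlated
clinical covariates, adaptive designs, centre-level heterogeneity beyond
activation/rate/target, informative dropout, or EDC audit trails. A
green test suite therefore demonstrates the correctness of the metric
arithmetic and the detection machinery on data with known structure —
not that real-trial exports are this clean.

Fault injection produces the canonical risk scenarios: `delayed-sae-entry`
shifts every SAE first entry by a given number of hours (advancing the
export date if a shifted timestamp would pass it, so the perturbed
snapshot still validates); `slow-centre` thins a centre's recruits after
a cut date; `missing-fields` knocks out completed fields of one form
type; `stalled-queries` reopens a centre's queries. Each fault is
detected by its matching pathway and surfaces in the alert list.

## Dashboard and alerts

The dashboard model is a typed tree (tabs → panels) restricted to five
panel kinds — value box, per-centre series, distribution, patient list,
alert list — plus an error panel: a failing pathway degrades its tab to
an error panel and the rest of the dashboard still builds, because a
partial daily report beats none. JSON rendering is lossless
(parse(render(m)) == m) and byte-deterministic; the HTML renderer
produces a single self-contained static page with one section per active
tab, tables in place of interactive charts (the full series remain in
the JSON). Record links are produced from a configurable URL template
(`ecrf_url_template`), defaulting to a local anchor, since real eCRF
deep links are installation-specific. E-mail reminders are modelled as
alert records in `alerts.json`; dispatch is out of scope.

Alert derivation is rule-based over the panels: due/overdue visit rows,
late/unreported SAE rows and pending re-consent rows each yield one
alert, and the dedicated alert-list panels (slow recruitment below 70 %
of expected once at least 5 are expected, restock, red query backlog,
form completeness below 0.8) are passed through; alerts are
deduplicated on (kind, tab, centre, participant, message).

## Problem sizes and tolerances

The test suite runs the full pipeline on a ~300-participant simulated
trial, checks the visit classifier against a brute-force day-stepping
oracle on 1,000+ randomized instances including every window boundary
day, and verifies parameter recovery on a 2,000-participant, 5-centre
simulation with all statistical assertions at 3 standard errors (or
3·√λ for Poisson counts). The acceptance script uses the same sizes;
everything completes in seconds on one CPU.

## Known limitations

* The bundle schema is a deliberate abstraction of an EDC daily export;
  no vendor's proprietary export format is parsed.
* Severity/likelihood scale size beyond 3 levels is supported
  mechanically, but the grade cut-points are calibrated for the 3×3
  matrix.
* Non-serious AEs are reported as counts only; severity/causality/
  outcome distributions are computed for SAEs.
* Site comparison is descriptive (traffic lights, trajectories), not
  inferential: no statistical testing for atypical centres or fraud
  detection is performed or planned.
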