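# trialwatch

Risk-tailored management and monitoring for investigator-initiated
randomized controlled trials.

Academic multicentre RCTs rarely have the budget for commercial clinical
trial management systems, yet the problems that sink them — slow
recruitment, losses to follow-up, late serious-adverse-event (SAE)
reporting, incomplete case report forms (CRFs) — are visible early in the
accumulating trial data if someone computes the right quantities every
day. `trialwatch` is a toolkit for trial managers, monitors and principal
investigators that does exactly that:

1. **Risk assessment.** A structured instrument of 4 domains (participant
   safety and rights, overall study management, device/medication
   management, study data) and 12 risk elements, each carrying *assets*
   (conditions essential for trial success) and *risk scenarios* (ways
   they fail). Each identified risk is rated on 3-level severity *s* and
   likelihood *l* ordinals; the score *s·l* maps to a grade
   (low ≤ 2 < medium ≤ 4 < high).
2. **Tab plan.** Grades compile into a dashboard plan: six *generic* tabs
   (recruitment, patient characteristics, retention, AE/SAE
   completeness-timeliness, safety management, data quality) are always
   active; *optional* tabs (follow-up visits, medication, informed
   consent/re-consent, inclusion-exclusion) activate when a mapped element
   is graded medium or worse.
3. **Pathways.** Each tab is backed by a metric pathway over a daily
   CSV export bundle of the trial database: visit-window classification
   (due/overdue/missed against the protocol's per-visit windows and grace
   periods), SAE first-entry timeliness against an hour deadline,
   cumulative actual-vs-expected accrual per centre, retention and
   early-exit reasons, pooled CRF completeness and query management,
   and investigational-product stock reconciliation.
4. **Dashboard.** The pathway outputs assemble into a machine-readable
   dashboard model (value boxes, per-centre series, distributions,
   patient lists with eCRF deep links) rendered to JSON or a static HTML
   page, and into a deduplicated alert list (due visits, late SAEs,
   restock, query backlog, pending re-consents) standing in for e-mail
   reminders.

A seeded simulator of a multicentre RCT (Poisson accrual per centre,
geometric dropout hazard, exposure-scaled Poisson adverse events,
window-respecting visits with configurable noncompliance, geometric
data-entry lags, query lifecycle) provides ground-truthed test data, and
a fault injector (delayed SAE entry, slowed centre, missing fields,
stalled queries) produces the risk scenarios the pathways must detect.

## Worked example

```python
import trialwatch as tw

snap, truth = tw.generate_trial(seed=1)        # simulated multicentre RCT
s = tw.safety_summary(snap)
t = tw.sae_report_timeliness(snap, 72)         # 72-hour deadline
v = tw.classify_visits(snap)
r = tw.retention_summary(snap)

print(len(snap.participants))                  # 293 randomized
print(s.overall.sae_count,
      s.overall.patients_with_sae)             # 44 SAEs in 41 patients
print(round(s.overall.sae_per_randomized, 3))  # 0.15 SAEs per randomized
print(t.n_on_time, t.n_late, t.n_unreported)   # 34 on time, 9 late, 1 unreported
print(v.counts["due"], v.counts["overdue"],
      v.counts["missed"])                      # 21 due, 2 overdue, 82 missed
print(round(r.overall.retention, 3))           # 0.928 still on study
```

`44 SAEs in 41 patients` and the 0.15 ratio are the safety tab's value
boxes; the 9 late and 1 unreported SAE rows, the 21 due and 2 overdue
visits become alerts; 82 missed visits at day 540 reflect the simulated
8 % visit-noncompliance accumulated over four protocol visits.

The same workflow from the shell:

```sh
trialwatch assess --ratings ratings.yaml --out plan.json
trialwatch simulate --seed 1 --out bundle/
trialwatch metrics --bundle bundle/ --tab safety --format json
trialwatch report --bundle bundle/ --plan plan.json --out report/
# -> report/dashboard.json, report/dashboard.html, report/alerts.json
```

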