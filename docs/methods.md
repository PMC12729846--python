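# Methods

`pm2pim` implements an end-to-end analytical chain for clinical event logs:
data preparation, conformance checking against a strictly sequential
normative pathway, KPI extraction, deterministic what-if scenario
remodeling (the Predictive Impact Model, PIM), statistical validation of
the forecast gains, and a frequency x impact decision matrix.  This note
documents the models, the calibration of the synthetic data generator, the
numerical choices, and the known limitations.

## The normative model and conformance

The intended chemotherapy pathway is a chain of seven activities:
Admission -> Billing -> Chemotherapy -> Nurse and Medication Basket ->
Injection -> Record Handling -> Treatment Completion.  Record Handling is
flagged as the approval-class step (the chart re-approval between injection
and completion); the set is configurable because real deployments may flag
additional validation steps.

Against a sequential model, optimal alignment degenerates to an edit
distance with matches and indels only (synchronous moves cost 0, log-only
and model-only moves cost 1, both configurable).  The dynamic program
breaks ties by preferring synchronous moves, then model moves as early as
possible.  Derived metrics:

- **Fitness** per trace is `1 - cost / (|trace| + |model|)` — the standard
  worst-case normalization; the log-level value is the unweighted mean
  (a cost-weighted aggregate is available as an option).
- **Precision** is escaping-edges precision over the prefix automaton of
  the aligned model runs.  Every alignment completes the model run, so each
  non-final state records the transition actually taken; for a chain the
  model allows exactly one transition per state and any non-empty log
  yields 1.0.  **Backwards precision** applies the same computation to the
  reversed traces against the reversed model; reversing twice recovers the
  forward value (an invariant under test).
- **Balanced precision** is the arithmetic mean of precision and backwards
  precision; F1 is the harmonic mean of fitness and precision.
- **Generalization** is event-class based, `1 - mean(1/sqrt(executions))`
  over model transitions, and **simplicity** scores degree-regularity of
  the place-transition chain, `1/(1 + |mean degree - 2|)` (1 by convention
  for a single-transition model).  Both are informational only: no
  published formula exists for the corresponding reported values, so they
  are deliberately not calibration targets.

### Deviation classification

Rules apply per case in priority order:

1. any activity occurring twice or more marks a **rework loop**; each
   maximal run of already-seen activities is one record.  The attributed
   *waiting delay* is the gap between the segment and its predecessor
   event; the *span* is the segment's internal duration.  Loops are
   detected on the raw trace first because their events would otherwise
   surface as unmatched log moves;
2. an unmatched log move and model move on the same single-occurrence
   activity is a **resequencing** (in an optimal alignment such a pair is
   necessarily position-crossed);
3. remaining model-only moves are **skipped steps** (approval-class first);
4. remaining log-only moves are **extra activities**, carrying the
   inter-event gap they occupy (capped at three times the case's mean gap)
   as attributed delay.

Model-only runs *after the last synchronous move* are treated as case
truncation — an incomplete journey, for example a patient whose record
stops after admission — rather than as skipped steps.  A literal reading of
rule 3 would label a one-event case a five-fold skipper; the truncation
rule keeps "skipped step" reserved for steps bypassed *inside* an ongoing
journey, which is the clinically meaningful category.

Root causes default to: rework loops and skipped Nurse/Record steps ->
human (preparation errors, bypassed double-checks and approvals); skipped
Chemotherapy/Injection records -> technical (HIS logging failures); skipped
Billing and resequencing -> organizational (queueing and scheduling).  The
map is configurable per (type, activity).

## The synthetic generator

No public dataset exists; the generator rebuilds a log from the published
marginals so that every pipeline stage is testable.  Hard calibration
targets (exact by construction, for every seed):

| statistic | target |
|---|---|
| cases / events | 214 / 1254 |
| per-activity counts | 215, 194, 188, 181, 176, 154, 146 |
| distinct variants | 15 |
| strictly adherent cases | 27 (mean workload exactly 7.00) |
| events per case | within [1, 14], both bounds attained |
| mean cycle time | 5.46 d (sd target 1.12 d), stochastic |
| scenario forecasts | 8%/6% (current), 12%/9% (full adherence) |

The variant catalog is an exact integer allocation: one canonical variant
(27 cases), four truncated prefixes, five skipped-step variants, one
resequenced variant (Nurse/Injection swapped), and four rework variants —
billing-correction loops (`Billing, Injection` repeats, 21 cases, up to 14
events) and records-rework loops (`Chemotherapy, Record Handling` repeats
plus one double-admission case, 13 cases).  The allocation was solved by
hand from the marginal equations and is re-verified by recount at build
time; non-standard configurations go through a greedy prefix allocator
with marginal-preserving adjacent-swap splitting, which raises a
calibration error when no integer allocation exists.

### Why several published marginals cannot hold simultaneously

The activity frequency table is treated as authoritative (counts are exact
integers), and it overconstrains the rest:

- 1254 events over 214 cases give 5.86 events/case; the reported baseline
  workload of 8.07 cannot hold at the same time.
- With a seven-step model, mean replay fitness on *any* log satisfying the
  frequency table is bounded near 0.89 (the table forces at least
  244 missing-activity indels); the reported 0.97 is unreachable at these
  marginals.  The calibrated log's fitness is about 0.78.
- 194 cases reach Treatment Completion while at most 146 contain the Nurse
  step, so at least ~48 cases skip a mid-pathway step: a "12% deviant
  share" cannot coexist with the frequency table.  On the calibrated log
  about 78% of cases carry at least one deviation record.
- The headline cycle-time forecasts (8%/12% of a 5.46-day mean over 214
  cases) require roughly 93/140 case-days of removable attributed delay.
  Rework loops averaging 2.3 h per case provide about 1.3 case-days — two
  orders of magnitude short.  The generator therefore supports two delay
  models: **kpi_calibrated** (default) sizes rework footprints to the
  forecast targets (about 4.5 days per billing-rework case, 3.6 per
  records-rework case), while **marginal** reproduces the 2.3 +/- 0.5 h
  per-loop-case delay instead.  They are mutually exclusive by arithmetic,
  not by implementation choice.

`deviant_fraction` and `loop_fraction` are floors for the same reason.

### Timing model

Case start times spread uniformly over one year.  Non-loop cases draw a
total span from a normal law whose mean/sd are solved in closed form so the
whole log matches the cycle-time moments, and split it into inter-event
gaps via normalized log-normal weights (sigma 0.6).  Loop cases draw a
rework-free span of 2.2 +/- 0.3 d and insert the rework block between its
neighbours: 55% of the block's footprint is the waiting delay before the
segment (the part the sensitivity knob scales) and 45% is the internal
segment span (removed structurally with the events).  The 55/45 split is
the package's model of a partially delay-elastic rework response; it
produces OFAT responses of about -0.44/+0.44 pp (current) and
-0.67/+0.67 pp (full adherence), inside the published sensitivity table's
cells and the +/-0.7 pp caption bound.  A post-block gap floor (8% of the
footprint) guarantees that re-timing at scale 1.1 never produces negative
gaps.  Per-case substreams derive from `(seed, case_index)` so catalog
edits do not perturb unrelated cases; the generator is a pure function of
(config, seed).

What the generator does *not* emulate: arrival-process seasonality,
resource contention, clinical content (regimens, doses), and realistic
inter-activity delay distributions (the source system's empirical
distributions are unpublished).  Passing tests therefore demonstrate the
pipeline's correctness and calibration machinery, not distributional
realism of any real hospital.

## Scenario remodeling (PIM)

Remodeling is removal-only, deterministic timestamp surgery:

- **rework loops**: the repeated events are deleted; later events move
  earlier by the segment span plus the attributed waiting delay times
  `delay_scale`.  Negative gaps are clamped to one minute with a warning
  counter;
- **extra activities**: deleted, later events recover the attributed delay;
- **resequencing**: events are reordered into canonical order over the
  same timestamp slots (span preserved);
- **skipped steps**: nothing is inserted.  Re-inserting events would
  *increase* workload, contradicting the direction of the published
  workload forecast, so full adherence is interpreted as deviation
  elimination, not path completion.

The *current optimization* scenario removes the top-frequency mitigable
classes — billing-correction rework (loop records whose activities include
Billing) and resequencing; *full adherence* removes every record.
Reductions use `(baseline - scenario)/baseline x 100` on the means of the
paired per-case KPIs; per-case pairs feed the statistics layer.  Removal
sets fixed, the cycle response is linear in `delay_scale` (verified by
finite differences up to whole-second rounding); workload is
delay-invariant because event-removal decisions are not scaled.

## Statistics

Paired t (with Cohen's d on the sd of differences), a Shapiro-Wilk gate
(p <= 0.05 recommends the nonparametric track — on the calibrated log the
difference distributions are far from normal because most cases have zero
difference), Wilcoxon signed-rank (zero differences dropped; exact null by
dynamic programming over doubled midranks for effective n <= 25, normal
approximation with continuity and tie correction beyond), and a Friedman
test with midranks and the tie-correction factor (exact enumeration of all
within-row orderings for n <= 5, k <= 3; chi-square approximation
otherwise).  The tie correction matters here: with ~180 fully-tied rows the
uncorrected statistic understates the evidence by an order of magnitude.
No multiple-testing correction is applied; the report flags each test at
alpha = 0.05 individually.

## Decision matrix

Scores are frequency x impact with half-open priority bands High [40, inf),
Medium-High [25, 40), Medium [10, 25), Low [0, 10) — the printed integer
band edges, extended to the reals without gaps.  Category inputs default to
the published six-row table and are config-supplied; equal scores tie-break
alphabetically.

## Numerical conventions

- days are exactly 86,400 s; sample sd uses the n-1 denominator;
- table percentages round half-up to 3 decimals; quartiles use inclusive
  linear interpolation; whisker outliers lie beyond 1.5 x IQR;
- timestamp repair re-spaces equal-minute runs at 0, +5, +10, ... minutes
  in recorded order (offset configurable); the operation is idempotent;
- unknown activity labels fail fast under the strict dictionary policy;
- all emitted CSVs use fixed 6-decimal formatting so a fixed seed makes
  every artifact byte-identical across runs.

## Known limitations

- The calibrated log reproduces the frequency-table marginals exactly and
  the KPI forecasts to within a percentage point, but (provably) cannot
  simultaneously reproduce the fitness, deviant-share, loop-share and
  loop-delay headlines; see the infeasibility notes above.
- Alignments support strictly sequential models only (general Petri nets
  are out of scope), and conformance is offline.
- Remodeling is deterministic; queueing effects, resource schedules and
  stochastic simulation are out of scope.
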