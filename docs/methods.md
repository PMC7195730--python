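# Methods

This note documents the models and procedures implemented in `rxcoverage`,
the design decisions taken where the underlying study description was open
to interpretation, and what the synthetic-data experiments do and do not
demonstrate.

## Time axis

The analysis unit is the civil calendar quarter, half-open
`[start, next-quarter start)`, 90–92 days long. Quarters are indexed from
the first study quarter (2010Q1 → t = 0 by default), so the default
intervention quarter 2013Q2 has index t₀ = 13. A `fixed_90_day_quarters`
mode instead tiles exact 90-day windows from the study start, for the
idealized reading in which every "quarter" has 90 days; the calendar mode
is the default because it matches how quarters are labelled (2013Q2) and
how rates are reported.

**Segment bookkeeping.** The window 2010Q1–2016Q4 holds 28 quarters: 13
pre-intervention and 15 post. The reference analysis used 13 pre and 14
post; the pipeline therefore drops the final quarter (2016Q4) by default
and documents it, with `keep_last_quarter` to retain it. Which quarter the
original analysts dropped is not recorded anywhere we could find; dropping
the last one is the choice that perturbs the series least and is surfaced
rather than hidden.

## Coverage scoring

A patient is **covered** for a drug class in a quarter when their dispensed
supply overlaps at least 75 % of the quarter's days. The threshold is
`floor(0.75 × days-in-quarter)`: 67 days for a 90-day quarter (the
canonical figure), 68 for 91, 69 for 92. `floor` rather than `ceil` keeps
the canonical 67-day value exact for 90-day quarters.

Supply accounting uses a running supply-end E over date-sorted dispensings
of `s` days at date `d`:

    leftover = min(max(0, E − d), 100)        # carryover cap, days
    E        = d + s + leftover

Intervals are half-open: a 90-day supply dispensed on day 0 covers days
0–89. The cap applies to the *leftover at refill time* only; a single
dispensing's own supply is never truncated, and a refill can shorten a
previously provisional supply-end (the leftover beyond 100 days is
forfeited), exactly as a day-by-day pill-stock simulation behaves. Covered
days in a quarter are the intersection of the merged intervals with the
quarter bounds; coverage accrued before cohort entry counts, because the
rule is purely temporal.

For the combined ACEI-or-ARB class, carryover runs within each constituent
class and the resulting interval sets are unioned, so 45 ACEI days plus the
adjacent 45 ARB days cover a 90-day quarter for the combined class but for
neither alone. The antiplatelet denominator excludes patients with a
myocardial-infarction history date before the quarter end, since
antiplatelets are indicated only for secondary prevention and the
published rate tables exclude those patients.

Validation: the interval engine is checked for *exact* agreement with an
independent day-by-day stock simulation on random dispensing sequences
(10 000 sequences, up to 12 dispensings of 1–100 days over 7 years, in the
acceptance run), plus order-invariance, monotonicity and cap-tightness
properties.

## Case definitions and eligibility

**Administrative rule.** Positive on two billing claims coded 250 within
730 days (inclusive) or one diabetes-coded hospital discharge, after
removing any claim or discharge dated within [−120, +180] days (inclusive)
of a pregnancy/delivery discharge. The index date is the earliest date the
definition is satisfied: the discharge date, or the second claim of the
earliest qualifying pair. Two claims on the same date count as distinct
records. The engine is validated against an exhaustive pair-scan oracle.

**EMR rule.** The diabetes flag is consumed as an input attribute (the
upstream EMR algorithm is out of scope); entry requires the flag date
strictly before the quarter and the quarter at or after the patient's
first EMR encounter. Patients carrying the flag but having no encounter
records — a real feature of EMR registries, where a problem-list diagnosis
can exist without visit dates — enter at the study start; the sensitivity
analysis (`exclude_no_encounter`) removes them entirely.

**Eligibility per quarter** requires age ≥ 66 in completed years at the
quarter start, case-positivity strictly before the quarter start (avoiding
partial-quarter ambiguity), and no censoring. Censoring removes the quarter
of the event itself and everything after (no partially-observed
denominators): death; loss of insurance eligibility or of primary-care
enrollment (first date not covered by any merged spell); and the
last-encounter rule — a patient whose final healthcare contact of any kind
(claim, discharge, dispensing, EMR encounter) precedes the study end by
more than a configurable look-ahead (default 1 quarter) is censored in the
quarter after that contact. The last-encounter rule is necessarily
retrospective; it is applied with full-window knowledge, as any
retrospective analysis must. When several rules fire in the same quarter
the reported reason follows the order death, last encounter, insurance
loss, disenrollment.

## Segmented regression

Design per point: `[1, t, post, (t − t₀)·post]` with `post = 1{t ≥ t₀}`
and no roll-in gap. The intervention quarter belongs to the post segment —
the level-change indicator is already 1 at t₀ while the slope-change term
is still 0 there — so β₂ is the difference at the beginning of the
intervention and β₃ the post-minus-pre slope difference. Estimation is OLS
on the percent scale, unweighted by default (denominator-weighted WLS is a
flag); standard errors iid by default with Newey–West (lag 1) as the usual
ITS robustness option, since autocorrelation handling is otherwise
unspecified; two-sided t-tests; Durbin–Watson reported as a diagnostic.
Missing quarters (empty denominators) are dropped, never interpolated; at
least 3 points per segment are required. On any noiseless piecewise-linear
series the fit is exact (zero residuals), and on noisy series it matches a
closed-form normal-equations solution to ~10 significant figures.

## Synthetic-data generator

The generator emulates the linked record tables of a provincial claims
environment — patients, pharmacy dispensings, billing claims, hospital
discharges, insurance-eligibility and enrollment spells, EMR encounters —
for a closed population aged 66–90 (uniform at study start; the real
cohort's median age is ~75, and a uniform draw is sufficient for testing
the age logic).

Key defaults (all overridable in `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| study window | 2010-01-01 … 2016-12-31 | 28 quarters, intervention 2013Q2 |
| diabetes prevalence (admin / EMR flag) | 0.85 / 0.80 | the population emulates a diabetes-registry extract; EMR-flagged cases nest inside administrative cases, mirroring the 94–97 % overlap seen in linked data |
| prevalent fraction | 0.9 | most cases diagnosed before the window, giving stable denominators |
| annual hazards: death, insurance loss, disenrollment | 0.045, 0.005, 0.010 | plausible for a 66+ diabetic cohort; independent exponential times, earliest event wins — the simplest mechanism exercising all four censoring rules |
| AMI-history probability | 0.083 | ~8 % as in published cohort tables |
| no-encounter probability | 0.10 | ~9–14 % of EMR-registry patients lack encounter dates |
| days supplied | 90-day refills, ≤ 100 | the formulary's 100-day maximum |
| refill jitter | 0–7 days early | exercises the carryover rule |

Per-class coverage truth follows a piecewise-linear trajectory
(baseline %, pre-slope %/quarter, level change %, slope change %/quarter);
defaults are the magnitudes observed for each class in province-wide
dispensing data, with the ACEI and ARB paths summing to the combined-class
path. Trajectories leaving [0, 100] anywhere in the window are rejected
with the offending quarter named. Each (patient, quarter, class) cell is
drawn covered/uncovered independently with the trajectory probability;
ACEI and ARB draws are mutually exclusive within a quarter (a single
uniform decides none/ACEI/ARB), which makes the combined-class rate the
sum of the two — the near-additive pattern real dispensing data show —
while preserving union dominance.

Dispensing sequences then *realize* the truth exactly: each maximal run of
covered quarters is tiled with 90-day supplies refilled up to 7 days early
(carryover absorbs the overlap), the final supply truncated so coverage
ends exactly at the run boundary; isolated uncovered quarters may receive
one short (7–21 day) supply, placed so it can neither merge with a covered
run nor reach the 67-day threshold. Diabetes case records invert the case
definition (qualifying claim pairs or discharges for true cases;
single-claim near-misses and gestationally-excluded claim pairs for
non-cases), so classifier output equals latent truth by construction —
verified exhaustively in the tests. Truth is masked from the censoring
quarter onward, so no dispensings post-date death.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: diagnostic-code breadth beyond the 250 prefix,
comorbidity and utilization structure, prescriber behaviour, quarter-to-
quarter adherence persistence (cells are drawn independently, so individual
adherence runs are shorter than in reality; quarterly *rates* are
unaffected), dynamic practice recruitment (real EMR cohorts grow as
practices join; the synthetic cohort is closed, so quarterly denominators
shrink slowly instead of growing), pregnancies restricted to plausible
ages (gestational near-miss records are emitted regardless of age — they
exist to exercise the exclusion filter), and over-the-counter antiplatelet
capture. Non-diabetic patients receive no dispensings, since they can
never enter a denominator.

## Numerical and implementation choices

- Scalar reference implementations (`supply_intervals`, `odd_classify`,
  `censor_quarter`, `eligible`) define the semantics; vectorized
  numpy/numba bulk paths reproduce them for population-scale runs, and the
  test suite asserts scalar/bulk agreement.
- Dates are handled as numpy `datetime64[D]` day offsets internally;
  tables carry pandas datetimes, CSVs ISO-8601 strings.
- The end-to-end recovery study uses 100 seeds × 50 000 patients with the
  statin trajectory (60, 0.2, 0, −0.12); binomial sampling around the
  trajectory makes the quarterly-rate errors independent, so iid OLS
  standard errors are correctly calibrated there (95 % CI coverage ≈ 0.95).
  Unit tests use 800–20 000 patients; the ITS sampling-distribution check
  uses 1 000 direct replicates at σ = 0.5.
- The quarterly calibration check accepts up to 5 % of quarters beyond 3
  binomial SEs across seeds: with 28 quarters per run, a single 3.1-SE
  excursion is expected binomial variation, not miscalibration.

## Known limitations

- Virtual enrollment is an input attribute on enrollment spells, not
  derived from billing-majority attribution.
- The bulk eligibility path folds spell gaps into monotone censoring
  (once uncovered, censored for good); a patient with a coverage gap who
  re-enrolls later is treated as censored at the gap, consistent with the
  monotone-exit reading of the censoring rules.
- PPI comparison is side-by-side only; no formal difference-in-differences
  and no ARIMA/seasonal modelling.
- Income, rurality, and proprietary comorbidity groupers are out of scope;
  the characteristics table reports only the computable subset (size, age,
  sex, AMI history, enrollment split).
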