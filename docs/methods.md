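# Methods

This note documents the models, rules and numerical choices behind
`inhalerswitch`. The package evaluates a health-system formulary switch from
a budesonide-formoterol metered-dose inhaler (MDI) to a
fluticasone-salmeterol dry-powder inhaler (DPI) on claims-shaped data, with
two complementary designs: a primary self-controlled case series (SCCS) and
a secondary coarsened-exact-matched (CEM) cohort analysis. A seeded
synthetic claims generator with known ground truth makes every stage
testable without access to protected records.

## Time grain and intervals

All dates are whole days; intervals are half-open `[start, end)` so that
lengths tile without double counting. A year is 365.25 days; 5-year age
bands therefore change every 1826.25 days, and band boundaries are kept
exact by working in quarter-days internally. Calendar quarters are the
usual Q1–Q4.

## Exposure episodes from pharmacy fills

A fill of `days_supply` days covers `ceil(days_supply * (1 + g))` days from
its fill date, where the grace fraction `g` represents imperfect adherence:
`g = 0` (used as prescribed; a 30-day supply covers 30 days), `g = 1/3`
(used 75% of the time; 40 days), `g = 1` (used half the time; 60 days). The
primary analysis uses `g = 1/3`; 0 and 1 are sensitivity variants.

Where the two named controller classes compete, the **later-starting fill
wins from its start date**: each day's state is the product of the most
recent fill at or before it, provided the day lies within that fill's
graced coverage; otherwise the day is `neither`. A switch therefore
truncates the prior fill's remaining coverage, and the truncated state does
not resume unless a new fill of that class appears. On an exact start-date
tie the switch target (DPI) wins. This rule is applied at fill granularity
rather than to merged coverage intervals: at fill granularity each day's
exposed status is monotone non-decreasing in `g` (a useful sanity
invariant), whereas the merged-interval variant is not — merging two MDI
fills can hide the later fill's restart and hand time to an intervening DPI
interval as `g` grows. `coverage_from_fills` still reports merged maximal
coverage intervals per class, which is the natural unit for coverage
summaries.

Each patient's observation window is `[first controller fill,
min(death date + 1 day, study end + 1 day))`; exposure inference is
undefined before the first fill. Fills of other controllers map to
`neither` — the estimand contrasts only the two named therapies. The SCCS
cohort comprises patients with at least one MDI fill before the formulary
window opens and at least one DPI fill on or after it. The gap-exclusion
sensitivity drops patients with a `neither` spell longer than 91 days (a
fixed-day reading of "3 months") strictly between two exposed spells.

## Cause classification and count outcomes

Respiratory causes are assigned by prefix matching of the principal ICD-10
code with dots ignored: COPD `J41*–J44*`, asthma `J45*, J46*`, pneumonia
`J09.X1, J10*–J18*, A01.03, A02.22, A37.01/.11/.81/.91, A54.84, B01.2,
B05.2, B06.81, B77.81, J85.1, J22*`. The pneumonia list is checked first,
then COPD, then asthma; no printed code collides, so the precedence only
guards malformed input. "Respiratory-related" means a COPD or asthma
principal diagnosis; pneumonia is its own family.

Nebulized albuterol is standardized to inhaler equivalents: an albuterol
MDI fill is one equivalent; nebulized doses are divided by a configurable
doses-per-inhaler factor (default 100, exposed in `SCCSDesign`), summed per
person-time interval, and rounded half up. Prednisone is counted as
discrete prescription fills. Both fill outcomes are analyzed as recurrent
events in the same SCCS machinery, with fill dates as event dates.

## The within-person model

Person-time is segmented at every exposure boundary, calendar-quarter
boundary, 5-year age-band crossing and region move, producing intervals
with constant covariates; events are assigned to the interval containing
their date, and intervals tile each observation window exactly.

For patient *i* with intervals *j* of length *t_ij*, covariates *x_ij* and
event counts *y_ij* ~ Poisson(*t_ij* exp(*α_i* + *x_ij'β*)), conditioning
on the patient total *Σ_j y_ij* eliminates *α_i* and yields the per-patient
multinomial likelihood

    l(β) = Σ_i Σ_j y_ij log p_ij,
    p_ij = t_ij exp(x_ij'β) / Σ_k t_ik exp(x_ik'β).

Only patients with ≥1 event and ≥2 intervals contribute. The covariates are
exposure level (MDI reference; `neither` time is retained as a third level
with its own coefficient, since discarding it would distort the
within-person totals), 5-year age band, calendar quarter, region, and
quarter-by-region dummies. The reported estimand is exp(β) for the DPI
level: the DPI-vs-MDI incidence rate ratio (IRR).

Numerics: Newton–Raphson with step-halving; convergence when the gradient's
max-norm falls below `1e-8 × max(1, total events)` (the relative form keeps
the criterion meaningful when the log-likelihood aggregates tens of
thousands of events and float64 summation noise exceeds an absolute 1e-8).
Standard errors come from the observed information; 95% intervals are
Wald, `exp(β ± 1.96·se)`, with no small-sample correction.

Identifiability is handled deterministically, first-kept in input order:

- Columns with no within-patient variation after centering (e.g. sex, or
  any patient-constant covariate) and columns collinear within-patient
  with earlier ones are dropped via sequential Gram–Schmidt on the
  within-patient-demeaned design, and logged.
- A dummy level whose on-level (or off-level) event count is zero *among
  the patients for whom the level varies within-patient* has an infinite
  MLE. The fitter applies the exact limiting MLE: the losing side's rows —
  which are necessarily event-free — are excluded from the affected
  patients' multinomial denominators, and the column is removed; the
  screen iterates to a fixed point, and exclusions are logged. (Merely
  dropping the column would pool the level's person-time into the
  reference level and misattribute its rate — person-time in extreme age
  bands correlates with calendar period and hence with exposure, so that
  approximation measurably biases the exposure IRR.) Exposure levels in
  this situation are instead flagged **non-estimable** and reported as
  missing rather than as a huge finite number.
- Joint flat directions a per-column screen cannot see (e.g. two adjacent
  event-free age bands) are detected after fitting when a nuisance
  estimate escapes |β| > 10 or se > 50 — bounds no real covariate effect
  approaches — and resolved by the same event-free row exclusion,
  followed by a refit.
- The age-band dummy reference is the band with the most events, so sparse
  outcomes are not contrasted against an event-free reference band.

The Hochberg step-up adjustment over the eight primary outcomes controls
the family-wise error rate: with ascending p(1..m), adjusted(m) = p(m) and
adjusted(i) = min(adjusted(i+1), (m−i+1)·p(i)), capped at 1.

Sensitivity variants: grace ∈ {0, 1/3, 1}; gap exclusion; removal of
pneumonia ED visits 0–3 days (configurable) before a pneumonia
hospitalization of the same patient (the visit that led to the admission);
stratification by patients with exactly one vs two or more events of the
outcome. Subgroups: sex, COPD, asthma, smoking status, combat-veteran
status, and any rescue-medication use / ED visit / hospitalization in the
365 days before the patient's first DPI fill.

## The matched cohort model

Arms are fixed at enrollment after the formulary window opens: patients
with any post-window DPI fill are `switched` (enrolled at the first such
fill); patients with post-window controller fills but no DPI fill are
`not_switched` (enrolled at their first post-window controller fill).
Baseline covariates are measured over the 365 days before enrollment: age,
sex, COPD, asthma, prior-year ED visit, prior-year hospitalization,
prior-year albuterol fill count, prior-year prednisone use, smoking
status, region.

CEM: patients are grouped by the coarsened covariate signature (age in
10-year bins, albuterol fills binned {0, 1–3, 4–6, ≥7}, other covariates
as-is; bins configurable). Strata lacking either arm are discarded with
logged counts. Switched patients keep weight 1; a control in stratum *s*
gets `(m_Ts/m_Cs) · (m_C/m_T)`, so weighted controls reproduce the
switched arm's stratum distribution and the weighted control total equals
the matched control count. Balance is checked with standardized mean
differences: weighted arm means divided by the unweighted pooled SD
`sqrt((s_T² + s_C²)/2)`; categorical covariates expand to level indicators
and report the maximum |SMD|.

Outcomes over `[enrollment, enrollment + horizon)` for horizons of 90 and
180 days: any-event binaries for ED visits and hospitalizations (all-cause,
respiratory, pneumonia), mortality as death within the horizon, and
albuterol-equivalent and prednisone fill counts. Patients whose horizon
extends past the study end are excluded (their outcomes are not fully
observable); patients dying before the horizon still contribute event
outcomes (intention-to-follow), with mortality reported separately.

Estimation: weighted logistic (binary) or Poisson (count) regression on
arm plus the ten covariates, via statsmodels GLM with frequency weights.
Predictive margins average the model predictions with the arm set
uniformly to each value over all weighted patients; the adjusted absolute
difference is exactly the margin difference; the ratio measure is the
exponentiated arm coefficient (odds ratio or rate ratio). Confidence
intervals use the delta method on the coefficient covariance — chosen over
the bootstrap for determinism. Binary margins are reported in percent. A
weights-only variant (no covariate adjustment) is available. Outcomes with
no events in the weighted sample are flagged non-estimable rather than
fitted.

## The synthetic cohort generator

The generator emulates the study setting: a five-year window (2018-01-01
to 2022-12-31) around a formulary switch window (2021-07-01 to
2021-09-30); an older, predominantly male population with COPD and/or
asthma, smoking history, and a South-weighted region mix; controller fills
every 30 days with a configurable per-refill gap process (probability 0.2,
geometric gaps of mean 21 days); a configurable fraction of switchers
(default 0.65) whose fills change from MDI to DPI at a switch date drawn
uniformly in the window; region moves only at quarter boundaries;
exponential mortality (default 0.035/person-year) that censors both fills
and events.

Outcome event streams are simulated per day as Poisson counts of the daily
rate — exact for piecewise-constant rates at day resolution —

    log rate(day) = log(baseline/365.25) + log IRR · 1[DPI-exposed]
                    + age-band slope + seasonal quarter term
                    + region offset + quarter-by-region term,

with defaults: age slope 0.03 per 5-year band around band 13 (ages 65–70),
seasonal amplitude 0.2 (peak Q1), region offsets {0, −0.1, +0.1, +0.2},
interaction amplitude 0.05 with a region-dependent phase. Streams are
cause-specific — ED and hospitalization each split into respiratory,
pneumonia and other causes, plus albuterol and prednisone fill streams —
so ICD-10 classification round-trips; an all-cause IRR is the rate-weighted
mixture of its components and cannot be set independently, which is why
the config is keyed by stream rather than by the eight analysis outcomes.
Default true IRRs are the headline values of the study setting (0.90
albuterol, 1.02 prednisone, 1.06/1.25 respiratory/pneumonia ED, 1.10/1.24
respiratory/pneumonia hospitalization, 1.04/1.06 for the other-cause
streams so the implied all-cause mixtures land near 1.05/1.08). Default
baseline rates (events/person-year, MDI reference): albuterol 6.0,
prednisone 0.8, ED 0.25/0.12/0.02 (other/respiratory/pneumonia),
hospitalization 0.22/0.05/0.05. The pneumonia-hospitalization rate of
0.05/person-year is the stated desk-scale simulation condition; scaled to
n≈2,000 patients it keeps the events-per-parameter ratio of the
conditional model near 8–9, where maximum-likelihood asymptotics are
serviceable but a small upward bias of the exposure log-IRR (a few
hundredths, vanishing by n≈8,000) remains visible in recovery studies —
the inherent sparse-data behaviour of ML with many correlated nuisance
dummies, not a pipeline defect. Ratio-parameter recovery is therefore
assessed on the log scale throughout the test suite, where the estimator
is additive and the mean is not additionally inflated by convexity.

The generator's ground-truth exposure is the grace-1/3 fill coverage with
switch truncation — the same rule as the primary analysis — so primary
parameter-recovery is free of exposure misclassification; grace-0/100
analyses see misclassification by construction, mirroring the sensitivity
design. `neither` time carries the baseline (MDI) rate. Nebulized
albuterol dispensings (10% of albuterol events) carry a constant 100
doses, a deliberate simplification that makes one dispensing one inhaler
equivalent.

What the generator does not emulate: real claim-record layouts,
overdispersed or self-exciting event processes, exposure-dependent
mortality, care-seeking disruptions (e.g. pandemic effects), FEV1, costs.
Passing recovery tests therefore demonstrates the estimators are correct
under the assumed piecewise-Poisson world, not that the design is robust
to violations the original study discusses (event-dependent observation,
residual temporal confounding).

## Emissions accounting

Per patient and calendar year, emissions are the sum over dispensed
products of a per-device kg CO2e factor. The default table (MDI 28 kg,
DPI and other controllers 1 kg, nebulized albuterol and prednisone 0) is
an order-of-magnitude, literature-typical placeholder, exposed as config;
cohort-level means divide by the full cohort size each year.

## Problem sizes used in the test suite

The suite exercises the pipeline at sizes a laptop handles comfortably:
unit fixtures of 1–4 patients with closed-form answers; 500–600-patient
cohorts for invariants and suite smoke tests; a 3,000-patient single-seed
recovery check; 100 seeds of 2,000 patients for the IRR-1.24 recovery and
coverage study; and 400 null cohorts of 300 patients for the type-I-error
study. These sizes were chosen so that Monte-Carlo error, not runtime,
is the binding constraint on each check.

## Known limitations

- No correction for event-dependent observation (death truncation) in the
  SCCS; deaths are independent of events in the generator, so recovery
  tests cannot detect the bias such dependence would cause on real data.
- Wald inference throughout; no overdispersion or robust-variance options.
- Quarter dummies capture seasonality only at quarter resolution.
- CEM with ten covariates produces many singleton strata at desk scale;
  matched fractions are small in toy cohorts (they are not at the scale
  the design targets), and sparse binary outcomes can be quasi-separated
  in the weighted GLMs, which statsmodels reports as warnings.
- The cohort analysis excludes late enrollees whose horizon is not fully
  observable instead of censoring them.
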