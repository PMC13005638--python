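# Methods

This note records the models the package implements, the defaults it ships,
and the reasoning behind the choices that were genuinely open.

## Data model

A cohort is four linked tables (patients, dispensings, diagnoses,
encounters) keyed by an opaque `patient_id`, exchanged as UTF-8 CSVs with
ISO-8601 dates.  Coding systems are abstracted into a small semantic
vocabulary (`"asthma"`, `"mepolizumab"`, `"ocs"`, …); a YAML code map can
translate real code systems into it.  Dates are converted to integer day
offsets from each patient's index date (day 0 = first-ever biologic
dispensing) as soon as a cohort is selected, because every adherence
threshold is expressed in days.  Currency is JPY throughout; no conversion
is attempted.

## Cohort selection

Eligibility applies, in a fixed order so the attrition table is
reproducible: biologic initiation → age ≥ 18 at index → asthma diagnosis
before index → a single biologic on the index date → ≥ 30 days of
enrollment pre-index → ≥ 365 days post-index → no biologic before the index
→ ICS and LABA dispensed within 90 days up to the latest asthma diagnosis
on or before the index (a fixed-dose combination satisfies both) → the
exclusion-diagnosis list, where some conditions apply only to particular
index biologics and two (hypereosinophilic syndrome, EGPA) disqualify up to
the end of follow-up.  "Continuous enrollment" is operationalized as
`enrollment_start ≤ index − 30` and `enrollment_end ≥ index + 365`, since
the schema carries no enrollment gaps.  A *switcher* is a patient with a
different biologic dispensed in the open interval (index, index + 365); the
trajectory analysis runs on non-switchers.

## Adherence engine

**Regimens.** Expected intervals: dupilumab 14 days; mepolizumab and
tezepelumab 28; benralizumab 28/28 then 56; omalizumab 14 or 28.  Because
claims carry neither weight nor IgE, the omalizumab mode is inferred from
the realized gaps: Q2W when the median inter-dose gap is below 21 days (the
midpoint of the two cycles), Q4W otherwise; a single dose defaults to Q4W.

**Schedule tracking.** The expected date of dose *k+1* is the actual date
of dose *k* plus the phase interval ("dynamic reset"); a dose is on
schedule when within ±`buffer_days` (default 7) of expectation.  Duplicate
dose dates collapse to one dose with a warning.

**Possession and MPR.** Dose *k* possesses `[date, date + phase interval)`;
intervals are unioned, clipped to `[0, 365)`, and MPR is the covered
fraction.  The scheduled interval is the natural supply proxy for
single-administration injectables and yields MPR = 1 for complete dosing on
every regimen (note that "complete" four-weekly dosing over 365 days means
14 doses — 13 doses possess 364 of 365 days).

**Categories.** Discontinuation is evaluated first: the terminal gap from
the last dose to day 365 reaching the phase's discontinuation limit
(benralizumab 112/140/168 days after doses 1/2/≥3; 42 days for Q2W drugs;
84 for Q4W drugs).  Otherwise a gap opened by dose *k* is *prolonged* when
it reaches that phase's window (benralizumab 56/84/112; Q2W 28; Q4W 56 —
each two full cycles, so the ±7-day buffer is *not* added on top: the
window already embodies one wholly missed cycle).  Adherent = no prolonged
gap and at least the minimum dose count (13 for Q2W drugs, 7 for Q4W, >4
for benralizumab); minimally adherent = a prolonged gap with at most
minimum−1 doses; partially adherent = the remaining two combinations.  The
four categories partition every dosed patient.

**Binary series.** Follow-up is split into 13 bins of 28 days (the final
day is ignored); bin *t* is adherent when *strictly more than half* its
days are possession-covered.  A full-coverage rule is available in config
but is not the default for two reasons: (i) buffer-compliant dosing slips
of up to 7 days open possession slivers that would zero bins behind a
perfectly on-schedule patient, and (ii) a skipped dose leaves partial
carry-over coverage in its bin, which a strict rule misattributes.  The
majority rule makes the series read "on treatment for most of this 4-week
period", which is the construct the trajectory model consumes.

**Trajectory response.** `series_matrix` drops the first bin by default:
the index dose is taken by definition, so bin 1 is structurally adherent
for every patient.  A constant column carries no clustering information but
badly distorts polynomial-logit class curves (no polynomial can follow a
jump from 1 to a low plateau), and empirically inflates BIC model-size
selection.  The engine's `adherence_series` itself still returns all 13
bins.

## Trajectory model

A K-class Bernoulli mixture with class curves
`logit p_kt = polynomial(β_k, t)`, *t* standardized to [−1, 1], degree 2 by
default.  Fitting is EM:

* E-step: exact posterior responsibilities via log-sum-exp; class
  log-probabilities use the softplus form (`log p = −softplus(−η)`), which
  is exact for extreme logits so no probability clipping is needed.
* M-step: class weights in closed form; each class's polynomial by
  Newton–Raphson on the T aggregated bins (sufficient statistics:
  responsibility-weighted successes and totals per bin), with step-halving
  so every update is an ascent step — this is what guarantees the monotone
  observed-data log-likelihood the tests assert at 10⁻⁸.
* Restarts: default 10 — one k-means initialization on the raw series rows
  plus random Dirichlet responsibilities; the best final log-likelihood
  wins.  A fixed seed makes the whole fit reproducible.

Model size is chosen by BIC = −2·loglik + p·log N over K ∈ 2–9, restricted
to fits whose smallest class holds at least 2% of patients (≈ 50 patients
at the cohort sizes of interest, the usual floor for interpretable
trajectory classes).  Degenerate fits are flagged, excluded from selection,
and only returned (with a warning) if nothing admissible exists.  Classes
are labeled A, B, C, … by strictly descending class-mean MPR, ties broken
by larger class then original index.

## Synthetic cohort generator

The generator produces claims bundles with the structure the analysis
assumes; it is the package's test bed, not a calibrated surrogate for any
real database.

* **Biologic mix** follows the relative initiator shares of a large
  Japanese severe-asthma cohort (≈ 38/29/14/13/5% for
  benralizumab/mepolizumab/dupilumab/omalizumab/tezepelumab); omalizumab
  patients are silently Q2W or Q4W (50/50), forcing the inference path.
* **Adherence archetypes.** Seven canonical 12-month trajectories —
  sustained adherence, a brief early U-shaped lapse, a longer late U,
  a late stopper, cyclic on/off ("intermittent") use, a delayed stopper,
  and near-immediate drop-off — with mixture weights ≈
  39/7/13/9/6/13/13% and implied mean MPRs descending from ~0.93 to ~0.08.
  Each patient draws one latent on/off state per 28-day window from the
  archetype's curve; curves are crisp steps (on-probability 0.995, off
  0.002) whose transitions sit on 8-week boundaries, so a lapse window
  corresponds to whole skipped doses on every regimen.
* **Dose realization.** Dose slots live on the protocol calendar
  (accumulated expected intervals from day 0); a slot due in an "on" window
  is dispensed at its protocol date plus a uniform ±7-day jitter, slots in
  "off" windows are skipped.  Design-time calibration showed two failure
  modes of softer alternatives: diffuse per-dose thinning makes the realized
  series distribution depend on the regimen's cycle length (classes
  fragment by biologic), and re-anchoring the realization at each jittered
  dose lets slips accumulate into a ±2-week random-walk drift that
  manufactures spurious "shifted-lapse" subpopulations.  Either effect
  creates within-class dependence that pushes BIC past the planted class
  count; the crisp, protocol-anchored design keeps the seven classes
  identifiable while the jitter still exercises the engine's buffer logic.
* **Outcomes and costs.** Asthma-related admissions, ED visits and OCS
  courses are inhomogeneous Poisson streams whose rate is the baseline
  (0.04 / 0.08 / 0.30 events per patient-year) times the adherence rate
  ratio (default 2.0) during possession-uncovered time; non-asthma
  admissions/ED visits run at adherence-independent baselines.  Every
  patient gets monthly ICS/LABA refills (¥8,000, each with an outpatient
  asthma diagnosis), biologic dose lines at realistic per-product prices
  (¥45k–350k), and event-linked pharmacy lines (admission ¥30k, ED ¥5k,
  OCS course ¥2k plus ¥12k of acute pharmacotherapy).  This reproduces, as
  a qualitative property, the reversal of the cost ordering when biologic
  acquisition costs are excluded.
* **What it does not emulate:** enrollment gaps, dose-strength titration,
  mid-year archetype changes, covariate-dependent adherence, regional price
  variation, or any empirical marginal distribution of a real claims
  source.  Passing tests therefore demonstrate that the *machinery* is
  correct under the stated generative assumptions, not that real data would
  yield the same clusters or effect sizes.

A packaged `gbtm_recovery_config` (N=2500, switching and exclusion
injections off) realizes the non-switcher trajectory analysis set directly;
the plain default config keeps a 12.84% switch share and is used for
switch-detection and attrition tests.

## Outcomes

Exacerbations: asthma-related admissions; asthma-related ED visits; OCS
dispensings of 3–28 supplied days in the calendar month of, or the month
before, an asthma diagnosis, plus IV steroids in, or at most one month
before, a diagnosis month (calendar months, matching monthly claims
billing; an unbounded "prior" look-back would be clinically implausible).
Same-type events closer than 7 days merge.  Whether an ED visit on an
admission day also counts is configurable (both counted by default).

HCRU: admission and ED counts with starts inside the follow-up window;
hospital days count both endpoints (`end − start + 1`) truncated at the
follow-up boundary.  Pharmacy costs sum dispensing lines in the window; a
line is asthma-attributed when an asthma diagnosis falls in its calendar
month or the line falls inside an asthma-flagged admission.  Steroid
exposure converts compound mass to prednisone equivalents (prednisolone
×1, methylprednisolone ×1.25, hydrocortisone ×0.25, dexamethasone ×6.67);
the daily average divides by distinct exposed days only.

## Association models

Follow-up is partitioned into maximal possession-covered ("adherent") and
uncovered ("non-adherent") periods; person-days sum to exactly 365 per
patient, and events join the period containing their day.  The count model
is `count ~ adherence_state` with a log person-days offset and a normal
patient random intercept, fitted by adaptive Gauss–Hermite quadrature
maximum likelihood (15 nodes by default; per-patient Laplace modes center
the nodes).  The rate ratio is `exp(state coefficient)`, Wald inference
from a finite-difference Hessian.  Overdispersion is assessed by a Pearson
χ²/df on empirical-Bayes conditional means whose denominator subtracts the
effective degrees of freedom absorbed by the random intercepts (shrinkage
weights, Hodges–Sargent style) — without that correction the statistic
sits well below 1 even under a correctly specified Poisson model.  Above
the threshold (default 1.5) the response switches to negative binomial
(gamma-mixed), adding a log-dispersion parameter to the same quadrature
machinery.  Period costs use a REML linear mixed model with a
fixed-effects-only OLS fallback when the mixed fit is singular.  No
multiple-testing adjustment is applied by default, matching the
descriptive framing; group comparisons gate ANOVA behind per-group Shapiro
tests (α = 0.05) and otherwise use Kruskal–Wallis, and standardized mean
differences use the pooled-SD form for numeric covariates and the
Mahalanobis multinomial form (max pairwise across >2 groups) for
categorical ones.

## Numerical and testing notes

Problem sizes were chosen so the full suite runs on one CPU in a few
minutes: the rule-engine cross-check enumerates all dose sequences on a
7-day grid up to 6 doses (≈2.9M per regimen, vectorized on padded gap
matrices) plus 10⁴ randomized sequences up to 27 doses per regimen against
an independently written transcription of the categorization rules; the
trajectory recovery benchmark uses the packaged N=2500 cohort; count-model
bias is estimated at n=2000 patients for true rate ratios 1.5/2/3, and
type-I error over 400 null replicates at n=120.  Known limitations: the
benralizumab 56-day maintenance cycle makes any 28-day binary series
pairwise-correlated within patients, which is why diffuse generative
archetypes are not identifiable by BIC (see above); the trajectory model
assumes conditional independence across bins and will over-select classes
on data with strong residual serial dependence; and the quadrature GLMM
assumes a lognormal frailty, so patient-level gamma heterogeneity is
absorbed rather than flagged as overdispersion (period-level extra
variance is what the dispersion switch detects).
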