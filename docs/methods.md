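# Methods

`coxcut` implements a comparative-effectiveness workflow for administrative
claims: a new-user, active-comparator cohort of fibrate vs statin
monotherapy initiators among high-cardiovascular-risk diabetic patients,
followed by survival modelling in which the treatment hazard ratio is
allowed to change at a data-selected cut-off time.  Because the national
claims databases this design targets are access-restricted, the package
ships a synthetic claims generator with known ground truth; every
statistical stage is exercised and validated against that truth.

## Study clock and cohort design

Time is integer days from a study epoch (day 0 = opening of the inclusion
window).  Defaults: an 18-month index window (days 0–548), administrative
end of follow-up at day 913 (~30 months), a 30-month (913-day) washout,
and "one year" = 365 days.  A subject initiates monotherapy at the first
run of ≥2 reimbursements of the same lipid-lowering class prescribed by a
GP inside the index window, with no lipid-lowering reimbursement of either
class in the washout.  The two reimbursements must fall within 120 days of
each other with no intervening reimbursement of the other class — the
source design does not bound the spacing, and 120 days is a generous upper
bound on a dispensing interval (configurable).  Subjects with both classes
reimbursed on the index day are combination users and are dropped.

Inclusion then requires, in this fixed order (each step logged for the
flow chart): treated diabetes and treated hypertension (≥3 reimbursements
of the defining class within some rolling 365-day window of the washout —
a rolling window, not a calendar year), the sex-specific age thresholds
(≥50 for men, ≥60 for women, boundary inclusive), and no cardiovascular
hospitalization in the washout.

The composite outcome is the first of all-cause death, ischemic stroke,
myocardial infarction, or above-ankle amputation; follow-up ends at the
first event or the administrative end (intention-to-treat).  Follow-up
stops at the first event even when the event is non-fatal; later records
are ignored.  An event on the index day is given one day of follow-up so
the subject contributes positive risk time.  Two sensitivity regimes
truncate follow-up: *persistence* at (last index-drug reimbursement +
183 days) when a ≥183-day reimbursement gap opens, and *switch* at (first
other-class reimbursement + 183 days).  "Six months" = 183 days,
configurable.  An amputation-excluded endpoint variant recomputes the
first occurrence over {death, stroke, MI}.

## Survival machinery

Analysis rows are expanded into counting-process rows (start, stop] with
interval copies X_k(t) of the treatment variable: X_k equals the subject's
arm indicator inside interval P_k and 0 elsewhere, so each interval gets
its own log hazard ratio while all other covariates keep constant
coefficients.

The Cox partial likelihood is maximized by Newton–Raphson with
step-halving on overshoot; convergence when the log-likelihood improves by
< 1e-8 (max 100 iterations).  Ties: Efron by default (day-granular claims
data produce many ties), Breslow available for oracle cross-checks.  Risk
sets are left-open/right-closed: a row is at risk at event time t iff
start < t ≤ stop.  Standard errors come from the inverse observed
information; fits can carry case weights, and weighted fits use a sandwich
(infinitesimal-jackknife) variance grouped by subject — exact under
Breslow ties, a Breslow-score approximation under Efron, which is why the
IPW fit defaults to Breslow.  Monotone likelihoods (separation) are
detected by coefficient escape (|β| > 20) and flagged rather than raised.
The implementation is validated against lifelines'
`CoxTimeVaryingFitter` (agreement ~1e-6) and against exhaustive grid
maximization on a six-subject fixture.

Proportional hazards is assessed with a score test on scaled Schoenfeld
residuals against event time (identity transform, averaged-information
approximation, as in the classic `cox.zph`); a covariate is flagged
"violated" at p < 0.05.  Empirical type-I error is 0.05 under
proportional-hazards simulation.  Kaplan–Meier curves (via lifelines) are
produced for visual inspection, but pipeline decisions use the test.

## Change-point selection

Candidates are cut-off vectors at multiples of a nominal 30-day month
(calendar months are ill-defined relative to subject-level index dates);
all month marks strictly inside the observed follow-up enter the grid, and
candidates leaving fewer than 5 events per interval per arm are flagged
infeasible and carry no likelihood.  For each feasible candidate a
univariate Cox model with interval-specific treatment coefficients is
fitted and its maximized log partial likelihood recorded.  Because the
split variable is one binary covariate whose interval copies never overlap
in time, the partial likelihood factorizes over intervals and each
coefficient is a one-dimensional concave maximization over per-day event
and at-risk counts by arm; this factorized path is exact (tests verify
equality with the general fitter to ~1e-6) and makes the bootstrap cheap.

Robustness to the realized event times comes from B = 500 bootstrap
resamples drawn with replacement, stratified by arm so every resample
keeps the exact per-arm counts.  One set of resamples is shared across
candidates, so candidate likelihoods within a resample are computed on the
same event set and are directly comparable.  The selected cut-off
maximizes the median of the B log-likelihoods among candidates whose
per-interval proportional-hazards test passes on the original cohort (not
on resamples — the sequencing is ambiguous in the source design, so the
cheaper and less noisy choice is made and is configurable in principle);
intervals with too few events to test cannot evidence a violation and do
not block selection.  Ties in the median break toward the earliest
cut-off.  Three-interval candidates are searched only when no two-interval
candidate passes; if nothing passes, the best two-interval candidate is
returned with an explicit "no PH-satisfying candidate" verdict.

## Estimation

*Adjusted rates.*  Annual event rates are events per 100 person-years of
first-event follow-up (the source reports percent-scale rates without
defining the denominator).  Stratum-specific rates over age-band × sex
strata (bands 50–59, 60–69, 70–79, ≥80) are combined with the stratum's
total person-years as Mantel–Haenszel-style weights, standardizing both
arms to the same stratum structure; CIs use a normal approximation on the
log rate and the comparison p-value a normal approximation on the
weighted rate difference.

*Screening.*  Each candidate confounder is screened in a Cox model with
continuous age and sex; it enters the final model when its adjusted HR is
significant at 0.05, it has no missing data, and it is on a configured
clinically-eligible allow-list (clinical judgment is not computable; the
default list is insulin, clopidogrel, Alzheimer's disease, cancer,
depression, Parkinson's disease, prior hospitalization).  P-values are
two-sided throughout, with no multiplicity adjustment.

*Final models.*  Three nested Cox models all include the treatment
variable split at the selected cut-off: (1) crude, (2) age and sex,
(3) age, sex, and the screened covariates.  Nesting is verified via the
log-likelihood ordering.

*IPW sensitivity analysis.*  A logistic model of the arm on the same
covariates gives each subject a weight 1/P(arm received | covariates),
optionally stabilized by the marginal arm probability; subjects with
estimated probability outside [0.01, 0.99] are flagged and weights can be
truncated at a percentile.  Weights enter the split Cox fit as case
weights with robust variance.  This is standard IPW practice; describing
the weight as a model covariate (as the source text does) contradicts the
estimator it cites, so weighting is implemented.  Balance is reported as
absolute standardized mean differences before/after weighting.

## Synthetic claims generator

The generator emulates: demographics with the documented age-band and sex
structure (women only above 60, reflecting the sex-specific inclusion
thresholds); baseline comedication, comorbidity and diabetes-duration
marginals typical of this cohort; deprivation quintile missing completely
at random at 9% (the real missingness mechanism is unreported); confounded
treatment choice via a logistic model whose coefficients reproduce the
documented channeling pattern (fibrate users younger, more often women and
depressed, less insulin/metformin/antiplatelet-exposed) with the intercept
root-found so the expected fibrate share hits the 12.8% target; and
outcomes from a piecewise-exponential law with hazard
λ(t) = λ₀·exp(Σ covariate effects + treatment log HR in force at t),
inverted in closed form from a unit-exponential draw.  Covariate log
hazards default to the published age/sex-adjusted estimates (age 1.07/yr,
male 1.61, insulin 1.65, depression 1.42, Alzheimer 2.46, cancer 2.29,
Parkinson 2.67, clopidogrel 1.44, calcium-channel blocker 1.14,
hospitalization 1.17, long diabetes duration 1.20/1.52).  λ₀ = 2.0e-5 per
person-day is calibrated once so the overall annual event rate is ≈2.2%
per year under the default covariate mix, matching the reported rates; the
default treatment schedule is log HR = log 0.95 on [0, 540) and log 1.73 on
[540, ∞), the published two-period point estimates.  The propensity
coefficient magnitudes are set so the crude-vs-adjusted HR gap is ~5%,
matching the gap between the published crude and fully adjusted models.

The claims stream materializes this truth: two GP index reimbursements 30
days apart, monthly refills with 92% monthly persistence, a 5% switch
fraction among fibrate users, ≥3 disease-defining reimbursements within a
one-year span of the lookback, comedication records consistent with the
covariate flags, and outcome records (death or cardiovascular
hospitalization).  A configurable 8% of subjects violate exactly one rule
(prior lipid drug — planted as the opposite class so it cannot merge into
the index run; prior cardiovascular event; age/sex threshold; single
reimbursement; non-GP prescriber), giving the cohort builder designed
exclusions to recover.  Random loss to follow-up is off by default (no
rate is reported for the real cohort); an exponential censoring rate is
available.

What the generator does **not** emulate: real ICD-10/ATC coding, calendar
seasonality, within-class molecule choice, informative censoring,
correlation between covariates beyond the age–sex structure, and
measurement error in claims.  Passing tests therefore demonstrate that
the pipeline recovers known truth from claims-shaped data of realistic
size and sparsity — not that it is robust to real-world coding noise.

Diabetes-duration derivation from claims deserves a note: inside a
913-day lookback only durations up to ~2.5 years are observable, so the
builder assigns "<2 years" when the first oral-antidiabetic record is
<730 days before index, "2–5 years" up to 30 days short of the lookback
edge, and "unknown (lookback-truncated)" beyond; the generator places
disease-onset records consistently with this rule.

## Problem sizes and statistical power

Tests run at reduced but statistically meaningful sizes chosen by the
package: the six-subject oracle fixture, cohorts of 2,000–6,000 for
calibration and invariance checks, and n = 20,000 with 20–50 replicates
for recovery simulations; the end-to-end reproduction script runs one full
cohort at the published scale (~31,650 included subjects, B = 500).

Two recovery suites are expected to fail at the defaults, and that is
informative rather than a defect: at the published event rate (~2.2% per
year) a cohort of 20,000 with 12.8% fibrate share yields roughly 30–45
fibrate-arm events after day 540, so SE(log HR_after) ≈ 0.16–0.19 and the
probability that a single replicate lands within ±0.25 of HR = 1.73 is
only ~55%; likewise the change point itself is weakly identified
(selection recovers day 540 ± 60 in about half of replicates, versus 6/6
within ±30 under a stronger generating contrast of HR 0.5 → 2.2).  The
bootstrap-median selection coincides with the observed-likelihood argmax
in almost every replicate, so the limitation is the information content of
~750 events, not the selection rule.

## Known limitations

- The two-period hazard-ratio structure is assumed piecewise-constant;
  smoothly time-varying effects are projected onto the nearest step.
- The per-interval PH constraint is checked on the original cohort only.
- The robust variance under Efron ties uses Breslow-form score residuals.
- The MH rate comparison uses a normal approximation; exact stratified
  rate tests are out of scope.
- No competing-risks treatment of death vs cardiovascular events, no
  frailty or stratified baselines, and no doubly-robust or matching
  estimators.
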