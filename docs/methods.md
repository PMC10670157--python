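# Methods

## Setting and estimand

A single-arm trial cohort (one treatment line per patient) is compared
with an external real-world control cohort in which each patient may
contribute several eligible lines of therapy (LOTs); the LOT is the
analysis unit and its start date the index date. The estimand is the
average treatment effect among the treated (ATT): the control cohort is
reweighted to the trial cohort's covariate distribution, so the
contrast answers "what would these trial patients have experienced
under physician's choice".

Endpoints: tumour response (at least partial response; LOTs with no
recorded response are excluded from response analyses only), and three
time-to-event outcomes measured in integer days from the index date —
progression-free survival (progression or death), time to next
treatment (next systemic therapy or death) and overall survival.
Month-scale summaries divide days by 30.4375; this constant is a
package convention, chosen so that conversions are exactly
reproducible.

## Propensity model and ATT weights

The propensity score is `PS(x) = P(trial | x)` from a main-effects
logistic regression on ECOG (0/1), number of prior lines (1/2/3+),
seven metastatic-site indicators and age category (<65, 65–75, ≥75);
reference levels are the first level of each factor. Fitting is Newton
IRLS (statsmodels) with tolerance 1e-10 and at most 100 iterations;
exact quasi-separation (a zero cell between a dummy and the cohort
label) is detected beforehand and reported as an error naming the
covariate level; an exactly singular design falls back to a tiny ridge
(1e-8) with a loud warning.

Trial records receive weight 1. Control records receive the odds weight
`PS/(1−PS)`, then all control weights are multiplied by
`n_control / Σ raw weights` so they sum to the original control sample
size; this renormalization preserves weight ratios and keeps weighted
analyses from overstating the information in the control arm. No
trimming is applied by default (none is part of the procedure being
implemented); min/max PS per cohort is reported as an overlap
diagnostic.

Balance is summarized by the standardized mean difference, computed as
trial minus (weighted) control difference in level proportions over the
pooled binomial standard deviation
`d = (p_T − p_C) / sqrt((p_T(1−p_T) + p_C(1−p_C))/2)`.
The direction convention (trial minus weighted control) is fixed by the
package. Three-level factors get per-level SMDs plus a non-negative
Mahalanobis-type summary over the non-reference level proportions with
the averaged multinomial covariance. A degenerate variance (both
proportions 0 or 1) yields SMD 0 when the proportions agree and an
infinite flag otherwise.

## Imputation of block-missing metastatic sites

Chart abstraction either records a line's metastatic work-up or none of
it, so the seven site fields are missing jointly ("block" missingness);
partial missingness is a validation error. For a missing block, the
nearest observed LOTs of the same patient (by line number, skipping
lines that are themselves missing) act as neighbours, per site:

* both neighbours observed, concordant → common value;
* both observed, discordant in either direction → presence imputed
  (conservative toward progression; the regression direction
  yes→no is treated identically, a deliberate choice since only the
  absence→presence case is canonical);
* only a prior LOT observed → last observation carried forward;
* only a subsequent LOT observed → value carried backward;
* no observed LOT → left missing and counted unimputable.

The procedure is idempotent, never alters observed values, and an audit
reports the per-rule counts. Eligibility is judged per LOT
independently (a later line can be eligible even if an earlier one
failed a criterion), except the trial-agent rule, which excludes every
line from the first agent-containing LOT onward.

## Outcome models

* **Response**: odds ratio from (weighted) logistic regression of
  responder on treatment (plus all covariates in the multivariable
  variant); rate ratio from a log-link binomial GLM, with a
  robust-variance Poisson fallback when the log-binomial fit does not
  converge. The *unadjusted* contrast uses the classical Wald variance
  of the 2×2 table rather than a clustered one — the standard interval
  for a plain 2×2 — while all adjusted analyses use the
  patient-clustered sandwich. A zero cell raises an error pointing to the optional 0.5
  continuity correction, which is flagged in the output when used.
* **Kaplan–Meier**: weighted product-limit estimator (lifelines) with
  exponential-Greenwood log(−log) pointwise intervals; the median is
  the first time the curve reaches 0.5 and its CI is read off where the
  confidence bounds cross 0.5 (Brookmeyer–Crowley style). An
  all-censored input yields a flat curve and an explicit
  "median undefined" flag, not an exception; report tables print `NR`.
* **Cox PH**: weighted partial likelihood with the Efron tie correction
  (day-resolution data tie often). ATT analyses use the renormalized
  weights and a treatment term only; multivariable analyses use unit
  weights with treatment plus all covariates. Variance is the Lin–Wei
  robust sandwich aggregated over patients (CR0, no small-sample
  factor; a flag applies the CR1 G/(G−1) rescaling). Zero events in an
  arm raise a monotone-likelihood error naming the arm. Zero-day
  durations are set to 0.5 day before fitting, a half-day convention
  needed by the risk-set construction.
* All two-sided p-values are Wald tests of the log-scale estimate
  against zero; 95% CIs are `exp(log est ± 1.96·SE)`.

## Synthetic cohort generator

The generator emulates the study conditions: 114 trial patients, 38
control patients whose extra LOT count is Poisson(0.45) truncated at 3
(expected ≈ 55 control LOTs, ≈ 1.45 per patient); per-cohort baseline
category margins default to the two cohorts' published baseline tables.
Outcomes follow exponential proportional-hazards models — progression
and death hazards with configurable treatment log-HRs (defaults
ln 0.42 and ln 0.48) and covariate effects; baseline rates are matched
to control medians of 4.86 months (PFS) and 11.47 months (OS). PFS is
min(progression, death) and TTNT is min(progression + exponential
delay, death), so the ordering constraints hold by construction.
Response is Bernoulli from a logistic model (defaults matched to 16.7%
control and 36.8% trial response). A per-patient gamma frailty with
mean 1 and variance θ multiplies all of a patient's hazards; θ defaults
to 0.5, a free choice (no within-patient correlation magnitude is
published) that produces clearly positive but not degenerate
correlation. Censoring is the minimum of an exponential dropout time
(rate 0.0008/day) and an administrative cap (760 days, ≈ the trial's
25-month follow-up). Across a patient's lines, prior-lines increments
and a previously absent site appears with probability 0.10 per line
(sites never regress), keeping covariate paths monotone.

Metastasis blocks are masked MCAR with probability 9/55 on control
LOTs, but a mask is only applied while the patient retains at least one
observed line, so masked LOTs are always imputable unless unimputable
records are explicitly enabled. A deterministic fixture reproduces the
study's missingness layout exactly (9 masked LOTs from 8 patients: 3
both-neighbour — one discordant — 4 prior-only, 2 subsequent-only) and
the exact response counts (42/114; 9/45/1 of 55).

What the generator does **not** emulate: informative censoring,
time-varying covariates within a line, competing risks, site-level
(non-block) missingness, and any dependence of eligibility on
unmodelled criteria (lab values, washout windows). Passing tests
therefore validate the estimators under the stated generative
assumptions, not the clinical fidelity of any particular dataset.

## Verification strategy and problem sizes

Desk-scale facts are exact: the unadjusted response contrast from the
printed counts (OR 2.92, CI 1.30–6.56; RR 2.21, CI 1.16–4.20), weight
renormalization (Σ control weights = 55 ± 1e-9), and the imputation
audit (3/4/2/0, nothing left missing). Estimators are cross-checked
against independent brute-force oracles: logistic and Cox coefficients
against direct likelihood maximization on ≤8-record datasets (1e-4),
the naive Cox SE against a numerical second derivative, the weighted KM
against a hand-rolled product-limit loop and the closed-form
exponential median at n = 5000 (within 3%).

Statistical properties use simulation sizes chosen to keep Monte-Carlo
error well below the assertion margins: ATT-weighted Cox recovery of a
true HR of 0.42 over 40 replicates of ~1400 LOTs (>1000 events each,
both event components share the treatment HR so the composite
conditional HR is exactly 0.42 and non-collapsibility cannot bias the
check); type-I error of the patient-clustered Wald test over 1000 null
replicates with strong clustering (~4 correlated LOTs per control
patient, frailty variance 2), asserting the nominal-5% band [0.03,
0.07] for the robust test and demonstrable anti-conservatism of the
naive variance; and balance improvement (weighted max |SMD| below the
unadjusted max) in ≥90% of 60 fittable replicates at twice the study
scale, where quasi-separated draws — a real small-sample phenomenon on
the rarest site — are resampled because no propensity model can be fit
to them.

## Known limitations

* The adjusted (ATT and multivariable) study results are not
  reproducible from printed summaries alone, since they require the
  patient-level covariate–outcome joint distribution; the pipeline's
  correctness on that path is established by the oracle and recovery
  properties above instead.
* The log-binomial rate-ratio model is known to be fragile near fitted
  probabilities of 1; the robust-Poisson fallback changes the variance
  model slightly and is flagged in the output when used.
* CR0 clustered variances are mildly liberal with few clusters; CR1 is
  available but not the default, matching the reference analysis's
  unstated (and therefore presumed uncorrected) sandwich.
* The eligibility engine covers only the five rules representable in
  the schema; criteria requiring lab values or date windows are out of
  scope.
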