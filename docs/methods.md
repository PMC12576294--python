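# Methods

This note documents the statistical machinery in `ediirisk`, the modelling
assumptions behind it, and the choices made where the design was genuinely
open. The package reimplements a complete epidemiological workflow linking
dietary inflammatory potential, polygenic risk and systemic inflammation to
abdominal aortic aneurysm (AAA) incidence, and ships a synthetic-cohort
generator so the whole workflow can be exercised and validated without
access to restricted cohort data.

## Dietary inflammatory scoring (E-DII)

For each of 30 dietary components with global reference mean μ_i, SD σ_i
(both per 1,000 kcal) and literature-derived inflammatory weight w_i, the
energy-adjusted score of a participant with component densities d_i is

    z_i = (d_i − μ_i) / σ_i,   c_i = 2·Φ(z_i) − 1,   E-DII = Σ_i c_i · w_i,

where Φ is the standard normal CDF. Densities use the nutrient-density
method (intake / energy × 1,000) and are averaged across a participant's
24-h recalls *after* energy adjustment. Higher scores indicate a more
pro-inflammatory diet; the score is bounded by Σ|w_i| and monotone in each
component (direction given by the weight's sign).

Open choices: the mapping from z-scores to "centered percentiles" is taken
as the normal CDF (an empirical-percentile variant is available via
`percentile="empirical"`); tertile ties go to the lower tertile. The shipped
reference table (`data/edii_reference_synthetic.csv`) is **synthetic** —
realistic magnitudes and signed weights, not the published reference
database, which users must supply for real analyses. Supplement intake is
excluded.

## Blood indices

SIRI = N·M/L, SII = N·P/L, PNI = albumin + 5·L (counts in 10⁹/L, albumin
g/L). CONUT uses the standard published banding (albumin g/dL:
≥3.5→0, 3.0–3.49→2, 2.5–2.99→4, <2.5→6; lymphocytes /µL: ≥1600→0,
1200–1599→1, 800–1199→2, <800→3; cholesterol mg/dL: ≥180→0, 140–179→1,
100–139→2, <100→3), edges inclusive on the lower-risk side; unit
conversions (÷10, ×1000, ×38.67) are applied internally and the band table
is exported for audit.

## Polygenic risk

Scores are allele-dosage-weighted sums after allele harmonization (effect
sign flipped when the dosage counts the other allele; unalignable variants
are an error). Clumping+thresholding is the greedy textbook rule: ascending
p (ties broken by id), accept unless a previously accepted same-chromosome
variant lies within the 1,000-kb window with r² > 0.1. Missing LD entries
are treated as r² = 0 with a logged warning (conservative for retention);
missing dosages are mean-imputed (2 × allele frequency). Posterior effect
sizes from external continuous-shrinkage tools are ingested as ordinary
effect tables — the Bayesian machinery itself is out of scope. Risk groups
are quintile-based (bottom / 2nd–4th / top), ties to the lower group.
Discrimination: AUC on event status (ties ½) and Harrell's C over
censoring-comparable pairs.

## Survival modelling

Three nested adjustment tiers: (1) age, sex, education, employment,
Townsend index, BMI; (2) + eight comorbidities, medication count, vitamin
use; (3) + smoking, physical activity, sleep pattern, sedentary time.
Exposure codings: tertile indicators (T1 reference) or per-cohort-SD
continuous.

The default fitter is an in-package Newton–Raphson maximizer of the
**Breslow** partial likelihood, vectorized over risk sets with step-halving
(the partial likelihood is non-decreasing across iterations) and explicit
failure modes: rank-deficient designs raise a collinearity error naming the
columns, monotone likelihoods a convergence error. Efron ties and
stratified fits are delegated to `statsmodels.PHReg`. Wald 95% CIs;
BIC = −2·logPL + k·log(events) (events, not n, as the effective sample
size); Harrell C-index via lifelines. The fitter is validated in the test
suite against a brute-force Newton oracle (n ≤ 30, agreement 1e-6) and
against R's `survival::coxph` (coefficients, SEs, concordance).

Proportional hazards are checked with Schoenfeld residuals scaled against
the Kaplan–Meier transform of event time; per-covariate and global
chi-square tests follow the Grambsch–Therneau construction
(T = d·u'Vu/Σg̃², u the g-weighted residual sum, V the coefficient
covariance). Type-I error of the global test is verified by simulation.

Dose-response uses a restricted cubic spline (truncated-power basis,
Harrell scaling), default 4 knots at the 5/35/65/95 percentiles, reference
at the exposure median (HR ≡ 1 there), and a Wald test on the nonlinear
coefficients as the nonlinearity test. Subgroup scans fit stratum-specific
models (sex, age < / ≥ 60, BMI 18.5–24.9 vs outside, hypertension,
smoking) plus a pooled cross-product interaction test. The per-component
scan fits one per-SD tier-3 model per energy-adjusted component density.
Sensitivity reruns: 2-year landmark exclusion, comorbidity-free subset, and
≥2-recall restriction.

Sparse binary covariates (<10 carriers, or <3 events among carriers) are
pruned with a warning before tier fits in the pipeline and replication
harnesses; rare flags (e.g. chronic liver disease, prevalence ~0.2%)
otherwise produce monotone partial likelihoods in small cohorts. `fit_cox`
itself never prunes silently.

## Joint effects, interaction, mediation

Joint effects come from a single Cox fit on 8 cell indicators of the
E-DII-tertile × PRS-group grid (low/low reference). Additive interaction is
RERI = HR11 − HR10 − HR01 + 1 with a delta-method CI from the joint
covariance of the three log-HRs (gradient (−HR10, −HR01, HR11)); a
participant-resampling bootstrap CI is optional. Multiplicative interaction
is the Wald test on a cross-product term.

Mediation of SIRI between the per-SD E-DII exposure and AAA incidence uses
the counterfactual decomposition on the **risk-difference scale at horizon
τ** (default: administrative censoring time): with a Gaussian linear
mediator model and a Cox outcome model whose Breslow baseline gives
F(x, m | c) = 1 − exp(−H₀(τ)·e^{βx·x + βm·m + βc·c}), the ACME moves only
the mediator between its potential values at x and x+1 SD, the ADE only
the exposure; both are averaged over the two exposure arms so that
total = ACME + ADE holds exactly, draw by draw. Hazard-scale mediation does
not decompose cleanly, which is why the incidence scale was chosen; the
scale and contrast are recorded in the result metadata. Uncertainty:
quasi-Bayesian draws (default 1,000) of both parameter vectors from their
asymptotic normals, with mediator residual noise redrawn per draw; CIs are
the 2.5/97.5 percentiles. Baseline-hazard uncertainty is not propagated
(it largely cancels in the mediated proportion). A full nonparametric
bootstrap is available via `method="bootstrap"`. The proportion mediated
ACME/(ACME+ADE) is flagged unstable when the total-effect CI spans zero —
it is a ratio and is heavy-tailed when the total effect is weakly
identified, which is also why the replication experiments use large
cohorts for this quantity.

## Cutpoint selection

The maximally selected rank statistic is computed through the log-rank
score representation: subject scores a_i = δ_i − Λ̂(t_i) (Nelson–Aalen at
the observed time), and the statistic at cut c is the standardized sum of
scores in {x ≤ c} under the permutation variance — an O(n log n)
formulation whose maximum is invariant to monotone transforms of x. The
search range is the 10th–90th percentile (maxstat convention). The
selection-adjusted p-value uses the Lausen–Schumacher improved-Bonferroni
approximation φ(b)(b − 1/b)·log[q₂(1−q₁)/(q₁(1−q₂))] + 4φ(b)/b, clipped to
[p_pointwise, 1]; an exact permutation option exists. The approximation is
conservative, so its null rejection rate sits at or below the nominal 5%.
Cutpoint stability is assessed by resampling participants, refitting the
tier-3 model on the dichotomized variable, and reporting the median HR and
percentile interval; degenerate resamples (<2 events per side) are skipped
and counted, with an instability warning above 20%.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real participant data:

* **Diet.** A latent "diet quality" factor u ~ N(0,1) loads on every
  component with correlation 0.5 signed by the component's inflammatory
  weight, so pro-inflammatory components co-vary; component densities are
  Gaussian around the reference values (floored at 1% of the mean), and
  recall-level intakes add multiplicative log-normal noise (SD 0.15) around
  participant energy (women 1,900 ± 400 kcal, men 2,300 ± 450, matching the
  exclusion thresholds' sex split). Recall counts 1–5 with probabilities
  (.35,.25,.18,.12,.10).
* **Blood panel.** Log-normal counts matched to the study's baseline means
  and SDs (neutrophils 4.1 ± 1.2, monocytes 0.45 ± 0.15, lymphocytes
  1.9 ± 0.5, platelets 248 ± 52; albumin 45.5 ± 2.5 g/L, cholesterol
  5.7 ± 1.1 mmol/L), giving SIRI ≈ 1.0 ± 0.55, PNI ≈ 55, CONUT ≈ 0.6 — the
  reported cohort values. The mediator path multiplies monocytes by
  exp(γ·x) with γ = log(1 + slope/E[SIRI]), so `edii_to_siri_slope` is
  approximately the SIRI-unit shift per E-DII SD.
* **Genetics.** 34 independent Hardy–Weinberg SNPs, MAF U(0.05, 0.5),
  effects N(0, 0.1²).
* **Outcome.** Exponential baseline hazard (Weibull shape configurable)
  multiplied by exp(linear predictor); the linear predictor is built from
  the *realized* exposures — the E-DII, SIRI and PRS computed from the
  simulated data with the same scoring code the analysis uses — so model
  fits recover the configured log-hazards without attenuation. Default
  nuisance hazards: male ln 4, age ln 1.8/SD, smoking ln 1.5 (AAA's strong
  demographic gradient). Administrative censoring at 13.8 years plus
  optional exponential dropout. Switches exist for a time-varying exposure
  effect (piecewise hazard, for PH-test power checks), a quadratic
  log-hazard (spline power checks) and a sex-specific effect (subgroup
  power checks).
* **Exclusions.** Applied in a fixed, logged order: refused follow-up;
  implausible mean daily energy (strictly <500/>3,500 kcal women,
  <800/>4,200 men); baseline disease; pregnancy; missing markers or
  covariates. The log's removals always sum to raw − retained.

What the generator does *not* emulate: real food-composition correlation
structure, measurement error in blood assays, LD between SNPs (available
only via an explicit correlation matrix for clumping tests), informative
censoring, or secular trends. Passing recovery tests therefore shows the
*estimators* are correct under the assumed data-generating process, not
that the original study's estimates are reproducible from real data.

## Calibration and replication experiments

`calibration.recovery_config` pins the generator's true effects to the
study's reported estimates (tertile-3 HR 1.36, per-SD HR 1.12, joint
high/high HR 3.04, PRS top-quintile HR 2.35, SIRI-step HR 1.57 at cut
1.22) with the baseline rate inflated to ~2,200 events per 20,000
participants — event count, not cohort size, drives the precision of a Cox
estimate, so this matches the precision of much larger rare-event cohorts
at a fraction of the compute. The mediation configuration was calibrated
once against a 600,000-participant potential-outcome oracle (exact
closed-form incidences, no event sampling) to a 9.16% mediated proportion
while holding the total per-SD effect at HR 1.12: slope 0.0584, direct
log-HR 0.1029, SIRI per-SD log-HR ln(1.10).

`scripts/acceptance.py` reruns these experiments from scratch: 40
replicates of n = 20,000 for each hazard-ratio target and 20 replicates of
n = 50,000 for the mediated proportion (the ratio estimator needs the
larger cohorts for per-replicate stability), reporting replicate means.
The test suite runs the same harnesses at reduced size, plus the
null-calibration battery (200 replicates each for the exposure Wald test,
the global Schoenfeld test, the spline nonlinearity test and the maxstat
adjusted p; the first three are checked against 5% ± 2 MC SE, maxstat
against the upper band only since its correction is conservative).

## Numerical notes

* Newton solver: convergence at step sup-norm < 1e-10, max 60 iterations,
  linear predictor recentred before exponentiation; separation detected via
  singular information or |β| > 50.
* Quantile-based groupings (tertiles, quintiles) send boundary ties to the
  lower group, deterministically.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  configs and results; replicate seeds derive from a `SeedSequence` and
  stay below 2³¹.
* Degenerate inputs raise typed errors (`errors` module) naming the
  offending field, column or component.

## Known limitations

* The shipped E-DII reference table is synthetic; absolute score values are
  not comparable to published E-DII scores.
* Fine–Gray competing-risks models and multiple imputation are not
  implemented (out of scope).
* The mediation estimator assumes sequential ignorability and no
  exposure–mediator interaction; the mediator model is linear on the raw
  (or log) scale while the generator's path is multiplicative — the small
  resulting bias is visible in the replication experiments (~0.5–1
  percentage point on the mediated proportion).
* Strata support routes through statsmodels and loses the in-package
  solver's speed.
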