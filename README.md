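# ediirisk

Dietary inflammatory potential, genetic susceptibility and systemic
inflammation in relation to abdominal aortic aneurysm (AAA) risk — a
tested, config-driven reimplementation of the complete analytic workflow
of a large prospective-cohort study, exercised on a synthetic cohort
generator that emulates the study's statistical structure (no restricted
biobank data required).

**For whom:** epidemiologists and biostatisticians who want to audit,
reuse or extend the study's methods — dietary inflammatory scoring,
polygenic risk scores, tiered Cox models, additive interaction, survival
mediation, cutpoint selection — on their own cohort tables or on
simulated data with known truth.

## What it computes

* **E-DII** (Energy-adjusted Dietary Inflammatory Index): per component
  *i*, z = (density − μᵢ)/σᵢ against a global reference, centered
  percentile c = 2Φ(z) − 1, score = Σ cᵢ·wᵢ with literature-derived
  inflammatory weights wᵢ; tertile and per-SD exposure codings.
* **Blood indices**: SIRI = N·M/L, SII = N·P/L, PNI = albumin + 5·L,
  CONUT (banded 0–12).
* **Polygenic risk**: dosage-weighted scores with allele harmonization,
  greedy LD clumping + thresholding (1,000-kb window, r² > 0.1), quintile
  risk groups, AUC and Harrell C.
* **Survival**: three nested Cox adjustment tiers (Breslow partial
  likelihood, in-package Newton solver validated against R's
  `survival::coxph`), Schoenfeld PH diagnostics, Kaplan–Meier + log-rank,
  restricted-cubic-spline dose–response, subgroup and per-component scans,
  landmark/comorbidity/recall sensitivity reruns.
* **Interaction**: joint E-DII × PRS cell grid (low/low reference),
  multiplicative product-term test, RERI = HR₁₁ − HR₁₀ − HR₀₁ + 1 with
  delta-method and bootstrap CIs.
* **Mediation**: quasi-Bayesian Monte Carlo decomposition of the per-SD
  E-DII effect through SIRI on the cumulative-incidence scale at horizon
  τ — ACME, ADE, total = ACME + ADE (exactly, draw by draw), proportion
  mediated with percentile CIs.
* **Cutpoints**: maximally selected log-rank statistics with the
  Lausen–Schumacher selection correction (or exact permutation), plus
  bootstrap stability of the dichotomized hazard ratio.

See `docs/methods.md` for formulas, assumptions and design choices.

## Worked example

```python
import ediirisk as er
from ediirisk.survival import fit_cox, pruned_spec, schoenfeld_test

# a calibrated synthetic cohort: true per-SD effect HR 1.12, part of it
# flowing through the diet -> SIRI -> AAA mediator path
cfg = er.calibration.recovery_config("mediation", n=20_000, seed=7)
cohort, exclusions, densities = er.simulate_analysis_cohort(cfg)

fit = fit_cox(cohort, pruned_spec(cohort, tier=3, exposure="edii_sd"))
print(fit.hr_table.loc["edii_sd"])
print(schoenfeld_test(fit).loc["GLOBAL"])

res = er.mediate(cohort, spec=pruned_spec(cohort, 3), n_sims=1000, seed=7)
print(res.proportion_mediated, res.proportion_ci)
```

prints (formatted):

```
analysis cohort: 19988 participants, 2199 events (12 excluded)
per-SD E-DII HR 1.12 (95% CI 1.08-1.17), C-index 0.741
PH global p = 0.56
proportion mediated by SIRI: 8.0% (95% CI 3.8-15.0%)
```

Read: each 1-SD increase in dietary inflammatory potential raises the AAA
hazard by 12% (the generator's truth, recovered by the tier-3 model); the
proportional-hazards assumption is not rejected; roughly 8–9% of the
effect flows through the systemic inflammation response index, matching
the generator's oracle value of 9.2%.

The same workflow runs from the shell:

```sh
ediirisk simulate --n 20000 --seed 7 --effect mediation --out cohort.csv
ediirisk fit cohort.csv --tier 3
ediirisk mediate cohort.csv --n-sims 1000 --seed 7
ediirisk run-all --n 20000 --seed 7 --out run/   # full pipeline + manifest
```

User-supplied data replace the simulation step: a recall-level intake CSV
(`ediirisk score`), a cohort table with the columns the models expect, an
E-DII reference CSV (component, unit, mean, sd, weight) and tab-delimited
SNP effect tables.

## Layout

```
src/ediirisk/
  edii.py          E-DII scoring and exposure codings
  indices.py       SIRI / SII / PNI / CONUT
  prs.py           weighted PRS, clumping+thresholding, risk groups
  survival.py      Cox tiers, diagnostics, KM, splines, scans
  interaction.py   joint effects, RERI
  mediation.py     quasi-Bayesian survival mediation
  cutpoint.py      maximally selected rank statistics
  synth_cohort.py  generator, exclusions, analysis-table assembly
  calibration.py   study-calibrated generator configurations
  replication.py   effect-recovery harnesses
  pipeline.py      orchestration + manifest; cli.py  console interface
```
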