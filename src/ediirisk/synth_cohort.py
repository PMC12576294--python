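"""Seed-controlled synthetic cohorts with the dependence structure the
analysis assumes.

The generator emulates a prospective dietary-recall cohort:

* per-participant 24-h recall intakes (1-5 recalls) drawn lognormally around
  a global reference database, with a shared latent "diet quality" factor so
  that pro-inflammatory components co-vary;
* a baseline blood panel whose monocyte count is shifted multiplicatively by
  the participant's standardized dietary inflammation score — the mediator
  path from diet to the systemic inflammation response index (SIRI);
* independent Hardy-Weinberg genotypes and a polygenic liability;
* exponential (optionally Weibull) proportional-hazards event times with
  administrative censoring near 13.8 years and optional exponential dropout.

Crucially, the hazards are driven by the *realized* exposures — the E-DII,
SIRI and PRS computed from the simulated data with the same scoring code the
analysis uses — so downstream model fits recover the configured log-hazards
without errors-in-variables attenuation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import edii as edii_mod
from . import indices as indices_mod
from . import prs as prs_mod
from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "RawCohort",
    "ExclusionLog",
    "generate_cohort",
    "apply_exclusions",
    "build_analysis_table",
    "simulate_analysis_cohort",
    "true_mediated_proportion",
]

# energy plausibility bounds, kcal/day (strict inequalities)
ENERGY_BOUNDS = {"female": (500.0, 3500.0), "male": (800.0, 4200.0)}

COMORBIDITIES = {
    "hypertension": 0.278,
    "diabetes": 0.057,
    "dyslipidemia": 0.374,
    "cancer": 0.128,
    "chronic_respiratory": 0.129,
    "chronic_liver": 0.0024,
    "chronic_kidney": 0.0029,
    "cardiovascular": 0.096,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Effect sizes are on the log-hazard scale; ``baseline_rate`` is the
    baseline event rate in events per person-year.  Defaults emulate the
    study population: ~56 year olds, 46% male, rare events (~0.25%/13.8 y
    at the default baseline rate before covariate effects).
    """

    n_participants: int = 10_000
    seed: int = 0

    # follow-up / event process
    baseline_rate: float = 2.45e-4          # events per person-year
    weibull_shape: float = 1.0              # 1.0 = exponential baseline
    admin_censor_years: float = 13.8
    dropout_rate: float = 0.0               # exponential loss to follow-up

    # diet
    latent_corr: float = 0.5                # component loading on diet factor
    recall_noise_sd: float = 0.15
    recall_count_probs: tuple = (0.35, 0.25, 0.18, 0.12, 0.10)
    energy_mean_female: float = 1900.0
    energy_sd_female: float = 400.0
    energy_mean_male: float = 2300.0
    energy_sd_male: float = 450.0

    # blood panel (mean, sd), counts 10^9/L, albumin g/L, cholesterol mmol/L
    neutrophil: tuple = (4.1, 1.2)
    monocyte: tuple = (0.45, 0.15)
    lymphocyte: tuple = (1.9, 0.5)
    platelet: tuple = (248.0, 52.0)
    albumin: tuple = (45.5, 2.5)
    total_cholesterol: tuple = (5.7, 1.1)
    edii_to_siri_slope: float = 0.0         # ~SIRI units per E-DII SD

    # genetics
    prs_snps: int = 34
    maf_range: tuple = (0.05, 0.5)
    snp_beta_sd: float = 0.10
    log_hr_prs_intermediate: float = 0.0
    log_hr_prs_high: float = 0.0

    # exposure effects
    log_hr_edii_sd: float = 0.0
    log_hr_edii_t2: float = 0.0
    log_hr_edii_t3: float = 0.0
    log_hr_siri_sd: float = 0.0             # per realized SIRI SD
    siri_step_cut: float | None = None
    log_hr_siri_step: float = 0.0
    # 3x3 grid [E-DII tertile][PRS group], reference cell [0][0] must be 0
    joint_cell_log_hr: tuple | None = None

    # misc hazard switches
    covariate_log_hr: dict = field(
        default_factory=lambda: {"male": np.log(4.0), "age_z": np.log(1.8),
                                 "smoker": np.log(1.5)}
    )
    quadratic_log_hr: float = 0.0           # on edii_sd^2 (nonlinearity switch)
    ph_violation_log_hr: float = 0.0        # extra edii_sd log-HR after switch
    ph_violation_years: float = 5.0
    log_hr_edii_sd_male_extra: float = 0.0  # sex-specific effect switch

    # covariate distributions
    age_mean: float = 56.2
    age_sd: float = 7.9
    p_male: float = 0.459
    bmi_mean: float = 26.8
    bmi_sd: float = 4.4
    townsend_mean: float = -1.8
    townsend_sd: float = 2.7
    p_degree: float = 0.443
    p_employed: float = 0.925
    p_never_smoker: float = 0.565
    activity_probs: tuple = (0.27, 0.34, 0.39)       # low/moderate/high
    sleep_probs: tuple = (0.36, 0.60, 0.04)          # poor/moderate/good
    sedentary_probs: tuple = (0.22, 0.33, 0.45)      # high/moderate/low
    comorbidity_prevalence: dict = field(
        default_factory=lambda: dict(COMORBIDITIES)
    )
    medications_lambda: float = 2.1
    p_vitamin_use: float = 0.252

    # exclusion-flag probabilities
    p_refused_followup: float = 0.001
    p_baseline_aaa: float = 0.003
    p_pregnant: float = 0.002               # among women
    p_missing_marker: float = 0.004
    p_missing_covariate: float = 0.004

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants", "must be >= 2")
        if self.baseline_rate <= 0:
            raise ConfigurationError("baseline_rate", "must be > 0")
        if self.admin_censor_years <= 0:
            raise ConfigurationError("admin_censor_years", "must be > 0")
        if self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape", "must be > 0")
        if self.dropout_rate < 0:
            raise ConfigurationError("dropout_rate", "must be >= 0")
        if not 0 <= self.latent_corr < 1:
            raise ConfigurationError("latent_corr", "must be in [0, 1)")
        for name in ("energy_sd_female", "energy_sd_male", "age_sd", "bmi_sd",
                     "townsend_sd", "snp_beta_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(name, "must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("maf_range", "must satisfy 0 < lo <= hi < 1")
        if abs(sum(self.recall_count_probs) - 1) > 1e-9:
            raise ConfigurationError("recall_count_probs", "must sum to 1")
        if self.ph_violation_log_hr != 0 and self.weibull_shape != 1.0:
            raise ConfigurationError(
                "ph_violation_log_hr",
                "non-proportional hazards only supported with exponential baseline",
            )
        if self.joint_cell_log_hr is not None:
            grid = np.asarray(self.joint_cell_log_hr, dtype=float)
            if grid.shape != (3, 3):
                raise ConfigurationError("joint_cell_log_hr", "must be 3x3")
            if grid[0, 0] != 0:
                raise ConfigurationError(
                    "joint_cell_log_hr", "reference cell [0][0] must be 0"
                )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, default=lambda o: list(o) if hasattr(o, "__iter__") else o,
                          indent=2)


@dataclass
class RawCohort:
    """A generated cohort before exclusions.

    ``participants`` holds one row per participant (covariates, blood panel,
    survival outcome, exclusion flags, and ``true_*`` columns recording the
    exposures the hazard was driven by).  ``recalls`` is recall-level dietary
    intake (may be ``None`` for the lightweight oracle path), ``dosages`` the
    genotype matrix, ``effects`` the per-SNP effect table.
    """

    participants: pd.DataFrame
    recalls: pd.DataFrame | None
    dosages: pd.DataFrame
    effects: pd.DataFrame
    config: GeneratorConfig
    siri_gamma: float = 0.0
    siri_center: float = 0.0
    siri_scale: float = 1.0

    @property
    def n(self) -> int:
        return len(self.participants)


@dataclass
class ExclusionLog:
    """Counts and ids removed per criterion, in application order."""

    raw_n: int
    steps: list  # list of (criterion, n_removed, ids)
    retained_n: int

    def counts(self) -> dict[str, int]:
        return {name: n for name, n, _ in self.steps}

    def to_json(self) -> str:
        return json.dumps(
            {
                "raw_n": self.raw_n,
                "retained_n": self.retained_n,
                "removed": [
                    {"criterion": name, "n": n, "ids": [int(i) for i in ids]}
                    for name, n, ids in self.steps
                ],
            },
            indent=2,
        )


def _lognormal(rng, mean, sd, size):
    """Draws with the requested arithmetic mean and SD."""
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size)


def generate_cohort(
    config: GeneratorConfig,
    *,
    reference: pd.DataFrame | None = None,
    include_recalls: bool = True,
) -> RawCohort:
    """Generate a reproducible synthetic cohort under ``config``.

    With ``include_recalls=False`` the recall-level dietary table is skipped
    and the E-DII is computed from the latent densities directly; this is the
    memory-light path used by the large-n mediation oracle and leaves the
    joint law of (exposure, mediator, outcome) unchanged.
    """
    config.validate()
    if reference is None:
        reference = edii_mod.default_reference()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pid = np.arange(n)

    # --- covariates -----------------------------------------------------
    male = rng.random(n) < config.p_male
    age = rng.normal(config.age_mean, config.age_sd, n)
    bmi = np.maximum(rng.normal(config.bmi_mean, config.bmi_sd, n), 14.0)
    townsend = rng.normal(config.townsend_mean, config.townsend_sd, n)
    part = pd.DataFrame(
        {
            "participant_id": pid,
            "male": male.astype(int),
            "age": age,
            "bmi": bmi,
            "townsend": townsend,
            "degree": (rng.random(n) < config.p_degree).astype(int),
            "employed": (rng.random(n) < config.p_employed).astype(int),
            "smoker": (rng.random(n) >= config.p_never_smoker).astype(int),
            "activity": rng.choice(
                ["low", "moderate", "high"], n, p=config.activity_probs
            ),
            "sleep": rng.choice(
                ["poor", "moderate", "good"], n, p=config.sleep_probs
            ),
            "sedentary": rng.choice(
                ["high", "moderate", "low"], n, p=config.sedentary_probs
            ),
            "n_medications": rng.poisson(config.medications_lambda, n),
            "vitamin_use": (rng.random(n) < config.p_vitamin_use).astype(int),
        }
    ).set_index("participant_id", drop=False)
    for name, prev in config.comorbidity_prevalence.items():
        part[name] = (rng.random(n) < prev).astype(int)

    # --- diet ------------------------------------------------------------
    comps = reference["component"].tolist()
    mu = reference["mean"].to_numpy(float)
    sigma = reference["sd"].to_numpy(float)
    w = reference["weight"].to_numpy(float)
    rho = config.latent_corr
    latent = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(comps)))
    zmat = np.sign(w) * rho * latent[:, None] + np.sqrt(1 - rho**2) * eps
    dens = np.maximum(mu + sigma * zmat, mu * 0.01)  # densities per 1,000 kcal

    e_mean = np.where(male, config.energy_mean_male, config.energy_mean_female)
    e_sd = np.where(male, config.energy_sd_male, config.energy_sd_female)
    energy = np.maximum(rng.normal(e_mean, e_sd), 300.0)

    recalls = None
    if include_recalls:
        n_rec = rng.choice(np.arange(1, 6), n, p=config.recall_count_probs)
        rep = np.repeat(np.arange(n), n_rec)
        rec_energy = np.maximum(
            energy[rep] * np.exp(rng.normal(0.0, 0.10, rep.size)), 300.0
        )
        noise = np.exp(
            rng.normal(0.0, config.recall_noise_sd, (rep.size, len(comps)))
            - config.recall_noise_sd**2 / 2.0
        )
        intake = dens[rep] * rec_energy[:, None] / 1000.0 * noise
        recalls = pd.DataFrame(intake, columns=comps)
        recalls.insert(0, "participant_id", rep)
        recalls.insert(
            1, "recall", np.concatenate([np.arange(k) for k in n_rec])
        )
        recalls["energy_kcal"] = rec_energy
        dens_measured = edii_mod.energy_adjust(recalls, comps)
    else:
        dens_measured = pd.DataFrame(dens, columns=comps, index=pd.Index(pid,
                                     name="participant_id"))
    scores = edii_mod.edii_score(dens_measured, reference)["edii"]
    scores = scores.reindex(pid)
    tert, edii_sd = edii_mod.code_exposure(scores)
    part["true_edii"] = scores.to_numpy()
    part["true_edii_sd"] = edii_sd.to_numpy()
    part["true_edii_tertile"] = tert.to_numpy()
    part["mean_energy_kcal"] = (
        recalls.groupby("participant_id")["energy_kcal"].mean().reindex(pid).to_numpy()
        if recalls is not None
        else energy
    )

    # --- blood panel with mediator path ----------------------------------
    neut = _lognormal(rng, *config.neutrophil, n)
    mono_base = _lognormal(rng, *config.monocyte, n)
    lymph = _lognormal(rng, *config.lymphocyte, n)
    plate = _lognormal(rng, *config.platelet, n)
    alb = rng.normal(*config.albumin, n)
    tc = np.maximum(rng.normal(*config.total_cholesterol, n), 1.0)
    x = part["true_edii_sd"].to_numpy()
    siri_base_mean = float(np.mean(neut * mono_base / lymph))
    gamma = (
        np.log1p(config.edii_to_siri_slope / siri_base_mean)
        if config.edii_to_siri_slope != 0
        else 0.0
    )
    mono = mono_base * np.exp(gamma * x)
    part["neutrophils"] = neut
    part["monocytes"] = mono
    part["lymphocytes"] = lymph
    part["platelets"] = plate
    part["albumin"] = alb
    part["total_cholesterol"] = tc
    part["_mono_base"] = mono_base
    siri = neut * mono / lymph
    siri_center, siri_scale = float(siri.mean()), float(siri.std(ddof=1))
    part["true_siri"] = siri

    # --- genetics ---------------------------------------------------------
    m = config.prs_snps
    freqs = rng.uniform(*config.maf_range, m)
    betas = rng.normal(0.0, config.snp_beta_sd, m)
    snp_ids = [f"rs{100000 + i}" for i in range(m)]
    geno = rng.binomial(2, freqs, (n, m)).astype(np.int8)
    dosages = pd.DataFrame(geno, columns=snp_ids,
                           index=pd.Index(pid, name="participant_id"))
    effects = pd.DataFrame(
        {
            "id": snp_ids,
            "chr": rng.integers(1, 23, m),
            "pos": rng.integers(1, 2.5e8, m),
            "a1": "A",
            "a2": "G",
            "beta": betas,
            "p": 10.0 ** rng.uniform(-12, -8, m),
        }
    )
    prs_score = prs_mod.weighted_prs(dosages, effects)
    prs_group = prs_mod.assign_risk_groups(prs_score)
    part["true_prs"] = prs_score.to_numpy()
    part["true_prs_group"] = prs_group.to_numpy()

    # --- linear predictor -------------------------------------------------
    age_z = (age - config.age_mean) / config.age_sd
    cov_design = {
        "male": male.astype(float),
        "age_z": age_z,
        "smoker": part["smoker"].to_numpy(float),
        "bmi_z": (bmi - config.bmi_mean) / config.bmi_sd,
        "townsend_z": (townsend - config.townsend_mean) / config.townsend_sd,
        **{k: part[k].to_numpy(float) for k in config.comorbidity_prevalence},
    }
    eta_cov = np.zeros(n)
    for key, b in config.covariate_log_hr.items():
        if b:
            eta_cov += b * cov_design[key]
    part["_eta_cov"] = eta_cov

    t2 = (part["true_edii_tertile"] == "T2").to_numpy(float)
    t3 = (part["true_edii_tertile"] == "T3").to_numpy(float)
    siri_z = (siri - siri_center) / siri_scale
    eta = (
        eta_cov
        + config.log_hr_edii_sd * x
        + config.quadratic_log_hr * x**2
        + config.log_hr_edii_sd_male_extra * x * male
        + config.log_hr_edii_t2 * t2
        + config.log_hr_edii_t3 * t3
        + config.log_hr_siri_sd * siri_z
    )
    if config.siri_step_cut is not None:
        eta = eta + config.log_hr_siri_step * (siri > config.siri_step_cut)
    grp = part["true_prs_group"].to_numpy()
    eta = eta + np.where(
        grp == "high",
        config.log_hr_prs_high,
        np.where(grp == "intermediate", config.log_hr_prs_intermediate, 0.0),
    )
    if config.joint_cell_log_hr is not None:
        grid = np.asarray(config.joint_cell_log_hr, float)
        ti = np.select([t2 == 1, t3 == 1], [1, 2], default=0)
        gi = np.select([grp == "intermediate", grp == "high"], [1, 2], default=0)
        eta = eta + grid[ti, gi]

    # --- event times ------------------------------------------------------
    rate = config.baseline_rate * np.exp(eta)
    exp_draw = rng.exponential(1.0, n)
    k = config.weibull_shape
    if config.ph_violation_log_hr != 0:
        # piecewise-constant hazard: exposure log-HR gains an increment after
        # ph_violation_years; invert the piecewise-linear cumulative hazard
        t0 = config.ph_violation_years
        rate2 = rate * np.exp(config.ph_violation_log_hr * x)
        h0 = rate * t0
        event_time = np.where(
            exp_draw <= h0, exp_draw / rate, t0 + (exp_draw - h0) / rate2
        )
    elif k == 1.0:
        event_time = exp_draw / rate
    else:
        event_time = (exp_draw / rate) ** (1.0 / k)
    censor_time = np.full(n, config.admin_censor_years)
    if config.dropout_rate > 0:
        censor_time = np.minimum(
            censor_time, rng.exponential(1.0 / config.dropout_rate, n)
        )
    part["latent_event_time"] = event_time
    part["latent_censor_time"] = censor_time
    part["time"] = np.minimum(event_time, censor_time)
    part["event"] = (event_time <= censor_time).astype(int)

    # --- exclusion flags --------------------------------------------------
    part["refused_followup"] = (rng.random(n) < config.p_refused_followup).astype(int)
    part["baseline_aaa"] = (rng.random(n) < config.p_baseline_aaa).astype(int)
    part["pregnant"] = (
        (~male) & (rng.random(n) < config.p_pregnant)
    ).astype(int)
    miss_marker = rng.random(n) < config.p_missing_marker
    miss_cov = rng.random(n) < config.p_missing_covariate
    part.loc[miss_marker, "albumin"] = np.nan
    part.loc[miss_cov, "bmi"] = np.nan

    return RawCohort(
        participants=part,
        recalls=recalls,
        dosages=dosages,
        effects=effects,
        config=config,
        siri_gamma=gamma,
        siri_center=siri_center,
        siri_scale=siri_scale,
    )


def apply_exclusions(raw: RawCohort) -> tuple[RawCohort, ExclusionLog]:
    """Apply the baseline exclusion filters in a fixed, logged order.

    Order: refused follow-up; implausible mean daily energy (strictly <500 or
    >3,500 kcal/day for women, <800 or >4,200 for men); baseline disease;
    pregnancy; missing inflammatory markers or baseline covariates.
    """
    part = raw.participants
    steps = []
    keep = pd.Series(True, index=part.index)

    def _remove(name: str, mask: pd.Series) -> None:
        removed = part.index[keep & mask]
        steps.append((name, len(removed), removed.tolist()))
        keep.loc[removed] = False

    _remove("refused_followup", part["refused_followup"] == 1)
    fem_lo, fem_hi = ENERGY_BOUNDS["female"]
    mal_lo, mal_hi = ENERGY_BOUNDS["male"]
    e = part["mean_energy_kcal"]
    implausible = pd.Series(
        np.where(
            part["male"] == 1,
            (e < mal_lo) | (e > mal_hi),
            (e < fem_lo) | (e > fem_hi),
        ),
        index=part.index,
    )
    _remove("implausible_energy", implausible)
    _remove("baseline_aaa", part["baseline_aaa"] == 1)
    _remove("pregnant", part["pregnant"] == 1)
    marker_cols = ["neutrophils", "monocytes", "lymphocytes", "platelets",
                   "albumin", "total_cholesterol"]
    cov_cols = ["age", "bmi", "townsend"]
    _remove("missing_data", part[marker_cols + cov_cols].isna().any(axis=1))

    retained = part.loc[keep]
    log = ExclusionLog(raw_n=len(part), steps=steps, retained_n=len(retained))
    out = RawCohort(
        participants=retained.copy(),
        recalls=(
            raw.recalls.loc[raw.recalls["participant_id"].isin(retained.index)]
            .reset_index(drop=True)
            if raw.recalls is not None
            else None
        ),
        dosages=raw.dosages.loc[retained.index],
        effects=raw.effects,
        config=raw.config,
        siri_gamma=raw.siri_gamma,
        siri_center=raw.siri_center,
        siri_scale=raw.siri_scale,
    )
    return out, log


def build_analysis_table(
    raw: RawCohort, *, reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assemble the analysis-ready cohort table from a (filtered) raw cohort.

    Recomputes the E-DII (scoring + exposure codings), blood indices and PRS
    from the raw data — the same path a user-supplied cohort would follow —
    and joins covariates and the survival outcome.
    """
    if reference is None:
        reference = edii_mod.default_reference()
    part = raw.participants
    comps = reference["component"].tolist()
    if raw.recalls is None:
        raise ValueError("build_analysis_table requires recall-level data")
    dens = edii_mod.energy_adjust(raw.recalls, comps)
    scored = edii_mod.edii_score(dens, reference)
    tert, edii_sd = edii_mod.code_exposure(scored["edii"])
    idx = indices_mod.compute_indices(part)
    prs_score = prs_mod.weighted_prs(raw.dosages, raw.effects)
    prs_group = prs_mod.assign_risk_groups(prs_score)

    cohort = part[
        [
            "participant_id", "male", "age", "bmi", "townsend", "degree",
            "employed", "smoker", "activity", "sleep", "sedentary",
            "n_medications", "vitamin_use", "mean_energy_kcal", "time", "event",
        ]
        + list(raw.config.comorbidity_prevalence)
    ].copy()
    cohort["edii"] = scored["edii"].reindex(cohort.index)
    cohort["edii_sd"] = edii_sd.reindex(cohort.index)
    cohort["edii_tertile"] = tert.reindex(cohort.index)
    for col in ("siri", "sii", "pni", "conut"):
        cohort[col] = idx[col]
    cohort["siri_sd"] = (cohort["siri"] - cohort["siri"].mean()) / cohort[
        "siri"
    ].std(ddof=1)
    cohort["prs"] = prs_score
    cohort["prs_group"] = prs_group
    return cohort


def simulate_analysis_cohort(
    config: GeneratorConfig,
    *,
    reference: pd.DataFrame | None = None,
    exclude: bool = True,
) -> tuple[pd.DataFrame, ExclusionLog | None, pd.DataFrame]:
    """Generate, (optionally) filter, and score a cohort in one call.

    Returns ``(cohort_table, exclusion_log, densities)`` where ``densities``
    are per-participant energy-adjusted component densities (for the
    per-component association scan).
    """
    if reference is None:
        reference = edii_mod.default_reference()
    raw = generate_cohort(config, reference=reference)
    log = None
    if exclude:
        raw, log = apply_exclusions(raw)
    cohort = build_analysis_table(raw, reference=reference)
    dens = edii_mod.energy_adjust(raw.recalls, reference["component"].tolist())
    return cohort, log, dens


def true_mediated_proportion(
    config: GeneratorConfig,
    *,
    n: int = 1_000_000,
    tau: float | None = None,
    seed: int | None = None,
) -> dict[str, float]:
    """Large-n Monte-Carlo oracle for the generator's own mediated fraction.

    Simulates the generator's structural equations, sets the exposure to
    ``x`` and ``x + 1`` (one E-DII SD) with the mediator (SIRI) at its
    potential values, and evaluates the *exact* cumulative incidence at
    horizon ``tau`` from the closed-form survival function — no event draws,
    so the only Monte-Carlo error is over the covariate distribution.

    Returns the risk-difference-scale ACME, ADE, total effect and proportion
    mediated (the same effect scale the estimator reports).
    """
    cfg = dataclasses.replace(
        config,
        n_participants=n,
        seed=config.seed if seed is None else seed,
        p_refused_followup=0.0,
        p_baseline_aaa=0.0,
        p_pregnant=0.0,
        p_missing_marker=0.0,
        p_missing_covariate=0.0,
    )
    raw = generate_cohort(cfg, include_recalls=False)
    part = raw.participants
    if tau is None:
        tau = cfg.admin_censor_years
    x = part["true_edii_sd"].to_numpy()
    eta_cov = part["_eta_cov"].to_numpy()
    neut = part["neutrophils"].to_numpy()
    lymph = part["lymphocytes"].to_numpy()
    mono_base = part["_mono_base"].to_numpy()
    gamma = raw.siri_gamma

    def siri_at(x_set):
        return neut * mono_base * np.exp(gamma * x_set) / lymph

    def incidence(x_direct, x_mediator):
        s = siri_at(x_mediator)
        eta = (
            eta_cov
            + cfg.log_hr_edii_sd * x_direct
            + cfg.quadratic_log_hr * x_direct**2
            + cfg.log_hr_siri_sd * (s - raw.siri_center) / raw.siri_scale
        )
        if cfg.siri_step_cut is not None:
            eta = eta + cfg.log_hr_siri_step * (s > cfg.siri_step_cut)
        cumhaz = cfg.baseline_rate * tau**cfg.weibull_shape * np.exp(eta)
        return 1.0 - np.exp(-cumhaz)

    x1 = x + 1.0
    f00, f01 = incidence(x, x), incidence(x, x1)
    f10, f11 = incidence(x1, x), incidence(x1, x1)
    acme = 0.5 * float(np.mean(f11 - f10) + np.mean(f01 - f00))
    ade = 0.5 * float(np.mean(f10 - f00) + np.mean(f11 - f01))
    total = float(np.mean(f11 - f00))
    return {
        "acme": acme,
        "ade": ade,
        "total": total,
        "proportion_mediated": acme / total if total != 0 else np.nan,
    }
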