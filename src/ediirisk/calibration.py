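"""Study-calibrated generator configurations.

Each factory returns a :class:`~ediirisk.synth_cohort.GeneratorConfig` whose
true effect sizes match the cohort study's reported estimates, so that
recovery harnesses can compare fitted values against a known truth:

* E-DII tertile 3 vs 1: HR 1.36 (tertile 2: 1.11);
* E-DII per 1 SD: HR 1.12 (+12% hazard per SD);
* joint high-PRS + high-E-DII vs low/low: HR 3.04;
* PRS top vs bottom quintile: HR 2.35 (intermediate: 1.50);
* SIRI above its cutpoint (1.22): HR 1.57; per SIRI SD: HR 1.10;
* proportion of the diet-AAA association mediated by SIRI: 9.16%.

The recovery harness inflates the baseline event rate so that a cohort of
20,000 participants yields on the order of 1,500-2,000 events — enough for
precise replication averages on a single workstation — while the
``study_scale`` configuration keeps the original rare-event regime
(~0.3% cumulative incidence over 13.8 years).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .synth_cohort import GeneratorConfig

__all__ = [
    "TARGET_HRS",
    "study_config",
    "recovery_config",
    "RECOVERY_BASELINE_RATE",
    "MEDIATION_PATHS",
]

TARGET_HRS = {
    "edii_t2": 1.11,
    "edii_t3": 1.36,
    "edii_per_sd": 1.12,
    "joint_high_high": 3.04,
    "prs_intermediate": 1.50,
    "prs_high": 2.35,
    "siri_step": 1.57,
    "siri_per_sd": 1.10,
}

TARGET_PROPORTION_MEDIATED = 0.0916
SIRI_CUT = 1.22

# event-rate regimes (events per person-year)
STUDY_BASELINE_RATE = 8.0e-5      # ~0.3% cumulative incidence by 13.8 y
RECOVERY_BASELINE_RATE = 2.6e-3   # ~8% cumulative incidence: ~1,600 events/20k

# mediator-path calibration: the slope of SIRI on standardized E-DII (SIRI
# units per E-DII SD) and the direct log-hazard are chosen so that the
# generator's own large-n potential-outcome oracle returns the target
# mediated proportion while the total per-SD effect stays at HR 1.12
MEDIATION_PATHS = {
    "edii_to_siri_slope": 0.0584,
    "log_hr_siri_sd": float(np.log(TARGET_HRS["siri_per_sd"])),
    "log_hr_edii_sd_direct": 0.1029,
}

# plausible joint-effect surface (log-HR), E-DII tertiles x PRS groups;
# only the high/high corner is pinned to the reported estimate
_JOINT_GRID = (
    (0.0, float(np.log(1.6)), float(np.log(2.3))),
    (float(np.log(1.1)), float(np.log(1.8)), float(np.log(2.6))),
    (float(np.log(1.3)), float(np.log(2.0)), float(np.log(TARGET_HRS["joint_high_high"]))),
)


def study_config(n: int = 140_000, seed: int = 0) -> GeneratorConfig:
    """Rare-event configuration emulating the full study conditions."""
    return GeneratorConfig(
        n_participants=n,
        seed=seed,
        baseline_rate=STUDY_BASELINE_RATE,
        log_hr_edii_sd=float(np.log(TARGET_HRS["edii_per_sd"])),
        log_hr_prs_intermediate=float(np.log(TARGET_HRS["prs_intermediate"])),
        log_hr_prs_high=float(np.log(TARGET_HRS["prs_high"])),
        edii_to_siri_slope=MEDIATION_PATHS["edii_to_siri_slope"],
    )


def recovery_config(effect: str, *, n: int = 20_000, seed: int = 0) -> GeneratorConfig:
    """Inflated-event-rate configuration with a single calibrated effect.

    ``effect`` selects which true effect drives the hazard:

    * ``"tertile"`` — E-DII tertile indicators (T3 HR 1.36, T2 1.11);
    * ``"per_sd"``  — continuous per-SD E-DII (HR 1.12);
    * ``"joint"``   — the 3x3 E-DII x PRS cell grid (high/high HR 3.04);
    * ``"prs"``     — PRS quintile groups (top HR 2.35);
    * ``"siri_step"`` — dichotomized SIRI at 1.22 (HR 1.57);
    * ``"mediation"`` — direct + SIRI-mediated paths (9.16% mediated);
    * ``"null"``    — no exposure effect (for calibration checks).

    Exclusion-flag probabilities are zeroed so the analysis table retains
    exactly the generated participants.
    """
    base = dict(
        n_participants=n,
        seed=seed,
        baseline_rate=RECOVERY_BASELINE_RATE,
        p_refused_followup=0.0,
        p_baseline_aaa=0.0,
        p_pregnant=0.0,
        p_missing_marker=0.0,
        p_missing_covariate=0.0,
    )
    if effect == "tertile":
        base.update(
            log_hr_edii_t2=float(np.log(TARGET_HRS["edii_t2"])),
            log_hr_edii_t3=float(np.log(TARGET_HRS["edii_t3"])),
        )
    elif effect == "per_sd":
        base.update(log_hr_edii_sd=float(np.log(TARGET_HRS["edii_per_sd"])))
    elif effect == "joint":
        base.update(joint_cell_log_hr=_JOINT_GRID)
    elif effect == "prs":
        base.update(
            log_hr_prs_intermediate=float(np.log(TARGET_HRS["prs_intermediate"])),
            log_hr_prs_high=float(np.log(TARGET_HRS["prs_high"])),
        )
    elif effect == "siri_step":
        base.update(
            siri_step_cut=SIRI_CUT,
            log_hr_siri_step=float(np.log(TARGET_HRS["siri_step"])),
        )
    elif effect == "mediation":
        base.update(
            log_hr_edii_sd=MEDIATION_PATHS["log_hr_edii_sd_direct"],
            log_hr_siri_sd=MEDIATION_PATHS["log_hr_siri_sd"],
            edii_to_siri_slope=MEDIATION_PATHS["edii_to_siri_slope"],
        )
    elif effect == "null":
        pass
    else:
        raise ValueError(f"unknown effect '{effect}'")
    return GeneratorConfig(**base)


def replicate_config(cfg: GeneratorConfig, seed: int) -> GeneratorConfig:
    """A copy of ``cfg`` with a new seed (for replicate loops)."""
    return dataclasses.replace(cfg, seed=seed)
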