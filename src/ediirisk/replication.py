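"""Effect-recovery harnesses on calibrated synthetic cohorts.

Each harness generates replicate cohorts whose true effect is pinned to the
study's reported estimate (see :mod:`ediirisk.calibration`), runs the
corresponding analysis, and summarises how well the fitted hazard ratios
recover the truth.  These are the package's replication experiments: the
original cohort data are not redistributable, so agreement is assessed
against the generator's known truth rather than against participant data.
"""

from __future__ import annotations

import numpy as np

from . import calibration
from .interaction import joint_effects, reri_from_loghr
from .mediation import mediate
from .survival import fit_cox, pruned_spec
from .synth_cohort import simulate_analysis_cohort, true_mediated_proportion

__all__ = ["recover_hr", "recover_mediation", "EFFECT_TERMS"]

# effect name -> (exposure coding, coefficient of interest, true HR)
EFFECT_TERMS = {
    "tertile": ("edii_tertile", "edii_tertile_T3", calibration.TARGET_HRS["edii_t3"]),
    "per_sd": ("edii_sd", "edii_sd", calibration.TARGET_HRS["edii_per_sd"]),
    "prs": ("prs_group", "prs_group_high", calibration.TARGET_HRS["prs_high"]),
}


def _rep_seeds(seed: int, n_reps: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_reps)]


def recover_hr(
    effect: str,
    *,
    n_reps: int = 40,
    n: int = 20_000,
    seed: int = 0,
    tier: int = 3,
) -> dict:
    """Replicate-averaged hazard-ratio recovery for one calibrated effect.

    ``effect`` is one of ``tertile | per_sd | prs | siri_step | joint``.
    Returns the per-replicate HRs, their mean, the generator truth, and the
    fraction of replicates whose 95% CI covered the truth.  For ``joint``
    the result additionally carries the RERI implied by the generator's
    corner cells and the delta-method RERI CI coverage.
    """
    seeds = _rep_seeds(seed, n_reps)
    hrs, covered = [], 0
    extra: dict = {}
    if effect == "joint":
        grid = np.asarray(calibration._JOINT_GRID)
        true_hr = float(np.exp(grid[2, 2]))
        # RERI of the corner cells implied by the generator grid
        true_reri = float(
            np.exp(grid[2, 2]) - np.exp(grid[2, 0]) - np.exp(grid[0, 2]) + 1.0
        )
        reri_covered = 0
        reris = []
        for s in seeds:
            cfg = calibration.recovery_config("joint", n=n, seed=s)
            cohort, _, _ = simulate_analysis_cohort(cfg)
            jt = joint_effects(cohort, pruned_spec(cohort, tier))
            tab = jt.table.set_index(["edii_group", "prs_group"])
            row = tab.loc[("T3", "high")]
            hrs.append(float(row["HR"]))
            if row["ci_lower"] <= true_hr <= row["ci_upper"]:
                covered += 1
            corner = ["cell_T3_low", "cell_T1_high", "cell_T3_high"]
            b = jt.fit.params[corner].to_numpy()
            v = jt.fit.covariance.loc[corner, corner].to_numpy()
            reri, (rlo, rhi) = reri_from_loghr(b, v)
            reris.append(reri)
            if rlo <= true_reri <= rhi:
                reri_covered += 1
        extra = {
            "true_reri": true_reri,
            "mean_reri": float(np.mean(reris)),
            "reri_ci_coverage": reri_covered / n_reps,
        }
    elif effect == "siri_step":
        true_hr = calibration.TARGET_HRS["siri_step"]
        for s in seeds:
            cfg = calibration.recovery_config("siri_step", n=n, seed=s)
            cohort, _, _ = simulate_analysis_cohort(cfg)
            cohort = cohort.copy()
            cohort["siri_high"] = (
                cohort["siri"] > calibration.SIRI_CUT
            ).astype(float)
            fit = fit_cox(cohort, pruned_spec(cohort, tier, "siri_high"))
            row = fit.hr_table.loc["siri_high"]
            hrs.append(float(row["HR"]))
            if row["ci_lower"] <= true_hr <= row["ci_upper"]:
                covered += 1
    else:
        exposure, term, true_hr = EFFECT_TERMS[effect]
        for s in seeds:
            cfg = calibration.recovery_config(effect, n=n, seed=s)
            cohort, _, _ = simulate_analysis_cohort(cfg)
            fit = fit_cox(cohort, pruned_spec(cohort, tier, exposure))
            row = fit.hr_table.loc[term]
            hrs.append(float(row["HR"]))
            if row["ci_lower"] <= true_hr <= row["ci_upper"]:
                covered += 1
    hrs_arr = np.asarray(hrs)
    return {
        "effect": effect,
        "true_hr": float(true_hr),
        "mean_hr": float(hrs_arr.mean()),
        "hrs": hrs,
        "ci_coverage": covered / n_reps,
        "n_reps": n_reps,
        "n": n,
        **extra,
    }


def recover_mediation(
    *,
    n_reps: int = 20,
    n: int = 20_000,
    seed: int = 0,
    n_sims: int = 1000,
    oracle_n: int = 600_000,
) -> dict:
    """Mediated-proportion recovery against the generator's own oracle.

    The large-n potential-outcome oracle evaluates the generator's true
    risk-difference-scale mediated proportion; each replicate runs the
    quasi-Bayesian estimator and the CI-coverage of the oracle value is
    tracked alongside the replicate mean.
    """
    seeds = _rep_seeds(seed, n_reps + 1)
    cfg0 = calibration.recovery_config("mediation", n=n, seed=seeds[-1])
    oracle = true_mediated_proportion(cfg0, n=oracle_n, seed=seeds[-1])
    props, covered = [], 0
    for s in seeds[:-1]:
        cfg = calibration.recovery_config("mediation", n=n, seed=s)
        cohort, _, _ = simulate_analysis_cohort(cfg)
        res = mediate(cohort, spec=pruned_spec(cohort, 3), n_sims=n_sims, seed=s)
        props.append(res.proportion_mediated)
        lo, hi = res.proportion_ci
        if lo <= oracle["proportion_mediated"] <= hi:
            covered += 1
    return {
        "oracle": oracle,
        "mean_proportion": float(np.mean(props)),
        "proportions": props,
        "ci_coverage": covered / n_reps,
        "n_reps": n_reps,
        "n": n,
        "n_sims": n_sims,
        "oracle_n": oracle_n,
    }
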