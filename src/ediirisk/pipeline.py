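"""Config-driven orchestration of the full analysis on a synthetic cohort.

Stages run in dependency order: cohort generation and exclusions, E-DII
scoring, blood indices, PRS, the three Cox model tiers, subgroup and
per-component scans, joint effects and additive interaction, mediation,
cutpoint selection, and the sensitivity reruns.  Every stage writes its
artifact (CSV or JSON) into the output directory and is recorded, with a
content hash, in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, calibration
from .cutpoint import bootstrap_cut_hr, maxstat_cutpoint
from .edii import default_reference, load_reference
from .errors import StageError
from .interaction import interaction_tests, joint_effects
from .mediation import mediate
from .survival import (
    ModelSpec,
    component_scan,
    fit_cox,
    km_curve,
    rcs_dose_response,
    schoenfeld_test,
    sensitivity_scan,
    subgroup_scan,
)
from .synth_cohort import GeneratorConfig, simulate_analysis_cohort

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = [
    "simulate", "edii", "indices", "prs", "cox", "subgroups",
    "component_scan", "joint", "reri", "mediation", "cutpoints", "sensitivity",
]

# stages that cannot run unless their upstream stage ran
_DEPENDENCIES = {
    "joint": "prs",
    "reri": "prs",
}


@dataclass
class PipelineConfig:
    """Inputs, stage toggles, seeds and the output directory of one run."""

    output_dir: str = "ediirisk_run"
    seed: int = 0
    n_participants: int = 20_000
    generator: GeneratorConfig | None = None
    reference_path: str | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    mediation_sims: int = 1000
    bootstrap_resamples: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest.

    A stage failure aborts the run with :class:`StageError`; artifacts from
    completed stages are preserved on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
        "warnings": [],
    }
    enabled = list(config.stages)
    for stage, dep in _DEPENDENCIES.items():
        if stage in enabled and dep not in enabled:
            msg = f"stage '{stage}' disabled: requires stage '{dep}'"
            logger.warning(msg)
            manifest["warnings"].append(msg)
            enabled.remove(stage)

    def _write_df(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest["artifacts"][path.name] = _hash_file(path)

    def _write_json(name: str, payload) -> None:
        path = out / f"{name}.json"
        path.write_text(
            payload if isinstance(payload, str) else json.dumps(payload, indent=2)
        )
        manifest["artifacts"][path.name] = _hash_file(path)

    gen = config.generator or calibration.study_config(
        n=config.n_participants, seed=config.seed
    )
    gen = dataclasses.replace(gen, seed=config.seed,
                              n_participants=config.n_participants)
    reference = (
        load_reference(config.reference_path)
        if config.reference_path
        else default_reference()
    )

    def _tier_spec(tier: int, exposure="edii_sd") -> ModelSpec:
        from .survival import pruned_spec, tier_covariates

        spec = pruned_spec(cohort, tier, exposure)
        for c in set(tier_covariates(tier)) - set(spec.covariates):
            manifest["warnings"].append(
                f"sparse covariate '{c}' dropped from tier {tier}"
            )
        return spec

    stage = "simulate"
    try:
        cohort, excl_log, densities = simulate_analysis_cohort(
            gen, reference=reference
        )
        _write_df("cohort", cohort)
        _write_json("exclusions", excl_log.to_json())
        manifest["n_raw"] = excl_log.raw_n
        manifest["n_analysis"] = len(cohort)
        manifest["events"] = int(cohort["event"].sum())
        manifest["stages"].append(stage)

        if "edii" in enabled:
            stage = "edii"
            _write_df(
                "edii_scores",
                cohort[["participant_id", "edii", "edii_sd", "edii_tertile"]],
            )
            manifest["stages"].append(stage)

        if "indices" in enabled:
            stage = "indices"
            _write_df(
                "indices",
                cohort[["participant_id", "siri", "sii", "pni", "conut"]],
            )
            manifest["stages"].append(stage)

        if "prs" in enabled:
            stage = "prs"
            _write_df("prs", cohort[["participant_id", "prs", "prs_group"]])
            manifest["stages"].append(stage)

        if "cox" in enabled:
            stage = "cox"
            rows = []
            for tier in (1, 2, 3):
                tert = fit_cox(cohort, _tier_spec(tier, "edii_tertile"))
                sd = fit_cox(cohort, _tier_spec(tier))
                row = {"model": f"Model {tier}", "T1": "1 (reference)"}
                for lev in ("T2", "T3"):
                    r = tert.hr_table.loc[f"edii_tertile_{lev}"]
                    row[lev] = (
                        f"{r['HR']:.2f} ({r['ci_lower']:.2f}-{r['ci_upper']:.2f})"
                    )
                r = sd.hr_table.loc["edii_sd"]
                row["per_SD"] = (
                    f"{r['HR']:.2f} ({r['ci_lower']:.2f}-{r['ci_upper']:.2f})"
                )
                row["p_per_SD"] = r["p"]
                row["c_index"] = sd.c_index
                row["bic"] = sd.bic
                rows.append(row)
                if tier == 3:
                    ph = schoenfeld_test(sd)
                    _write_df("schoenfeld", ph.reset_index(names="term"))
                    spl = rcs_dose_response(cohort, "edii", _tier_spec(3))
                    _write_df("spline_curve", spl.curve)
                    _write_json(
                        "spline_test",
                        {
                            "nonlinearity_chi2": spl.nonlinearity_stat,
                            "nonlinearity_p": spl.nonlinearity_p,
                            "knots": list(spl.knots),
                        },
                    )
            _write_df("cox_tiers", pd.DataFrame(rows))
            curves, logrank_p = km_curve(cohort, "edii_tertile")
            _write_df("km_curves", curves)
            _write_json("km_logrank", {"p": logrank_p})
            manifest["stages"].append(stage)

        if "subgroups" in enabled:
            stage = "subgroups"
            _write_df("subgroups", subgroup_scan(cohort, _tier_spec(3)))
            manifest["stages"].append(stage)

        if "component_scan" in enabled:
            stage = "component_scan"
            _write_df(
                "component_scan",
                component_scan(cohort, densities, _tier_spec(3)),
            )
            manifest["stages"].append(stage)

        if "joint" in enabled:
            stage = "joint"
            jt = joint_effects(cohort, _tier_spec(3))
            _write_df("joint_effects", jt.table)
            manifest["stages"].append(stage)

        if "reri" in enabled:
            stage = "reri"
            res = interaction_tests(
                cohort,
                _tier_spec(3),
                edii_high=(cohort["edii_tertile"] == "T3"),
                prs_high=(cohort["prs_group"] == "high"),
            )
            _write_json("interaction", res.to_json())
            manifest["stages"].append(stage)

        if "mediation" in enabled:
            stage = "mediation"
            med = mediate(
                cohort, spec=_tier_spec(3),
                n_sims=config.mediation_sims, seed=config.seed,
            )
            _write_json("mediation", med.to_json())
            manifest["stages"].append(stage)

        if "cutpoints" in enabled:
            stage = "cutpoints"
            cut_results = {}
            for var in ("edii", "prs", "siri"):
                res = maxstat_cutpoint(
                    cohort[var].to_numpy(),
                    cohort["time"].to_numpy(),
                    cohort["event"].to_numpy(),
                    variable=var,
                )
                _write_df(f"cutpoint_trace_{var}", res.trace)
                boot = bootstrap_cut_hr(
                    cohort, var, res.cutpoint, _tier_spec(3),
                    n_boot=config.bootstrap_resamples, seed=config.seed,
                )
                cut_results[var] = {
                    "cutpoint": res.cutpoint,
                    "statistic": res.statistic,
                    "p_adjusted": res.p_adjusted,
                    "bootstrap": boot,
                }
            _write_json("cutpoints", cut_results)
            manifest["stages"].append(stage)

        if "sensitivity" in enabled:
            stage = "sensitivity"
            work = cohort.copy()
            _write_df(
                "sensitivity",
                sensitivity_scan(work, _tier_spec(3)),
            )
            manifest["stages"].append(stage)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    _write_json("generator_config", gen.to_json())
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return manifest
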