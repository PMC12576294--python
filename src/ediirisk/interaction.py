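"""Joint diet x genetic-risk effects and additive/multiplicative interaction.

The joint-effect analysis crosses E-DII tertiles with polygenic risk groups
(low / intermediate / high) in a single Cox model whose reference cell is
low genetic risk + lowest dietary inflammation; each remaining cell gets an
indicator, so cell hazard ratios are read directly off the coefficients.

Additive interaction is summarised by the relative excess risk due to
interaction, RERI = HR11 - HR10 - HR01 + 1, with a delta-method CI from the
joint covariance of the three log-hazard ratios (and an optional
nonparametric bootstrap).  Multiplicative interaction is the Wald test on a
cross-product term.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConvergenceError
from .survival import CoxFit, ModelSpec, fit_cox

__all__ = [
    "JointEffectTable",
    "InteractionResult",
    "joint_effects",
    "interaction_tests",
    "reri_from_loghr",
]

logger = logging.getLogger(__name__)


@dataclass
class JointEffectTable:
    """Per-cell hazard ratios for the exposure x genetic-risk grid."""

    table: pd.DataFrame  # rows: (edii_group, prs_group), HR/CI/n/events
    fit: CoxFit
    edii_col: str
    prs_col: str


@dataclass
class InteractionResult:
    """Multiplicative (product-term) and additive (RERI) interaction."""

    product_hr: float
    product_ci: tuple
    product_p: float
    reri: float
    reri_ci: tuple
    reri_ci_bootstrap: tuple | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, default=lambda o: list(o), indent=2)


def joint_effects(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    *,
    edii_col: str = "edii_tertile",
    prs_col: str = "prs_group",
) -> JointEffectTable:
    """Single Cox fit with joint-category indicators (reference cell omitted).

    Cells with no participants are reported with ``n = 0`` and no estimate.
    """
    edii_levels = list(pd.Categorical(cohort[edii_col]).categories)
    prs_levels = list(pd.Categorical(cohort[prs_col]).categories)
    ref = (edii_levels[0], prs_levels[0])
    work = cohort.copy()
    cells = [(e, g) for e in edii_levels for g in prs_levels]
    ind_cols = []
    for e, g in cells:
        if (e, g) == ref:
            continue
        col = f"cell_{e}_{g}"
        work[col] = (
            (work[edii_col] == e) & (work[prs_col] == g)
        ).astype(float)
        ind_cols.append(col)
    covs = [
        c for c in spec.resolved_covariates() if c not in (edii_col, prs_col)
    ]
    nonempty = [c for c in ind_cols if work[c].sum() > 0]
    fit = fit_cox(
        work,
        ModelSpec(tier=spec.tier, exposure=nonempty, covariates=covs,
                  ties=spec.ties, strata=spec.strata),
    )
    rows = []
    for e, g in cells:
        mask = (work[edii_col] == e) & (work[prs_col] == g)
        n_cell = int(mask.sum())
        events = int(work.loc[mask, "event"].sum())
        col = f"cell_{e}_{g}"
        if (e, g) == ref:
            rows.append({"edii_group": e, "prs_group": g, "n": n_cell,
                         "events": events, "HR": 1.0, "ci_lower": 1.0,
                         "ci_upper": 1.0, "p": np.nan})
        elif col in fit.hr_table.index:
            r = fit.hr_table.loc[col]
            rows.append({"edii_group": e, "prs_group": g, "n": n_cell,
                         "events": events, "HR": r["HR"],
                         "ci_lower": r["ci_lower"], "ci_upper": r["ci_upper"],
                         "p": r["p"]})
        else:
            rows.append({"edii_group": e, "prs_group": g, "n": n_cell,
                         "events": events, "HR": np.nan, "ci_lower": np.nan,
                         "ci_upper": np.nan, "p": np.nan})
    return JointEffectTable(
        table=pd.DataFrame(rows), fit=fit, edii_col=edii_col, prs_col=prs_col
    )


def reri_from_loghr(
    beta: np.ndarray, cov: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple]:
    """RERI and delta-method CI from (b10, b01, b11) log-HRs and covariance.

    RERI = exp(b11) - exp(b10) - exp(b01) + 1; the gradient w.r.t. the three
    log-HRs is (-exp(b10), -exp(b01), exp(b11)).
    """
    b10, b01, b11 = (float(b) for b in beta)
    reri = np.exp(b11) - np.exp(b10) - np.exp(b01) + 1.0
    grad = np.array([-np.exp(b10), -np.exp(b01), np.exp(b11)])
    var = float(grad @ np.asarray(cov, dtype=float) @ grad)
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(reri), (float(reri - half), float(reri + half))


def interaction_tests(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    *,
    edii_high: pd.Series,
    prs_high: pd.Series,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> InteractionResult:
    """Multiplicative and additive interaction for two binary exposures.

    ``edii_high`` and ``prs_high`` are boolean/0-1 indicators (e.g. top
    tertile and top quintile).  The Cox model includes both indicators, their
    product and the tier covariates; the product-term HR tests departure from
    multiplicativity and RERI from additivity of excess risks.
    """
    work = cohort.copy()
    work["_e"] = np.asarray(edii_high, dtype=float)
    work["_g"] = np.asarray(prs_high, dtype=float)
    work["_eg"] = work["_e"] * work["_g"]
    covs = spec.resolved_covariates()
    fit = fit_cox(
        work,
        ModelSpec(tier=spec.tier, exposure=["_e", "_g", "_eg"],
                  covariates=covs, ties=spec.ties),
    )
    prod = fit.hr_table.loc["_eg"]
    # log-HRs of the three non-reference cells of the implied 2x2 table
    cell_terms = [["_e"], ["_g"], ["_e", "_g", "_eg"]]
    contrast = np.zeros((3, len(fit.params)))
    names = list(fit.params.index)
    for i, terms in enumerate(cell_terms):
        for t in terms:
            contrast[i, names.index(t)] = 1.0
    b = contrast @ fit.params.to_numpy()
    v = contrast @ fit.covariance.to_numpy() @ contrast.T
    reri, reri_ci = reri_from_loghr(b, v)

    boot_ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        stats = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(work), len(work))
            sample = work.iloc[idx]
            try:
                f = fit_cox(
                    sample,
                    ModelSpec(tier=spec.tier, exposure=["_e", "_g", "_eg"],
                              covariates=covs, ties=spec.ties),
                )
            except (ConvergenceError, np.linalg.LinAlgError) as exc:
                logger.debug("bootstrap resample skipped: %s", exc)
                continue
            bb = contrast @ f.params.reindex(names).to_numpy()
            stats.append(np.exp(bb[2]) - np.exp(bb[0]) - np.exp(bb[1]) + 1.0)
        if stats:
            boot_ci = tuple(np.percentile(stats, [2.5, 97.5]))
    return InteractionResult(
        product_hr=float(prod["HR"]),
        product_ci=(float(prod["ci_lower"]), float(prod["ci_upper"])),
        product_p=float(prod["p"]),
        reri=reri,
        reri_ci=reri_ci,
        reri_ci_bootstrap=boot_ci,
    )
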