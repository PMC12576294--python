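"""Polygenic risk scores: weighted sums, clumping+thresholding, risk groups.

Three PRS flavours are supported, distinguished only by where the per-variant
effect sizes come from (an ``EffectTable``):

* ``weighted34`` — a small set of genome-wide significant SNPs with published
  effect sizes;
* ``external_posterior`` — posterior effect sizes produced by an external
  Bayesian continuous-shrinkage tool, ingested as a precomputed table;
* ``ct`` — clumping-and-thresholding output of :func:`clump_and_threshold`.

In every case the score is the allele-dosage-weighted sum
``score_j = sum_i dosage_ji * beta_i`` after allele harmonization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score

from .errors import DegenerateScoreError, HarmonizationError, UndefinedMetricError

__all__ = [
    "weighted_prs",
    "clump_and_threshold",
    "assign_risk_groups",
    "evaluate_prs",
    "load_effect_table",
]

logger = logging.getLogger(__name__)

EFFECT_COLUMNS = ["id", "chr", "pos", "a1", "a2", "beta", "p"]


def load_effect_table(path) -> pd.DataFrame:
    """Read a tab-delimited effect table (id, chr, pos, a1, a2, beta, p)."""
    tab = pd.read_csv(path, sep="\t")
    missing = set(EFFECT_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"effect table missing columns: {sorted(missing)}")
    return tab


def weighted_prs(
    dosages: pd.DataFrame,
    effects: pd.DataFrame,
    *,
    counted_alleles: dict[str, tuple[str, str]] | None = None,
) -> pd.Series:
    """Dosage-weighted PRS: multiply risk-allele dosages by effect sizes and sum.

    ``dosages`` is participants x variants (columns named by variant id,
    values in [0, 2] counting copies of the dosage's counted allele).
    ``counted_alleles`` maps variant id -> (counted allele, other allele) for
    the dosage matrix; when omitted, dosages are assumed to count the effect
    allele ``a1`` of ``effects``.  When the counted allele is the effect
    table's *other* allele, the effect sign is flipped; any variant whose
    allele pair cannot be matched raises :class:`HarmonizationError`.

    Missing dosages are imputed to the variant's observed mean (twice the
    allele frequency).
    """
    effects = effects.set_index("id", drop=False)
    ids = [v for v in effects["id"] if v in dosages.columns]
    absent = [v for v in effects["id"] if v not in dosages.columns]
    if absent:
        raise HarmonizationError(absent)
    beta = effects.loc[ids, "beta"].to_numpy(dtype=float).copy()
    if counted_alleles is not None:
        bad = []
        for k, vid in enumerate(ids):
            counted, other = counted_alleles[vid]
            a1, a2 = effects.loc[vid, "a1"], effects.loc[vid, "a2"]
            if counted == a1 and other == a2:
                pass
            elif counted == a2 and other == a1:
                beta[k] = -beta[k]
            else:
                bad.append(vid)
        if bad:
            raise HarmonizationError(bad)
    x = dosages[ids].to_numpy(dtype=float)
    if np.isnan(x).any():
        col_mean = np.nanmean(x, axis=0)
        nan_r, nan_c = np.where(np.isnan(x))
        x[nan_r, nan_c] = col_mean[nan_c]
    return pd.Series(x @ beta, index=dosages.index, name="prs")


def clump_and_threshold(
    effects: pd.DataFrame,
    ld: pd.DataFrame | None,
    *,
    p_max: float,
    r2_max: float = 0.1,
    window_kb: float = 1000.0,
) -> pd.DataFrame:
    """Greedy LD clumping with a p-value threshold.

    Variants with p <= ``p_max`` are visited in ascending p order (ties broken
    by id); a variant is accepted iff no previously accepted variant on the
    same chromosome lies within ``window_kb`` kilobases with pairwise
    r^2 > ``r2_max``.  ``ld`` is a square r^2 frame indexed by variant id;
    missing pairs are treated as r^2 = 0 with a logged warning.
    """
    kept_rows = []
    cand = effects.loc[effects["p"] <= p_max].copy()
    cand = cand.sort_values(["p", "id"], kind="mergesort")
    window_bp = window_kb * 1000.0
    warned = False
    for _, row in cand.iterrows():
        ok = True
        for kept in kept_rows:
            if kept["chr"] != row["chr"]:
                continue
            if abs(kept["pos"] - row["pos"]) > window_bp:
                continue
            r2 = None
            if ld is not None and row["id"] in ld.index and kept["id"] in ld.columns:
                r2 = ld.loc[row["id"], kept["id"]]
            if r2 is None or pd.isna(r2):
                if not warned:
                    logger.warning(
                        "missing LD entry (e.g. %s-%s); assuming r2=0",
                        row["id"], kept["id"],
                    )
                    warned = True
                r2 = 0.0
            if r2 > r2_max:
                ok = False
                break
        if ok:
            kept_rows.append(row)
    out = pd.DataFrame(kept_rows, columns=effects.columns)
    return out.reset_index(drop=True)


def assign_risk_groups(scores: pd.Series) -> pd.Series:
    """Quintile-based genetic risk groups.

    low = bottom quintile, intermediate = quintiles 2-4, high = top quintile,
    with cuts at the empirical 20th and 80th percentiles.  A score equal to a
    cut goes to the lower group (deterministic tie rule).
    """
    if len(scores) < 5:
        raise DegenerateScoreError("need at least 5 participants for quintiles")
    s = scores.to_numpy(dtype=float)
    if np.nanstd(s) == 0:
        raise DegenerateScoreError("polygenic score has zero variance")
    q20, q80 = np.quantile(s, [0.2, 0.8])
    labels = np.where(s <= q20, "low", np.where(s <= q80, "intermediate", "high"))
    return pd.Series(
        pd.Categorical(labels, categories=["low", "intermediate", "high"]),
        index=scores.index,
        name="prs_group",
    )


def evaluate_prs(
    scores: pd.Series, event: pd.Series, time: pd.Series
) -> tuple[float, float]:
    """Discrimination of a PRS: (AUC on event status, Harrell C-index).

    AUC is the rank statistic with half credit for ties; the C-index is
    Harrell's concordance over censoring-comparable pairs (also half credit
    for tied predictions).
    """
    y = np.asarray(event, dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedMetricError("need at least one event and one non-event")
    auc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    # lifelines expects higher prediction = longer survival; a PRS is a risk
    # score, so concordance is taken against the negated score
    cindex = float(
        concordance_index(time, -np.asarray(scores, dtype=float), event_observed=y)
    )
    return auc, cindex
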