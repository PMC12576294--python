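"""Optimal survival cutpoints via maximally selected rank statistics.

For a continuous marker ``x`` the two-sample log-rank statistic is computed
at every candidate cutpoint inside a quantile search range (10th-90th
percentile by default) and the cut with the maximal standardized statistic
is selected.  Because the maximum is taken over many correlated statistics,
the naive pointwise p-value is anti-conservative; the selection-adjusted
p-value uses the Lausen-Schumacher improved-Bonferroni approximation for
the maximum of the standardized Brownian-bridge process, with an exact
permutation option.

The log-rank statistic is evaluated through its rank-score representation:
each subject contributes the score ``a_i = delta_i - Lambda(t_i)`` (event
indicator minus Nelson-Aalen cumulative hazard at the observed time), and
the two-sample statistic at cut ``c`` is the standardized sum of scores in
the ``x <= c`` group under the permutation variance.  This makes the whole
scan O(n log n) and the maximum invariant to strictly monotone transforms
of ``x``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import CutpointRangeError
from .survival import ModelSpec, fit_cox

__all__ = ["CutpointResult", "maxstat_cutpoint", "bootstrap_cut_hr"]

logger = logging.getLogger(__name__)


@dataclass
class CutpointResult:
    """Selected cutpoint, max statistic, adjusted p and the candidate trace."""

    variable: str
    cutpoint: float
    statistic: float
    p_adjusted: float
    p_pointwise: float
    search_range: tuple
    trace: pd.DataFrame  # columns: cut, statistic
    method: str = "lausen-schumacher"
    n_permutations: int = 0
    seed: int | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["trace"] = None  # exported separately as CSV
        return json.dumps(d, default=lambda o: list(o), indent=2)


def _logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject log-rank scores: event indicator minus Nelson-Aalen at t_i."""
    order = np.argsort(time, kind="mergesort")
    t_sorted = time[order]
    e_sorted = event[order]
    n = len(time)
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    # deaths and at-risk counts per unique time
    deaths = np.zeros(len(uniq))
    np.add.at(deaths, np.searchsorted(uniq, t_sorted), e_sorted)
    at_risk = n - first_idx
    increments = deaths / at_risk
    cum_haz = np.cumsum(increments)
    scores = event - cum_haz[np.searchsorted(uniq, time)]
    return scores


def _scan(x, scores, cuts):
    """Standardized score-sum statistic at each cut (x <= cut group)."""
    n = len(x)
    a_bar = scores.mean()
    ss = float(np.sum((scores - a_bar) ** 2))
    order = np.argsort(x, kind="mergesort")
    x_sorted = x[order]
    cum_scores = np.cumsum(scores[order])
    # number of subjects with x <= cut
    n1 = np.searchsorted(x_sorted, cuts, side="right")
    s = cum_scores[n1 - 1]
    mean_s = n1 * a_bar
    var_s = n1 * (n - n1) / (n * (n - 1)) * ss
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (s - mean_s) / np.sqrt(var_s)
    return z


def maxstat_cutpoint(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    *,
    variable: str = "x",
    q_low: float = 0.10,
    q_high: float = 0.90,
    correction: str = "lausen-schumacher",
    n_permutations: int = 1000,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected log-rank statistic over candidate cutpoints.

    Candidates are the distinct values of ``x`` whose split proportions fall
    inside ``[q_low, q_high]``.  ``correction`` is either
    ``"lausen-schumacher"`` (improved-Bonferroni approximation, default) or
    ``"permutation"`` (``n_permutations`` label permutations).

    Raises :class:`CutpointRangeError` when fewer than 2 candidate cuts lie
    inside the search range.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lo, hi = np.quantile(x, [q_low, q_high])
    cuts = np.unique(x)
    cuts = cuts[(cuts >= lo) & (cuts <= hi) & (cuts < np.max(x))]
    if len(cuts) < 2:
        raise CutpointRangeError(
            f"only {len(cuts)} candidate cutpoints in [{lo:.4g}, {hi:.4g}]"
        )
    scores = _logrank_scores(time, event)
    z = _scan(x, scores, cuts)
    absz = np.abs(z)
    best = int(np.nanargmax(absz))
    b = float(absz[best])
    p_point = float(2 * norm.sf(b))

    if correction == "lausen-schumacher":
        # improved Bonferroni bound for the max of |B(t)/sqrt(t(1-t))| over
        # t in [q_low, q_high] (Lausen & Schumacher approximation)
        q1, q2 = q_low, q_high
        log_term = np.log((q2 * (1 - q1)) / (q1 * (1 - q2)))
        p_adj = norm.pdf(b) * (b - 1.0 / b) * log_term + 4.0 * norm.pdf(b) / b
        p_adj = float(np.clip(p_adj, p_point, 1.0))
        n_perm_used = 0
    elif correction == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(x))
            zp = _scan(x[perm], scores, cuts)
            if np.nanmax(np.abs(zp)) >= b:
                count += 1
        p_adj = float((count + 1) / (n_permutations + 1))
        p_adj = float(max(p_adj, p_point))
        n_perm_used = n_permutations
    else:
        raise ValueError(f"unknown correction '{correction}'")

    return CutpointResult(
        variable=variable,
        cutpoint=float(cuts[best]),
        statistic=b,
        p_adjusted=p_adj,
        p_pointwise=p_point,
        search_range=(float(lo), float(hi)),
        trace=pd.DataFrame({"cut": cuts, "statistic": z}),
        method=correction,
        n_permutations=n_perm_used,
        seed=seed if correction == "permutation" else None,
    )


def bootstrap_cut_hr(
    cohort: pd.DataFrame,
    variable: str,
    cutpoint: float,
    spec: ModelSpec,
    *,
    n_boot: int = 200,
    seed: int = 0,
    min_events_per_side: int = 2,
) -> dict:
    """Bootstrap stability of the dichotomized-variable hazard ratio.

    Resamples participants with replacement, refits the Cox model defined by
    ``spec`` on the ``variable > cutpoint`` indicator, and reports the median and
    2.5/97.5 percentiles of the HR across non-degenerate resamples.
    Resamples with fewer than ``min_events_per_side`` events on either side
    of the cut are skipped and counted; more than 20% skips trigger an
    instability warning.
    """
    rng = np.random.default_rng(seed)
    work = cohort.copy()
    hrs = []
    skipped = 0
    covs = spec.resolved_covariates()
    for _ in range(n_boot):
        idx = rng.integers(0, len(work), len(work))
        sample = work.iloc[idx].copy()
        sample["_above"] = (sample[variable] > cutpoint).astype(float)
        ev = sample.groupby("_above")["event"].sum()
        if (
            len(ev) < 2
            or (ev < min_events_per_side).any()
        ):
            skipped += 1
            continue
        try:
            f = fit_cox(
                sample,
                ModelSpec(tier=spec.tier, exposure="_above",
                          covariates=covs, ties=spec.ties),
            )
        except Exception as exc:  # degenerate resample (separation etc.)
            logger.debug("bootstrap resample failed: %s", exc)
            skipped += 1
            continue
        hrs.append(float(f.hr_table.loc["_above", "HR"]))
    unstable = skipped > 0.2 * n_boot
    if unstable:
        logger.warning(
            "%d/%d degenerate bootstrap resamples; estimates unstable",
            skipped, n_boot,
        )
    med, lo, hi = (
        np.percentile(hrs, [50, 2.5, 97.5]) if hrs else (np.nan,) * 3
    )
    return {
        "variable": variable,
        "cutpoint": float(cutpoint),
        "median_hr": float(med),
        "ci_lower": float(lo),
        "ci_upper": float(hi),
        "n_boot": n_boot,
        "n_skipped": skipped,
        "unstable": bool(unstable),
        "seed": seed,
    }
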