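"""Tiered Cox proportional-hazards modelling and diagnostics.

Model tiers nest progressively richer adjustment sets:

* tier 1 — demographics and socioeconomics: age, sex, education, employment,
  Townsend deprivation index, BMI;
* tier 2 — tier 1 plus baseline comorbidities, medication count and vitamin
  supplement use;
* tier 3 — tier 2 plus lifestyle (smoking, physical activity, sleep pattern,
  sedentary time).

The default fitter is an in-package Newton-Raphson maximizer of the
Breslow partial likelihood (vectorized over risk sets; step-halving keeps
the likelihood non-decreasing); Efron tie handling and stratified fits are
delegated to :class:`statsmodels.PHReg`.  On top of the fitter this module
provides design-matrix construction, fit statistics (Harrell C-index, BIC
with the number of events as the penalty sample size), proportional-hazards
diagnostics on scaled Schoenfeld residuals, Kaplan-Meier curves,
restricted-cubic-spline dose-response, subgroup scans and per-component
association scans.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import linalg
from scipy.stats import chi2, norm

from .errors import (
    CollinearityError,
    ConvergenceError,
    SplineUnavailableError,
)

__all__ = [
    "ModelSpec",
    "CoxFit",
    "SplineFit",
    "tier_covariates",
    "fit_cox",
    "schoenfeld_test",
    "km_curve",
    "rcs_basis",
    "rcs_dose_response",
    "subgroup_scan",
    "component_scan",
    "sensitivity_scan",
]

logger = logging.getLogger(__name__)

CATEGORICAL = {
    "activity": ["low", "moderate", "high"],
    "sleep": ["poor", "moderate", "good"],
    "sedentary": ["high", "moderate", "low"],
    "edii_tertile": ["T1", "T2", "T3"],
    "prs_group": ["low", "intermediate", "high"],
}

_TIER1 = ["age", "male", "degree", "employed", "townsend", "bmi"]
_TIER2 = _TIER1 + [
    "hypertension", "diabetes", "dyslipidemia", "cardiovascular", "cancer",
    "chronic_respiratory", "chronic_kidney", "chronic_liver",
    "n_medications", "vitamin_use",
]
_TIER3 = _TIER2 + ["smoker", "activity", "sleep", "sedentary"]


def tier_covariates(tier: int) -> list[str]:
    """Adjustment set for a model tier (1, 2 or 3); tiers nest."""
    return {1: list(_TIER1), 2: list(_TIER2), 3: list(_TIER3)}[tier]


@dataclass
class ModelSpec:
    """Specification of one Cox model tier.

    ``exposure`` names the exposure coding: ``"edii_tertile"`` (indicator
    coding, T1 reference), ``"edii_sd"`` (per-SD continuous) or any cohort
    column(s).
    """

    tier: int = 3
    exposure: str | list[str] = "edii_sd"
    covariates: list[str] | None = None
    ties: str = "breslow"
    strata: list[str] | None = None

    def resolved_covariates(self) -> list[str]:
        if self.covariates is not None:
            return list(self.covariates)
        return tier_covariates(self.tier)


def pruned_spec(
    cohort: pd.DataFrame,
    tier: int,
    exposure: str | list[str] = "edii_sd",
    *,
    min_carriers: int = 10,
    min_carrier_events: int = 3,
) -> ModelSpec:
    """Tier spec with sparse binary covariates pruned.

    A binary flag with very few carriers, or with no events among carriers,
    makes the Cox partial likelihood monotone in that coefficient; such
    columns (e.g. rare comorbidities in a small cohort) are dropped with a
    warning before fitting.
    """
    covs = []
    for c in tier_covariates(tier):
        col = cohort[c]
        if set(col.unique()) <= {0, 1}:
            carriers = col == 1
            if (
                carriers.sum() < min_carriers
                or cohort.loc[carriers, "event"].sum() < min_carrier_events
            ):
                logger.warning("sparse covariate '%s' dropped from tier %d",
                               c, tier)
                continue
        covs.append(c)
    return ModelSpec(tier=tier, exposure=exposure, covariates=covs)


@dataclass
class CoxFit:
    """A fitted Cox model: coefficients, covariance, HR table, fit stats."""

    params: pd.Series
    covariance: pd.DataFrame
    hr_table: pd.DataFrame  # columns HR, ci_lower, ci_upper, p
    log_likelihood: float
    c_index: float
    bic: float
    n: int
    events: int
    baseline: tuple = field(repr=False)  # (event times, cumulative hazard)
    data: pd.DataFrame = field(repr=False)
    duration_col: str = "time"
    event_col: str = "event"

    def baseline_cumulative_hazard_at(self, t: float) -> float:
        """Breslow baseline cumulative hazard H0(t) (all covariates at 0)."""
        times, cumhaz = self.baseline
        pos = np.searchsorted(times, t, side="right") - 1
        return float(cumhaz[pos]) if pos >= 0 else 0.0


def _breslow_newton(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, float, tuple]:
    """Newton-Raphson maximization of the Breslow partial likelihood.

    Returns ``(beta, covariance, log_partial_likelihood, baseline)`` where
    ``baseline`` is the Breslow estimate of the cumulative hazard at the
    distinct event times (covariates at zero).  Step-halving keeps the
    partial likelihood non-decreasing across iterations; a diverging
    coefficient (monotone likelihood) raises :class:`ConvergenceError`.
    """
    order = np.argsort(time, kind="mergesort")
    xs = np.ascontiguousarray(x[order], dtype=float)
    ts = time[order]
    es = event[order] == 1
    n, p = xs.shape
    # risk sets include every subject with t_j >= t_i, ties included
    first = np.searchsorted(ts, ts, side="left")
    ev_idx = np.flatnonzero(es)
    ev_first = first[ev_idx]
    starts, deaths = np.unique(ev_first, return_counts=True)
    grp = np.searchsorted(starts, ev_first)  # event -> tied group index
    x_ev_sum = xs[ev_idx].sum(axis=0)
    d_groups = len(starts)

    def risk_sums(w):
        """Suffix sums of w and w*x evaluated at each event-group start."""
        s0 = np.cumsum(np.add.reduceat(w, starts)[::-1])[::-1]
        s1 = np.cumsum(
            np.add.reduceat(w[:, None] * xs, starts, axis=0)[::-1], axis=0
        )[::-1]
        return s0, s1

    def loglik(beta):
        eta = xs @ beta
        m = eta.max()
        w = np.exp(eta - m)
        s0, _ = risk_sums(w)
        return float(
            (xs[ev_idx] @ beta).sum() - ((np.log(s0[grp]) + m) * 1.0).sum()
        ), w, s0

    beta = np.zeros(p)
    ll, w, s0 = loglik(beta)
    for _ in range(max_iter):
        _, s1 = risk_sums(w)
        # suffix sums of w x x^T at group starts, accumulated segment-wise
        wx = w[:, None] * xs
        s2 = np.empty((d_groups, p, p))
        acc = np.zeros((p, p))
        bounds = list(starts) + [n]
        for k in range(d_groups - 1, -1, -1):
            seg = slice(bounds[k], bounds[k + 1])
            acc = acc + wx[seg].T @ xs[seg]
            s2[k] = acc
        s0e = s0[grp]
        mean_x = s1[grp] / s0e[:, None]
        grad = x_ev_sum - mean_x.sum(axis=0)
        info = (s2[grp] / s0e[:, None, None]).sum(axis=0) - np.einsum(
            "ij,ik->jk", mean_x, mean_x
        )
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix (separation?): {exc}"
            ) from exc
        scale = 1.0
        for _ in range(30):  # step-halving: partial likelihood never decreases
            cand = beta + scale * step
            ll_c, w_c, s0_c = loglik(cand)
            if ll_c >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, w, s0 = cand, ll_c, w_c, s0_c
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "diverging coefficient (monotone partial likelihood?)"
            )
        if np.max(np.abs(scale * step)) < tol:
            break
    else:
        if np.max(np.abs(grad)) > 1e-6 * max(1, len(ev_idx)):
            raise ConvergenceError("Newton iterations did not converge")

    # covariance and Breslow baseline at the optimum
    _, s1 = risk_sums(w)
    wx = w[:, None] * xs
    s2 = np.empty((d_groups, p, p))
    acc = np.zeros((p, p))
    bounds = list(starts) + [n]
    for k in range(d_groups - 1, -1, -1):
        seg = slice(bounds[k], bounds[k + 1])
        acc = acc + wx[seg].T @ xs[seg]
        s2[k] = acc
    s0e = s0[grp]
    mean_x = s1[grp] / s0e[:, None]
    info = (s2[grp] / s0e[:, None, None]).sum(axis=0) - np.einsum(
        "ij,ik->jk", mean_x, mean_x
    )
    cov = np.linalg.inv(info)
    m = (xs @ beta).max()
    increments = deaths / (s0[np.arange(d_groups)] * np.exp(m))
    baseline = (ts[starts], np.cumsum(increments))
    return beta, cov, ll, baseline


@dataclass
class SplineFit:
    """Restricted-cubic-spline dose-response summary."""

    knots: np.ndarray
    reference: float
    curve: pd.DataFrame  # x, hr, ci_lower, ci_upper
    nonlinearity_stat: float
    nonlinearity_p: float
    cox: "CoxFit"


def _expand(cohort: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Dummy-code known categorical columns (first level is the reference)."""
    out = {}
    for col in columns:
        if col in CATEGORICAL:
            levels = CATEGORICAL[col]
            vals = pd.Categorical(cohort[col], categories=levels)
            for lev in levels[1:]:
                out[f"{col}_{lev}"] = (vals == lev).astype(float)
        else:
            out[col] = cohort[col].astype(float)
    return pd.DataFrame(out, index=cohort.index)


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, _, piv = linalg.qr(x, pivoting=True, mode="economic")
        bad = [design.columns[j] for j in piv[rank:]]
        raise CollinearityError(bad)


def fit_cox(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    *,
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Maximize the Cox partial likelihood for one model tier.

    Raises :class:`CollinearityError` on a rank-deficient design and
    :class:`ConvergenceError` when the partial likelihood is monotone
    (complete separation) or Newton iterations fail.
    """
    exposures = [spec.exposure] if isinstance(spec.exposure, str) else list(spec.exposure)
    cols = exposures + [c for c in spec.resolved_covariates() if c not in exposures]
    design = _expand(cohort, cols)
    if int(cohort[event_col].sum()) < 2:
        raise ConvergenceError("need at least 2 events to fit a Cox model")
    _check_rank(design)
    df = design.copy()
    df[duration_col] = cohort[duration_col].to_numpy(dtype=float)
    df[event_col] = cohort[event_col].to_numpy(dtype=int)
    strata = None
    if spec.strata:
        strata = (
            cohort[spec.strata].astype(str).agg("|".join, axis=1).to_numpy()
        )
    events = int(df[event_col].sum())
    if spec.ties == "breslow" and strata is None:
        beta, cov_arr, ll, baseline = _breslow_newton(
            design.to_numpy(dtype=float),
            df[duration_col].to_numpy(dtype=float),
            df[event_col].to_numpy(dtype=int),
        )
        params = pd.Series(beta, index=design.columns)
    else:
        # Efron ties and stratified fits go through statsmodels PHReg
        model = sm.PHReg(
            df[duration_col], design, status=df[event_col],
            ties=spec.ties, strata=strata,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit()
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix (separation?): {exc}"
            ) from exc
        params = pd.Series(res.params, index=design.columns)
        if not np.all(np.isfinite(params)):
            raise ConvergenceError("non-finite coefficients (separation?)")
        if np.max(np.abs(model.score(res.params))) > 1e-4 * max(1, events):
            raise ConvergenceError(
                "partial-likelihood score did not vanish (monotone likelihood?)"
            )
        cov_arr = res.cov_params()
        ll = float(model.loglike(res.params))
        bch = res.baseline_cumulative_hazard[0]
        baseline = (np.asarray(bch[0]), np.asarray(bch[1]))
    if not np.all(np.isfinite(params)):
        raise ConvergenceError("non-finite coefficients (separation?)")
    cov = pd.DataFrame(cov_arr, index=params.index, columns=params.index)
    se = np.sqrt(np.diag(cov))
    zcrit = norm.ppf(0.975)
    hr_table = pd.DataFrame(
        {
            "coef": params,
            "HR": np.exp(params),
            "ci_lower": np.exp(params - zcrit * se),
            "ci_upper": np.exp(params + zcrit * se),
            "p": 2 * norm.sf(np.abs(params / se)),
        }
    )
    bic = -2.0 * ll + len(params) * np.log(events)
    eta = design.to_numpy(dtype=float) @ params.to_numpy()
    cindex = float(
        concordance_index(df[duration_col], -eta, event_observed=df[event_col])
    )
    return CoxFit(
        params=params,
        covariance=cov,
        hr_table=hr_table,
        log_likelihood=ll,
        c_index=cindex,
        bic=float(bic),
        n=len(df),
        events=events,
        baseline=baseline,
        data=df,
        duration_col=duration_col,
        event_col=event_col,
    )


def _schoenfeld_residuals(
    design: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow Schoenfeld residuals x_i - xbar(t_i) at each event, with times.

    ``xbar(t)`` is the exp(linear predictor)-weighted covariate mean over the
    risk set at ``t``; residuals are returned in ascending event-time order.
    """
    order = np.argsort(time, kind="mergesort")
    x = design[order]
    t = time[order]
    e = event[order]
    w = np.exp(x @ beta)
    # suffix sums over the risk set {j : t_j >= t_i}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
    # align tied times to the first index of their tie group
    first = np.searchsorted(t, t, side="left")
    xbar = s1[first] / s0[first, None]
    mask = e == 1
    return x[mask] - xbar[mask], t[mask]


def schoenfeld_test(fit: CoxFit) -> pd.DataFrame:
    """Proportional-hazards diagnostics from scaled Schoenfeld residuals.

    Each covariate's Schoenfeld residuals are correlated against the
    Kaplan-Meier transform of the event times; the global row tests all
    covariates jointly (chi-square with one degree of freedom per
    covariate).  Constant covariate columns are excluded with a warning.

    Returns a frame indexed by covariate (plus ``GLOBAL``) with columns
    ``chi2, df, p``.
    """
    df = fit.data
    cov_cols = list(fit.params.index)
    resid_all, times = _schoenfeld_residuals(
        df[cov_cols].to_numpy(dtype=float),
        df[fit.duration_col].to_numpy(dtype=float),
        df[fit.event_col].to_numpy(dtype=int),
        fit.params.to_numpy(),
    )
    keep = [c for c in cov_cols if df[c].nunique() > 1]
    dropped = [c for c in cov_cols if c not in keep]
    if dropped:
        logger.warning("constant covariates excluded from PH test: %s", dropped)
    keep_idx = [cov_cols.index(c) for c in keep]
    r = resid_all[:, keep_idx]
    d = r.shape[0]
    if d < 2:
        raise ConvergenceError("too few events for the proportional-hazards test")

    # KM transform of event times, as in the standard cox.zph diagnostics
    km = KaplanMeierFitter().fit(
        df[fit.duration_col], event_observed=df[fit.event_col]
    )
    g = km.survival_function_at_times(times).to_numpy(dtype=float)
    gc = g - g.mean()
    ssg = float(np.sum(gc**2))

    v = fit.covariance.loc[keep, keep].to_numpy(dtype=float)
    u = gc @ r  # p-vector
    rows = {}
    uv = u @ v
    for j, name in enumerate(keep):
        stat = d * uv[j] ** 2 / (v[j, j] * ssg)
        rows[name] = {"chi2": stat, "df": 1, "p": float(chi2.sf(stat, 1))}
    gstat = float(d * (u @ v @ u) / ssg)
    rows["GLOBAL"] = {
        "chi2": gstat,
        "df": len(keep),
        "p": float(chi2.sf(gstat, len(keep))),
    }
    return pd.DataFrame(rows).T


def km_curve(
    cohort: pd.DataFrame,
    group_col: str,
    *,
    duration_col: str = "time",
    event_col: str = "event",
) -> tuple[pd.DataFrame, float]:
    """Product-limit survival estimates per group plus the log-rank p-value.

    Returns ``(curves, logrank_p)`` where ``curves`` stacks per-group
    stepwise estimates with columns ``group, time, survival, ci_lower,
    ci_upper``.  Groups without observations are dropped with a warning.
    """
    frames = []
    groups = [g for g, sub in cohort.groupby(group_col, observed=True) if len(sub)]
    for g in groups:
        sub = cohort[cohort[group_col] == g]
        if len(sub) == 0:
            logger.warning("empty group %r dropped from KM", g)
            continue
        km = KaplanMeierFitter().fit(
            sub[duration_col], event_observed=sub[event_col], label=str(g)
        )
        ci = km.confidence_interval_survival_function_
        frames.append(
            pd.DataFrame(
                {
                    "group": str(g),
                    "time": km.survival_function_.index,
                    "survival": km.survival_function_.iloc[:, 0].to_numpy(),
                    "ci_lower": ci.iloc[:, 0].to_numpy(),
                    "ci_upper": ci.iloc[:, 1].to_numpy(),
                }
            )
        )
    res = multivariate_logrank_test(
        cohort[duration_col], cohort[group_col], cohort[event_col]
    )
    return pd.concat(frames, ignore_index=True), float(res.p_value)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (truncated power form, Harrell scaling).

    Returns an ``n x (k-1)`` matrix whose first column is linear and whose
    remaining ``k-2`` columns are the nonlinear terms; the function is linear
    beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise SplineUnavailableError("need at least 3 knots")
    norm_sq = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            np.clip(x - t[j], 0, None) ** 3
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm_sq)
    return np.column_stack(cols)


def rcs_dose_response(
    cohort: pd.DataFrame,
    exposure: str,
    spec: ModelSpec,
    *,
    n_knots: int = 4,
    knots: np.ndarray | None = None,
    reference: float | None = None,
    grid_size: int = 100,
) -> SplineFit:
    """Dose-response curve from a Cox fit on a restricted cubic spline basis.

    Knots default to the 5/35/65/95 percentiles of the exposure (4 knots);
    the hazard-ratio curve is anchored at the exposure median (HR = 1).  The
    nonlinearity test is a Wald test on the nonlinear basis coefficients.
    """
    x = cohort[exposure].to_numpy(dtype=float)
    if len(np.unique(x)) < 4:
        raise SplineUnavailableError("need >= 4 distinct exposure values")
    if knots is None:
        pct = {3: [10, 50, 90], 4: [5, 35, 65, 95], 5: [5, 27.5, 50, 72.5, 95]}[
            n_knots
        ]
        knots = np.percentile(x, pct)
    knots = np.asarray(knots, dtype=float)
    basis = rcs_basis(x, knots)
    basis_cols = [f"rcs_{exposure}_{j}" for j in range(basis.shape[1])]
    work = cohort.copy()
    for j, c in enumerate(basis_cols):
        work[c] = basis[:, j]
    sub_spec = ModelSpec(
        tier=spec.tier,
        exposure=basis_cols,
        covariates=[c for c in spec.resolved_covariates() if c != exposure],
        ties=spec.ties,
        strata=spec.strata,
    )
    fit = fit_cox(work, sub_spec)

    nonlin = basis_cols[1:]
    beta_nl = fit.params[nonlin].to_numpy()
    v_nl = fit.covariance.loc[nonlin, nonlin].to_numpy()
    stat = float(beta_nl @ np.linalg.solve(v_nl, beta_nl))
    p_nl = float(chi2.sf(stat, len(nonlin)))

    if reference is None:
        reference = float(np.median(x))
    grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), grid_size)
    b_grid = rcs_basis(grid, knots)
    b_ref = rcs_basis(np.array([reference]), knots)
    delta = b_grid - b_ref
    beta = fit.params[basis_cols].to_numpy()
    vmat = fit.covariance.loc[basis_cols, basis_cols].to_numpy()
    log_hr = delta @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", delta, vmat, delta))
    zcrit = norm.ppf(0.975)
    curve = pd.DataFrame(
        {
            "x": grid,
            "hr": np.exp(log_hr),
            "ci_lower": np.exp(log_hr - zcrit * se),
            "ci_upper": np.exp(log_hr + zcrit * se),
        }
    )
    return SplineFit(
        knots=knots,
        reference=reference,
        curve=curve,
        nonlinearity_stat=stat,
        nonlinearity_p=p_nl,
        cox=fit,
    )


DEFAULT_STRATIFIERS = {
    "sex": lambda c: np.where(c["male"] == 1, "male", "female"),
    "age": lambda c: np.where(c["age"] >= 60, "age>=60", "age<60"),
    "bmi": lambda c: np.where(
        (c["bmi"] >= 18.5) & (c["bmi"] <= 24.9), "normal", "outside"
    ),
    "hypertension": lambda c: np.where(c["hypertension"] == 1, "yes", "no"),
    "smoking": lambda c: np.where(c["smoker"] == 1, "ever", "never"),
}

_STRATIFIER_SOURCE = {
    "sex": "male", "age": "age", "bmi": "bmi",
    "hypertension": "hypertension", "smoking": "smoker",
}


def subgroup_scan(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    *,
    stratifiers: dict | None = None,
    min_events: int = 2,
) -> pd.DataFrame:
    """Stratum-specific exposure HRs plus an interaction p per stratifier.

    The interaction test adds an exposure x indicator cross-product to the
    pooled model (continuous exposures only).  Sparse strata (< ``min_events``
    events) are skipped with a warning.
    """
    if stratifiers is None:
        stratifiers = DEFAULT_STRATIFIERS
    if not isinstance(spec.exposure, str):
        raise ValueError("subgroup scan requires a single exposure column")
    rows = []
    for name, fn in stratifiers.items():
        labels = pd.Series(fn(cohort), index=cohort.index)
        source = _STRATIFIER_SOURCE.get(name)
        covs = [
            c for c in spec.resolved_covariates() if c != source
        ]
        # interaction p from the pooled model with a cross-product term
        first = sorted(labels.unique())[0]
        work = cohort.copy()
        work["_stratum_ind"] = (labels != first).astype(float)
        work["_cross"] = work["_stratum_ind"] * work[spec.exposure].astype(float)
        pooled = fit_cox(
            work,
            ModelSpec(
                tier=spec.tier,
                exposure=[spec.exposure, "_stratum_ind", "_cross"],
                covariates=covs,
                ties=spec.ties,
            ),
        )
        p_int = float(pooled.hr_table.loc["_cross", "p"])
        for lev in sorted(labels.unique()):
            sub = cohort[labels == lev]
            if int(sub["event"].sum()) < min_events:
                logger.warning("stratum %s=%s too sparse; skipped", name, lev)
                continue
            try:
                f = fit_cox(
                    sub,
                    ModelSpec(tier=spec.tier, exposure=spec.exposure,
                              covariates=covs, ties=spec.ties),
                )
            except (CollinearityError, ConvergenceError) as exc:
                logger.warning("stratum %s=%s fit failed: %s", name, lev, exc)
                continue
            row = f.hr_table.loc[spec.exposure]
            rows.append(
                {
                    "stratifier": name,
                    "stratum": lev,
                    "n": f.n,
                    "events": f.events,
                    "HR": row["HR"],
                    "ci_lower": row["ci_lower"],
                    "ci_upper": row["ci_upper"],
                    "p": row["p"],
                    "p_interaction": p_int,
                }
            )
    return pd.DataFrame(rows)


def component_scan(
    cohort: pd.DataFrame,
    densities: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Per-component association scan: one per-SD Cox fit per component.

    ``densities`` holds per-participant energy-adjusted component densities
    aligned to ``cohort``'s index.  Degenerate (zero-variance) components are
    skipped.  Returns one row per component with HR, CI and p.
    """
    rows = []
    for comp in densities.columns:
        d = densities[comp].reindex(cohort.index)
        sd = d.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("degenerate component %s skipped", comp)
            continue
        work = cohort.copy()
        work["_comp_sd"] = (d - d.mean()) / sd
        f = fit_cox(
            work,
            ModelSpec(tier=spec.tier, exposure="_comp_sd",
                      covariates=spec.resolved_covariates(), ties=spec.ties),
        )
        row = f.hr_table.loc["_comp_sd"]
        rows.append(
            {
                "component": comp,
                "HR": row["HR"],
                "ci_lower": row["ci_lower"],
                "ci_upper": row["ci_upper"],
                "p": row["p"],
            }
        )
    return pd.DataFrame(rows)


def sensitivity_scan(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    *,
    landmark_years: float = 2.0,
    comorbidity_cols: list[str] | None = None,
    min_recalls: int = 2,
) -> pd.DataFrame:
    """Rerun the same model under the standard robustness filters.

    1. landmark — drop cases occurring within the first ``landmark_years``;
    2. no-comorbidity — drop participants with any major baseline condition;
    3. recalls — restrict to participants with >= ``min_recalls`` dietary
       recalls (requires an ``n_recalls`` column).
    """
    if comorbidity_cols is None:
        comorbidity_cols = [
            c for c in ("hypertension", "diabetes", "dyslipidemia",
                        "cardiovascular", "cancer", "chronic_respiratory",
                        "chronic_kidney", "chronic_liver")
            if c in cohort.columns
        ]
    filters = {
        "landmark": ~((cohort["event"] == 1) & (cohort["time"] <= landmark_years)),
        "no_comorbidity": cohort[comorbidity_cols].sum(axis=1) == 0,
    }
    if "n_recalls" in cohort.columns:
        filters["min_recalls"] = cohort["n_recalls"] >= min_recalls
    exposure = spec.exposure if isinstance(spec.exposure, str) else spec.exposure[0]
    rows = []
    for name, mask in filters.items():
        sub = cohort[mask]
        # covariates that became constant under the filter (e.g. comorbidity
        # flags in the no-comorbidity rerun) are dropped with a warning
        covs = []
        for c in spec.resolved_covariates():
            if sub[c].nunique() > 1:
                covs.append(c)
            else:
                logger.warning("covariate %s constant under filter %s; dropped",
                               c, name)
        f = fit_cox(sub, ModelSpec(tier=spec.tier, exposure=spec.exposure,
                                   covariates=covs, ties=spec.ties,
                                   strata=spec.strata))
        key = exposure if exposure in f.hr_table.index else f.hr_table.index[0]
        row = f.hr_table.loc[key]
        rows.append(
            {
                "analysis": name,
                "n": f.n,
                "events": f.events,
                "term": key,
                "HR": row["HR"],
                "ci_lower": row["ci_lower"],
                "ci_upper": row["ci_upper"],
                "p": row["p"],
            }
        )
    return pd.DataFrame(rows)
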