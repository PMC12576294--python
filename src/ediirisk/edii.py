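"""Energy-adjusted Dietary Inflammatory Index (E-DII) scoring.

The E-DII summarises the inflammatory potential of a diet as a weighted sum
over dietary components.  For each component the energy-adjusted intake
density (per 1,000 kcal, nutrient-density method) is compared against a
global reference mean and standard deviation; the resulting z-score is
mapped to a centered percentile ``2*Phi(z) - 1`` and multiplied by a
literature-derived inflammatory effect weight.  Positive weights mark
pro-inflammatory components (e.g. saturated fat), negative weights
anti-inflammatory ones (e.g. fiber, magnesium, vitamin E).  The sum over
components is the E-DII score; higher values indicate a more
pro-inflammatory diet.

The global reference table shipped with the package
(``data/edii_reference_synthetic.csv``) is a synthetic stand-in with
realistic per-1,000 kcal magnitudes; real analyses should supply the
published reference database via :func:`load_reference`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DegenerateExposureError, InvalidRecordError, SchemaError

__all__ = [
    "load_reference",
    "default_reference",
    "energy_adjust",
    "edii_score",
    "code_exposure",
    "tertile_labels",
]

REFERENCE_COLUMNS = ["component", "unit", "mean", "sd", "weight"]


def load_reference(path) -> pd.DataFrame:
    """Read an E-DII reference table (CSV: component, unit, mean, sd, weight)."""
    ref = pd.read_csv(path)
    missing = set(REFERENCE_COLUMNS) - set(ref.columns)
    if missing:
        raise SchemaError(f"reference table missing columns: {sorted(missing)}")
    if (ref["sd"] <= 0).any():
        bad = ref.loc[ref["sd"] <= 0, "component"].tolist()
        raise SchemaError(f"non-positive reference SD for components: {bad}")
    if ref["component"].duplicated().any():
        dup = ref.loc[ref["component"].duplicated(), "component"].tolist()
        raise SchemaError(f"duplicate reference components: {dup}")
    return ref.reset_index(drop=True)


def default_reference() -> pd.DataFrame:
    """The synthetic 30-component global reference table shipped with the package."""
    with resources.files("ediirisk.data").joinpath(
        "edii_reference_synthetic.csv"
    ).open() as fh:
        return load_reference(fh)


def energy_adjust(
    records: pd.DataFrame,
    components: list[str],
    *,
    id_col: str = "participant_id",
    energy_col: str = "energy_kcal",
) -> pd.DataFrame:
    """Energy-adjust recall-level intakes and average across a participant's recalls.

    ``records`` holds one row per 24-h recall with raw component intakes
    (native units/day) and total energy (kcal/day).  Each intake is converted
    to a density per 1,000 kcal (nutrient-density method), then densities are
    averaged across recalls, giving one row per participant.

    Raises
    ------
    InvalidRecordError
        If any recall has energy <= 0.
    SchemaError
        If a configured component column is absent.
    """
    missing = [c for c in components if c not in records.columns]
    if missing:
        raise SchemaError(f"missing component columns: {missing}")
    if energy_col not in records.columns:
        raise SchemaError(f"missing energy column '{energy_col}'")
    energy = records[energy_col].to_numpy(dtype=float)
    if (energy <= 0).any() or np.isnan(energy).any():
        raise InvalidRecordError("recall with non-positive or missing energy")
    densities = records[components].to_numpy(dtype=float) / energy[:, None] * 1000.0
    out = pd.DataFrame(densities, columns=components, index=records.index)
    out[id_col] = records[id_col].to_numpy()
    return out.groupby(id_col, sort=True)[components].mean()


def edii_score(
    densities: pd.DataFrame,
    reference: pd.DataFrame,
    *,
    percentile: str = "normal",
) -> pd.DataFrame:
    """Score energy-adjusted densities against a global reference.

    For component *i* with reference mean mu_i, SD sigma_i and weight w_i:

        z_i = (density_i - mu_i) / sigma_i
        c_i = 2 * P(z_i) - 1          (centered percentile, in [-1, 1])
        score = sum_i c_i * w_i

    ``percentile='normal'`` uses the standard normal CDF for P;
    ``percentile='empirical'`` uses the within-cohort empirical CDF of the
    z-scores (midrank convention).

    Returns a frame indexed like ``densities`` with one ``edii`` column plus
    a ``contrib_<component>`` column per component.
    """
    components = reference["component"].tolist()
    missing = [c for c in components if c not in densities.columns]
    if missing:
        raise SchemaError(f"densities missing components: {missing}")
    mu = reference["mean"].to_numpy(dtype=float)
    sigma = reference["sd"].to_numpy(dtype=float)
    w = reference["weight"].to_numpy(dtype=float)
    x = densities[components].to_numpy(dtype=float)
    z = (x - mu) / sigma
    if percentile == "normal":
        p = norm.cdf(z)
    elif percentile == "empirical":
        # midrank empirical CDF per component, computed within the cohort
        n = z.shape[0]
        order = np.argsort(z, axis=0, kind="mergesort")
        ranks = np.empty_like(z)
        rows = np.arange(n, dtype=float) + 0.5
        for j in range(z.shape[1]):
            ranks[order[:, j], j] = rows
        p = ranks / n
    else:
        raise ValueError(f"unknown percentile method '{percentile}'")
    centered = 2.0 * p - 1.0
    contrib = centered * w
    out = pd.DataFrame(
        contrib, columns=[f"contrib_{c}" for c in components], index=densities.index
    )
    out.insert(0, "edii", contrib.sum(axis=1))
    return out


def tertile_labels(scores: pd.Series) -> pd.Series:
    """Label scores T1/T2/T3 at the empirical 1/3 and 2/3 quantiles.

    Ties at a cut go to the lower tertile (a value equal to the cut is kept
    below it), so the partition is deterministic under duplicated scores.
    """
    s = scores.to_numpy(dtype=float)
    q1, q2 = np.quantile(s, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(s <= q1, "T1", np.where(s <= q2, "T2", "T3"))
    return pd.Series(pd.Categorical(labels, categories=["T1", "T2", "T3"]),
                     index=scores.index, name="edii_tertile")


def code_exposure(scores: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Derive the two exposure codings used in the survival models.

    Returns ``(tertiles, standardized)`` where tertiles partition the cohort
    at the empirical 1/3 and 2/3 quantiles and ``standardized`` is the
    per-cohort z-score (per 1-SD increase coding).

    Raises
    ------
    DegenerateExposureError
        With fewer than 3 participants or zero score variance.
    """
    if len(scores) < 3:
        raise DegenerateExposureError("need at least 3 participants for tertiles")
    sd = scores.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateExposureError("exposure has zero variance")
    standardized = (scores - scores.mean()) / sd
    standardized.name = "edii_sd"
    return tertile_labels(scores), standardized
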