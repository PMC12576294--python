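"""Blood-based systemic inflammation and nutrition indices.

Computed from the baseline blood panel (counts in 10^9/L, albumin in g/L,
total cholesterol in mmol/L):

* SIRI  = neutrophils x monocytes / lymphocytes
* SII   = neutrophils x platelets / lymphocytes
* PNI   = albumin + 5 x lymphocytes
* CONUT = banded points from albumin (0/2/4/6), lymphocytes (0/1/2/3) and
  total cholesterol (0/1/2/3); total 0-12, higher = worse nutritional status.

The CONUT banding follows the standard published scheme (albumin in g/dL,
lymphocytes per microlitre, cholesterol in mg/dL); the unit conversions from
the panel units are applied internally and the band table is exposed as
:data:`CONUT_BANDS` for auditability.  Band edges are inclusive on the
lower-risk side (e.g. albumin exactly 3.5 g/dL scores 0 points).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidPanelError, UndefinedIndexError

__all__ = ["compute_indices", "conut_points", "CONUT_BANDS", "PANEL_COLUMNS"]

PANEL_COLUMNS = [
    "neutrophils",
    "monocytes",
    "lymphocytes",
    "platelets",
    "albumin",
    "total_cholesterol",
]

# thresholds are lower bounds of the 0/1(2)/2(4)/3(6)-point bands, highest first
CONUT_BANDS = {
    # albumin g/dL -> points 0, 2, 4, 6
    "albumin_g_dl": {"edges": [3.5, 3.0, 2.5], "points": [0, 2, 4, 6]},
    # lymphocytes /uL -> points 0, 1, 2, 3
    "lymphocytes_per_ul": {"edges": [1600.0, 1200.0, 800.0], "points": [0, 1, 2, 3]},
    # total cholesterol mg/dL -> points 0, 1, 2, 3
    "cholesterol_mg_dl": {"edges": [180.0, 140.0, 100.0], "points": [0, 1, 2, 3]},
}

MMOL_L_TO_MG_DL = 38.67  # total cholesterol


def _band_points(values: np.ndarray, criterion: str) -> np.ndarray:
    spec = CONUT_BANDS[criterion]
    # edges descend from the healthiest band; a value equal to an edge falls
    # in the lower-risk band ("inclusive on the lower-risk side")
    edges = np.asarray(spec["edges"], dtype=float)
    idx = np.searchsorted(-edges, -np.asarray(values, dtype=float), side="left")
    return np.asarray(spec["points"], dtype=int)[idx]


def conut_points(
    albumin_g_l: np.ndarray,
    lymphocytes_1e9_l: np.ndarray,
    cholesterol_mmol_l: np.ndarray,
) -> pd.DataFrame:
    """Per-criterion CONUT points and the total score (0-12)."""
    alb = _band_points(np.asarray(albumin_g_l, dtype=float) / 10.0, "albumin_g_dl")
    lym = _band_points(
        np.asarray(lymphocytes_1e9_l, dtype=float) * 1000.0, "lymphocytes_per_ul"
    )
    chol = _band_points(
        np.asarray(cholesterol_mmol_l, dtype=float) * MMOL_L_TO_MG_DL,
        "cholesterol_mg_dl",
    )
    return pd.DataFrame(
        {
            "conut_albumin_pts": alb,
            "conut_lymphocyte_pts": lym,
            "conut_cholesterol_pts": chol,
            "conut": alb + lym + chol,
        }
    )


def compute_indices(panel: pd.DataFrame) -> pd.DataFrame:
    """Compute SIRI, SII, PNI and CONUT from a baseline blood panel.

    ``panel`` must contain :data:`PANEL_COLUMNS` (counts in 10^9/L, albumin
    g/L, total cholesterol mmol/L).  Returns a frame aligned to ``panel``'s
    index with columns ``siri, sii, pni, conut`` plus per-criterion CONUT
    points.

    Raises
    ------
    UndefinedIndexError
        If any lymphocyte count is <= 0 (ratio indices undefined).
    InvalidPanelError
        If any panel entry is negative.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise InvalidPanelError(f"panel missing columns: {missing}")
    vals = panel[PANEL_COLUMNS].to_numpy(dtype=float)
    if (vals < 0).any():
        raise InvalidPanelError("negative blood panel entries")
    n, m, l, p, a, tc = (vals[:, i] for i in range(6))
    if (l <= 0).any():
        raise UndefinedIndexError("lymphocyte count <= 0: SIRI/SII/PNI undefined")
    out = pd.DataFrame(index=panel.index)
    out["siri"] = n * m / l
    out["sii"] = n * p / l
    out["pni"] = a + 5.0 * l
    conut = conut_points(a, l, tc)
    conut.index = panel.index
    return pd.concat([out, conut], axis=1)
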