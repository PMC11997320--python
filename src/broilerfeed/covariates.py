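"""Per-bird modelling covariates and the descriptive correlation matrix.

Builds start body weight (14 d), body-weight gain ((BW35 - BW14)/21 g/day),
summed hock-burn and footpad-dermatitis scores, and the good/suboptimal
gait dichotomy from the 27 d gait score. Hock-burn and footpad scores are
carried for description only and never enter the mixed models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .rfid_io import SCORE_AGES, CovariateTableRaw

logger = logging.getLogger(__name__)

GAIT_CLASS_GOOD = "GG"
GAIT_CLASS_SUBOPTIMAL = "SG"


def compute_bw_gain(bw14: float, bw35: float, days: int = 21) -> float:
    """Daily body-weight gain (BW35 - BW14) / days, grams per day."""
    if days <= 0:
        raise ValueError("days must be > 0")
    if bw14 <= 0 or bw35 <= 0:
        raise ValueError("body weights must be positive")
    gain = (bw35 - bw14) / days
    if gain < 0:
        logger.warning("negative body-weight gain: %.2f g/day", gain)
    return gain


def classify_gait(score: int) -> str:
    """Dichotomize a 0-5 gait score: <= 2 good gait (GG), >= 3 suboptimal (SG)."""
    if not float(score).is_integer() or not 0 <= score <= 5:
        raise ValueError(f"gait score must be an integer in [0, 5], got {score!r}")
    return GAIT_CLASS_GOOD if score <= 2 else GAIT_CLASS_SUBOPTIMAL


def sum_leg_scores(left: int, right: int) -> int:
    """Sum left + right leg scores (each 0-5) to one 0-10 score."""
    for side, v in (("left", left), ("right", right)):
        if not float(v).is_integer() or not 0 <= v <= 5:
            raise ValueError(f"{side} score must be an integer in [0, 5], got {v!r}")
    return int(left) + int(right)


def build_covariates(raw: CovariateTableRaw, *, gain_days: int = 21) -> pd.DataFrame:
    """Per-bird modelling covariates from the raw table (complete birds only).

    Returns a DataFrame keyed by bird_id with sex, start_bw_g,
    bw_gain_g_d, hb_sum_<age> and fpd_sum_<age> for the scoring ages,
    gait_score_27 and gait_class.
    """
    wide = raw.complete_table()
    rows = []
    for _, r in wide.iterrows():
        rec = {
            "bird_id": r["bird_id"],
            "sex": r["sex"],
            "start_bw_g": float(r["bw_14"]),
            "bw_gain_g_d": compute_bw_gain(float(r["bw_14"]), float(r["bw_35"]), gain_days),
        }
        for a in SCORE_AGES:
            rec[f"hb_sum_{a}"] = sum_leg_scores(int(r[f"hb_left_{a}"]), int(r[f"hb_right_{a}"]))
            rec[f"fpd_sum_{a}"] = sum_leg_scores(int(r[f"fpd_left_{a}"]), int(r[f"fpd_right_{a}"]))
        rec["gait_score_27"] = int(r["gait_27"])
        rec["gait_class"] = classify_gait(int(r["gait_27"]))
        rows.append(rec)
    return pd.DataFrame(rows)


def aggregate_descriptors(desc_table: pd.DataFrame) -> pd.DataFrame:
    """Per-bird means of nfv, mfbd_s and ndf across days."""
    g = desc_table.groupby("bird_id")
    return pd.DataFrame(
        {
            "mean_nfv": g["nfv"].mean(),
            "mean_mfbd_s": g["mfbd_s"].mean(),
            "mean_ndf": g["ndf"].mean(),
        }
    ).reset_index()


def correlation_matrix(
    per_bird: pd.DataFrame,
    *,
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations with two-sided p-values.

    Binary columns (sex, gait_class) are numerically coded 0/1, making
    their Pearson correlations point-biserial. Zero-variance columns give
    missing coefficients, never an error. No multiplicity correction.

    Parameters
    ----------
    per_bird:
        One row per bird; all columns except bird_id are correlated.
    method:
        "pearson" (default) or "spearman".

    Returns
    -------
    (r, p): symmetric DataFrames with unit diagonal / zero p diagonal.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    df = per_bird.drop(columns=["bird_id"], errors="ignore").copy()
    if "sex" in df.columns:
        df["sex"] = (df["sex"] == "male").astype(float)
    if "gait_class" in df.columns:
        df["gait_class"] = (df["gait_class"] == GAIT_CLASS_SUBOPTIMAL).astype(float)
    if len(df) < 3:
        raise ValueError("correlation matrix needs at least 3 birds")

    cols = list(df.columns)
    n = len(cols)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    func = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(n):
        for j in range(i, n):
            xi = df[cols[i]].astype(float)
            xj = df[cols[j]].astype(float)
            ok = xi.notna() & xj.notna()
            if ok.sum() < 3:
                continue
            a, b = xi[ok].to_numpy(), xj[ok].to_numpy()
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            if np.std(a) == 0 or np.std(b) == 0:
                continue  # undefined, reported missing
            res = func(a, b)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
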