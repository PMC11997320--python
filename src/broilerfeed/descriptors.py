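"""Per-bird per-day feeding descriptors and the k-SD outlier filter.

For every bird and day of age in the analysis window three descriptors are
derived from the bout table: NFV (number of feeder visits), MFBD (mean
feeding bout duration, seconds; undefined on zero-visit days) and NDF
(number of different feeders visited).
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = ("nfv", "mfbd_s", "ndf")


def compute_daily_descriptors(
    bouts: pd.DataFrame,
    hatch_date: dt.date,
    *,
    age_window: tuple[int, int] = (20, 30),
    birds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Derive NFV, MFBD and NDF per bird per day of age.

    Each bout is assigned to the calendar day of its start (bouts spanning
    midnight are not split). Bouts whose start day falls outside
    ``age_window`` are excluded with a logged count. Every (bird, age) cell
    in the window appears in the output; zero-visit days get nfv = 0,
    ndf = 0 and missing mfbd_s.

    Parameters
    ----------
    bouts:
        Bout table from segmentation (or ground truth).
    hatch_date:
        Day-0 date of the flock; age = start date - hatch_date in days.
    birds:
        Bird universe; defaults to the birds present in ``bouts``.
    """
    lo, hi = age_window
    if lo > hi:
        raise ValueError("age_window must be (low, high) with low <= high")
    if bouts.empty:
        bird_list = sorted(birds) if birds is not None else []
        bouts = bouts.assign(age_days=pd.Series(dtype=int))
    else:
        start = pd.to_datetime(bouts["start"])
        age = (start.dt.normalize() - pd.Timestamp(hatch_date)).dt.days
        bouts = bouts.assign(age_days=age)
        outside = (age < lo) | (age > hi)
        if outside.any():
            logger.info("excluding %d bouts outside the age window %s", int(outside.sum()), age_window)
            bouts = bouts[~outside]
        bird_list = sorted(birds) if birds is not None else sorted(bouts["bird_id"].unique())

    grid = pd.MultiIndex.from_product(
        [bird_list, range(lo, hi + 1)], names=["bird_id", "age_days"]
    )
    if bouts.empty:
        agg = pd.DataFrame(index=pd.MultiIndex.from_arrays([[], []], names=["bird_id", "age_days"]),
                           columns=["nfv", "mfbd_s", "ndf"])
    else:
        g = bouts.groupby(["bird_id", "age_days"])
        agg = pd.DataFrame(
            {
                "nfv": g.size(),
                "mfbd_s": g["duration_s"].mean(),
                "ndf": g["feeder_id"].nunique(),
            }
        )
    out = agg.reindex(grid)
    out["nfv"] = out["nfv"].fillna(0).astype(int)
    out["ndf"] = out["ndf"].fillna(0).astype(int)
    out["mfbd_s"] = out["mfbd_s"].astype(float)
    return out.reset_index()


@dataclass
class OutlierReport:
    """Per-descriptor pooled mean/SD and the observations excluded by them."""

    k: float
    stats: dict[str, dict[str, float]] = field(default_factory=dict)
    excluded: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def n_excluded(self, descriptor: str) -> int:
        return len(self.excluded.get(descriptor, []))


def flag_outliers(
    table: pd.DataFrame,
    k: float = 4.0,
    descriptors: Iterable[str] = DESCRIPTOR_COLUMNS,
) -> tuple[dict[str, pd.DataFrame], OutlierReport]:
    """Flag bird-day observations beyond k pooled standard deviations.

    The mean and SD of each descriptor are computed once over all bird-day
    observations (outliers included; single pass, no re-computation after
    removal) and an observation is excluded when |x - mean| > k * SD.
    Exclusion is per descriptor and per observation: a row flagged for NFV
    is dropped only from the NFV table. A zero or undefined SD flags
    nothing.

    Returns
    -------
    (filtered, report):
        ``filtered`` maps descriptor name to the table with that
        descriptor's outlier rows removed; ``report`` carries the pooled
        statistics and the excluded (bird_id, age_days) pairs. The input
        table is not modified; ``<desc>_outlier`` flag columns are present
        on each filtered table.
    """
    if table.empty:
        raise ValueError("descriptor table is empty")
    if not (k > 0):
        raise ValueError("outlier threshold k must be > 0")

    report = OutlierReport(k=k)
    filtered: dict[str, pd.DataFrame] = {}
    work = table.copy()
    for desc in descriptors:
        x = work[desc].astype(float)
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        report.stats[desc] = {"mean": mean, "sd": sd}
        if not math.isfinite(sd) or sd == 0 or math.isinf(k):
            flags = pd.Series(False, index=work.index)
        else:
            flags = (x - mean).abs() > k * sd
            flags = flags.fillna(False)
        work[f"{desc}_outlier"] = flags
        report.excluded[desc] = [
            (str(b), int(a))
            for b, a in zip(work.loc[flags, "bird_id"], work.loc[flags, "age_days"])
        ]
        filtered[desc] = work[~flags].copy()
        if flags.any():
            logger.info("flagged %d outlier(s) for %s at k=%g", int(flags.sum()), desc, k)
    return filtered, report
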