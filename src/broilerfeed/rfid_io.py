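"""Reading, validation and writing of RFID detection logs and covariate tables.

A detection log is delimited text (comma or tab) with a header, one row per
second per detected bird: an ISO 8601 timestamp at whole-second resolution,
an opaque bird (tag) identifier and an integer antenna/feeder number.
Covariate tables carry per-bird sex, body weights and leg-health scores and
are accepted in wide (one row per bird) or long (one row per bird per
scoring day) layout.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: canonical detection-log column names
DETECTION_COLUMNS = ("timestamp", "bird_id", "antenna_id")

#: scoring schedule (days of age)
BW_AGES = (14, 21, 27, 35)
SCORE_AGES = (21, 27, 35)


class ValidationError(ValueError):
    """Raised when an input file violates a structural or range invariant."""


# ---------------------------------------------------------------------------
# pen layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PenLayout:
    """Feeder identities, which feeders carry antennas, and pen halves.

    The default layout has 16 feeders of which 15 are antenna-equipped
    (feeder 1 carries no antenna) and splits the pen into halves A
    (feeders 1-8) and B (feeders 9-16).
    """

    feeder_ids: tuple[int, ...]
    antenna_equipped: frozenset[int]
    pen_half: dict[int, str] = field(compare=False)

    def __post_init__(self) -> None:
        feeders = set(self.feeder_ids)
        if not set(self.antenna_equipped) <= feeders:
            raise ValidationError(
                "antenna_equipped must be a subset of feeder_ids; offending: "
                f"{sorted(set(self.antenna_equipped) - feeders)}"
            )
        if set(self.pen_half) != feeders:
            raise ValidationError("pen_half must map every feeder_id")
        bad = {h for h in self.pen_half.values() if h not in ("A", "B")}
        if bad:
            raise ValidationError(f"pen halves must be 'A' or 'B', got {sorted(bad)}")

    @property
    def n_feeders_total(self) -> int:
        return len(self.feeder_ids)

    @classmethod
    def default(cls) -> "PenLayout":
        feeders = tuple(range(1, 17))
        return cls(
            feeder_ids=feeders,
            antenna_equipped=frozenset(f for f in feeders if f != 1),
            pen_half={f: ("A" if f <= 8 else "B") for f in feeders},
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "feeder_ids": list(self.feeder_ids),
            "antenna_equipped": sorted(self.antenna_equipped),
            "pen_half": {int(k): v for k, v in self.pen_half.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PenLayout":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            feeder_ids=tuple(int(f) for f in payload["feeder_ids"]),
            antenna_equipped=frozenset(int(f) for f in payload["antenna_equipped"]),
            pen_half={int(k): str(v) for k, v in payload["pen_half"].items()},
        )


# ---------------------------------------------------------------------------
# detection logs
# ---------------------------------------------------------------------------


def _sniff_sep(path: str | Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_detection_log(
    path: str | Path,
    layout: PenLayout,
    *,
    column_map: Mapping[str, str] | None = None,
    subsecond: str = "error",
    conflict: str = "previous",
) -> pd.DataFrame:
    """Read and validate a detection log.

    Parameters
    ----------
    path:
        Delimited text file (comma or tab, autodetected) with a header.
    layout:
        Pen layout; every antenna_id must be antenna-equipped under it.
    column_map:
        Optional mapping from canonical names (``timestamp``, ``bird_id``,
        ``antenna_id``) to the file's column names.
    subsecond:
        ``"error"`` (default) rejects sub-second timestamps, ``"truncate"``
        floors them to the whole second.
    conflict:
        Resolution for a bird detected at two antennas in the same second:
        ``"previous"`` (default) keeps the record matching the previous
        second's antenna, falling back to the lower antenna_id;
        ``"lower"`` always keeps the lower antenna_id.

    Returns
    -------
    DataFrame with columns timestamp (datetime64[s]), bird_id (str),
    antenna_id (int), sorted by (bird_id, timestamp), exact duplicates
    collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if subsecond not in ("error", "truncate"):
        raise ValueError("subsecond must be 'error' or 'truncate'")
    if conflict not in ("previous", "lower"):
        raise ValueError("conflict must be 'previous' or 'lower'")

    raw = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    colmap = dict(column_map or {})
    rename = {colmap.get(k, k): k for k in DETECTION_COLUMNS}
    missing = [colmap.get(k, k) for k in DETECTION_COLUMNS if colmap.get(k, k) not in raw.columns]
    if missing:
        raise ValidationError(f"detection log is missing column(s): {missing}")
    df = raw.rename(columns=rename)[list(DETECTION_COLUMNS)].copy()

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValidationError(
            f"unparseable timestamp at data row {row}: {df['timestamp'].iloc[row]!r}"
        )
    floored = ts.dt.floor("s")
    if (ts != floored).any():
        if subsecond == "error":
            row = int(np.flatnonzero((ts != floored).to_numpy())[0])
            raise ValidationError(
                f"sub-second timestamp at data row {row}: {df['timestamp'].iloc[row]!r}"
            )
        ts = floored
    df["timestamp"] = ts.astype("datetime64[s]")

    try:
        df["antenna_id"] = df["antenna_id"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer antenna_id: {exc}") from exc
    known = np.isin(df["antenna_id"].to_numpy(), sorted(layout.antenna_equipped))
    if not known.all():
        row = int(np.flatnonzero(~known)[0])
        raise ValidationError(
            f"unknown antenna_id {df['antenna_id'].iloc[row]} at data row {row} "
            f"(antenna-equipped feeders: {sorted(layout.antenna_equipped)})"
        )
    df["bird_id"] = df["bird_id"].astype(str)

    n_raw = len(df)
    df = df.drop_duplicates(subset=list(DETECTION_COLUMNS))
    n_collapsed = n_raw - len(df)

    df = df.sort_values(["bird_id", "timestamp", "antenna_id"], kind="mergesort")
    df = _resolve_same_second_conflicts(df, conflict)
    df = df.reset_index(drop=True)
    logger.info(
        "read %d detection records from %s (%d duplicate rows collapsed)",
        len(df), path, n_collapsed,
    )
    return df


def _resolve_same_second_conflicts(df: pd.DataFrame, conflict: str) -> pd.DataFrame:
    """Keep one record per (bird, second); see ``read_detection_log``."""
    dup = df.duplicated(subset=["bird_id", "timestamp"], keep=False)
    if not dup.any():
        return df
    keep_mask = np.ones(len(df), dtype=bool)
    positions = {(b, t): i for i, (b, t) in enumerate(zip(df["bird_id"], df["timestamp"]))
                 if not dup.iloc[i]}
    grouped = df[dup].groupby(["bird_id", "timestamp"], sort=False)
    for (bird, t), grp in grouped:
        antennas = grp["antenna_id"].tolist()
        chosen = min(antennas)
        if conflict == "previous":
            prev = positions.get((bird, t - pd.Timedelta(seconds=1)))
            if prev is not None and df["antenna_id"].iloc[prev] in antennas:
                chosen = int(df["antenna_id"].iloc[prev])
        logger.warning(
            "bird %s detected at antennas %s at %s; keeping antenna %d",
            bird, sorted(antennas), t, chosen,
        )
        for idx, ant in zip(grp.index, antennas):
            if ant != chosen:
                keep_mask[df.index.get_loc(idx)] = False
        # drop all-but-first if the chosen antenna itself is duplicated
        seen = False
        for idx, ant in zip(grp.index, antennas):
            if ant == chosen:
                if seen:
                    keep_mask[df.index.get_loc(idx)] = False
                seen = True
        positions[(bird, t)] = df.index.get_loc(grp.index[antennas.index(chosen)])
    return df[keep_mask]


def write_detection_log(records: pd.DataFrame, path: str | Path) -> None:
    """Write a detection log as CSV; inverse of ``read_detection_log``.

    Records are written sorted by (bird_id, timestamp) with ISO 8601
    second-resolution timestamps so that read(write(x)) == x bit-exactly.
    """
    df = records.loc[:, list(DETECTION_COLUMNS)].copy()
    df = df.sort_values(["bird_id", "timestamp", "antenna_id"], kind="mergesort")
    out = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "bird_id": df["bird_id"].astype(str),
            "antenna_id": df["antenna_id"].astype(int),
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# covariate tables
# ---------------------------------------------------------------------------

#: wide-format covariate columns required for a bird to count as complete
def _wide_columns() -> list[str]:
    cols = ["bird_id", "sex"]
    cols += [f"bw_{a}" for a in BW_AGES]
    for score in ("hb", "fpd"):
        for side in ("left", "right"):
            cols += [f"{score}_{side}_{a}" for a in SCORE_AGES]
    cols += [f"gait_{a}" for a in SCORE_AGES]
    return cols


WIDE_COVARIATE_COLUMNS = _wide_columns()


@dataclass
class CovariateTableRaw:
    """Per-bird raw covariates in wide layout plus a completeness report."""

    table: pd.DataFrame
    incomplete: dict[str, list[str]]

    @property
    def complete_ids(self) -> list[str]:
        return [b for b in self.table["bird_id"] if b not in self.incomplete]

    def complete_table(self) -> pd.DataFrame:
        return self.table[~self.table["bird_id"].isin(self.incomplete)].reset_index(drop=True)


def read_covariates(path: str | Path) -> CovariateTableRaw:
    """Read a covariate table, autodetecting wide vs long layout.

    Long layout has columns bird_id, sex, age_days, bw, hb_left, hb_right,
    fpd_left, fpd_right, gait and is pivoted to the wide layout. Scores must
    lie in [0, 5] and body weights must be positive; violations are hard
    errors. Birds missing any required field are flagged incomplete (not
    dropped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sniff_sep(path))
    if "age_days" in raw.columns:
        wide = _long_to_wide(raw)
    else:
        wide = raw.copy()
    for col in WIDE_COVARIATE_COLUMNS:
        if col not in wide.columns:
            wide[col] = np.nan
    wide = wide[WIDE_COVARIATE_COLUMNS]
    wide["bird_id"] = wide["bird_id"].astype(str)

    _validate_covariates(wide)

    incomplete: dict[str, list[str]] = {}
    value_cols = [c for c in WIDE_COVARIATE_COLUMNS if c != "bird_id"]
    for _, row in wide.iterrows():
        missing = [c for c in value_cols if pd.isna(row[c])]
        if missing:
            incomplete[row["bird_id"]] = missing
    logger.info(
        "read covariates for %d birds from %s (%d incomplete)",
        len(wide), path, len(incomplete),
    )
    return CovariateTableRaw(table=wide, incomplete=incomplete)


def _long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    need = {"bird_id", "age_days"}
    if not need <= set(long.columns):
        raise ValidationError(f"long covariate table needs columns {sorted(need)}")
    out: dict[str, dict] = {}
    for _, row in long.iterrows():
        bird = str(row["bird_id"])
        rec = out.setdefault(bird, {"bird_id": bird})
        if "sex" in long.columns and pd.notna(row.get("sex")):
            rec["sex"] = row["sex"]
        age = int(row["age_days"])
        if pd.notna(row.get("bw")):
            rec[f"bw_{age}"] = row["bw"]
        for score in ("hb", "fpd"):
            for side in ("left", "right"):
                col = f"{score}_{side}"
                if col in long.columns and pd.notna(row.get(col)):
                    rec[f"{score}_{side}_{age}"] = row[col]
        if "gait" in long.columns and pd.notna(row.get("gait")):
            rec[f"gait_{age}"] = row["gait"]
    return pd.DataFrame(list(out.values()))


def _validate_covariates(wide: pd.DataFrame) -> None:
    if wide["bird_id"].duplicated().any():
        dups = wide.loc[wide["bird_id"].duplicated(), "bird_id"].tolist()
        raise ValidationError(f"duplicate bird_id(s) in covariate table: {dups}")
    sex_vals = wide["sex"].dropna().unique()
    bad_sex = [s for s in sex_vals if s not in ("male", "female")]
    if bad_sex:
        raise ValidationError(f"sex must be 'male' or 'female', got {bad_sex}")
    for a in BW_AGES:
        bw = pd.to_numeric(wide[f"bw_{a}"], errors="raise")
        if (bw.dropna() <= 0).any():
            bird = wide.loc[bw <= 0, "bird_id"].iloc[0]
            raise ValidationError(f"non-positive body weight bw_{a} for bird {bird}")
    score_cols = [c for c in wide.columns if c.startswith(("hb_", "fpd_", "gait_"))]
    for col in score_cols:
        vals = pd.to_numeric(wide[col], errors="raise").dropna()
        if ((vals < 0) | (vals > 5)).any():
            bird = wide.loc[(wide[col] < 0) | (wide[col] > 5), "bird_id"].iloc[0]
            raise ValidationError(f"score {col} outside [0, 5] for bird {bird}")


def write_covariates(table: pd.DataFrame, path: str | Path) -> None:
    """Write a wide-format covariate table as CSV."""
    cols = [c for c in WIDE_COVARIATE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)
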