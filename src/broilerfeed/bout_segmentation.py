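"""Feeding-bout segmentation of per-bird detection streams.

A feeding bout is a maximal run of same-bird, same-feeder detections whose
internal record gaps do not exceed the record-gap threshold (default 24 s).
Because the reader keeps reporting a tag at its last antenna for a further
6 s (the auto-extension, already present in the log), the effective
wall-clock gap merged into one bout is 30 s. A detection of the same bird
at a different antenna always closes the current bout, whatever the gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BOUT_COLUMNS = ("bird_id", "feeder_id", "start", "end", "duration_s", "close_reason")


@dataclass(frozen=True)
class SegmentationParams:
    """Gap-merging parameters.

    ``effective_gap_threshold_s`` is derived: the record-level threshold
    applied to log timestamps plus the reader auto-extension already baked
    into those timestamps.
    """

    record_gap_threshold_s: float = 24.0
    auto_extension_s: float = 6.0

    def __post_init__(self) -> None:
        if self.record_gap_threshold_s < 0 or self.auto_extension_s < 0:
            raise ValueError("segmentation thresholds must be >= 0")

    @property
    def effective_gap_threshold_s(self) -> float:
        return self.record_gap_threshold_s + self.auto_extension_s


def _check_sorted(records: pd.DataFrame) -> None:
    birds = records["bird_id"].to_numpy()
    times = records["timestamp"].to_numpy()
    same = birds[1:] == birds[:-1]
    if (same & (times[1:] < times[:-1])).any():
        raise ValueError("records are not sorted by (bird_id, timestamp)")
    # each bird must occupy one contiguous block
    change = np.flatnonzero(birds[1:] != birds[:-1])
    starts = birds[np.concatenate([[0], change + 1])] if len(birds) else np.array([])
    if len(starts) != len(set(starts)):
        raise ValueError("records are not sorted by (bird_id, timestamp): "
                         "a bird appears in more than one block")


def segment_bouts(records: pd.DataFrame, params: SegmentationParams) -> pd.DataFrame:
    """Single-pass segmentation of a sorted detection stream into bouts.

    Parameters
    ----------
    records:
        DataFrame with timestamp/bird_id/antenna_id, sorted by
        (bird_id, timestamp); unsorted input raises (never silently sorted).
    params:
        Gap thresholds; only ``record_gap_threshold_s`` is applied here
        because the auto-extension is a property of the log itself.

    Returns
    -------
    DataFrame with one row per bout: bird_id, feeder_id, start, end,
    duration_s = (end - start) + 1, and close_reason in
    {"gap", "switch", "end_of_log"}.
    """
    if records.empty:
        return pd.DataFrame(columns=list(BOUT_COLUMNS))
    _check_sorted(records)

    birds = records["bird_id"].to_numpy()
    ants = records["antenna_id"].to_numpy()
    t = records["timestamp"].to_numpy().astype("datetime64[s]").astype(np.int64)

    new_bird = np.concatenate([[True], birds[1:] != birds[:-1]])
    gap = np.concatenate([[0], t[1:] - t[:-1]])
    new_bout = new_bird | np.concatenate([[True], ants[1:] != ants[:-1]]) \
        | (gap > params.record_gap_threshold_s)
    bout_id = np.cumsum(new_bout) - 1

    first = np.flatnonzero(new_bout)
    last = np.concatenate([first[1:] - 1, [len(records) - 1]])

    # why the NEXT record (if same bird) ended this bout
    reason = np.full(len(first), "end_of_log", dtype=object)
    has_next = last + 1 < len(records)
    nxt = np.minimum(last + 1, len(records) - 1)
    same_bird_next = has_next & (birds[nxt] == birds[last])
    gap_next = np.where(has_next, t[nxt] - t[last], 0)
    reason[same_bird_next & (gap_next > params.record_gap_threshold_s)] = "gap"
    reason[same_bird_next & (gap_next <= params.record_gap_threshold_s)] = "switch"

    start = records["timestamp"].to_numpy()[first]
    end = records["timestamp"].to_numpy()[last]
    return pd.DataFrame(
        {
            "bird_id": birds[first],
            "feeder_id": ants[first].astype(int),
            "start": start,
            "end": end,
            "duration_s": (t[last] - t[first] + 1).astype(int),
            "close_reason": reason,
        }
    )


def merge_oracle(records: pd.DataFrame, params: SegmentationParams) -> pd.DataFrame:
    """Quadratic reference segmentation used only in tests.

    Builds, per bird, the pairwise relation "same feeder, gap within
    threshold, no different-feeder detection in between" and takes its
    transitive closure with union-find; each component is a bout. Intended
    for small inputs (<= 1e4 records).
    """
    if records.empty:
        return pd.DataFrame(columns=list(BOUT_COLUMNS))
    _check_sorted(records)

    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    birds = records["bird_id"].tolist()
    ants = records["antenna_id"].tolist()
    t = records["timestamp"].to_numpy().astype("datetime64[s]").astype(np.int64).tolist()

    thr = params.record_gap_threshold_s
    for i in range(n):
        for j in range(i + 1, n):
            if birds[j] != birds[i]:
                break
            if ants[j] != ants[i] or t[j] - t[i] > thr:
                break  # a feeder change or an over-threshold span blocks the pair
            union(i, j)

    comp_members: dict[int, list[int]] = {}
    for i in range(n):
        comp_members.setdefault(find(i), []).append(i)

    rows = []
    for members in comp_members.values():
        members.sort(key=lambda i: t[i])
        i0, i1 = members[0], members[-1]
        nxt = i1 + 1
        if nxt >= n or birds[nxt] != birds[i1]:
            reason = "end_of_log"
        elif t[nxt] - t[i1] > thr:
            reason = "gap"
        else:
            reason = "switch"
        rows.append(
            {
                "bird_id": birds[i0],
                "feeder_id": int(ants[i0]),
                "start": records["timestamp"].iloc[i0],
                "end": records["timestamp"].iloc[i1],
                "duration_s": int(t[i1] - t[i0] + 1),
                "close_reason": reason,
            }
        )
    out = pd.DataFrame(rows, columns=list(BOUT_COLUMNS))
    out["start"] = out["start"].astype("datetime64[s]")
    out["end"] = out["end"].astype("datetime64[s]")
    return out.sort_values(["bird_id", "start"], kind="mergesort").reset_index(drop=True)
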