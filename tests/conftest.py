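import datetime as dt

import numpy as np
import pandas as pd
import pytest

from broilerfeed import FlockConfig, PenLayout, SegmentationParams, emit_detections, simulate_flock


def make_records(rows):
    """Detection DataFrame from (iso_timestamp, bird_id, antenna_id) tuples."""
    df = pd.DataFrame(rows, columns=["timestamp", "bird_id", "antenna_id"])
    df["timestamp"] = pd.to_datetime(df["timestamp"]).astype("datetime64[s]")
    df["antenna_id"] = df["antenna_id"].astype(int)
    df["bird_id"] = df["bird_id"].astype(str)
    return df.sort_values(["bird_id", "timestamp"]).reset_index(drop=True)


def ts(second, base="2022-06-21T08:00:00"):
    return (pd.Timestamp(base) + pd.Timedelta(seconds=second)).isoformat()


@pytest.fixture(scope="session")
def layout():
    return PenLayout.default()


@pytest.fixture
def seg_params():
    return SegmentationParams()


@pytest.fixture(scope="session")
def small_config():
    return FlockConfig(
        n_birds=8,
        age_start=20,
        age_end=23,
        mean_nfv=12.0,
        mean_mfbd_s=40.0,
        mean_ndf=4.0,
        var_id={"nfv": 9.0, "mfbd": 36.0, "ndf": 0.5},
        var_resid={"nfv": 16.0, "mfbd": 100.0, "ndf": 1.0},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_flock(small_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_detections(small_truth):
    return emit_detections(small_truth, np.random.default_rng(8))
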