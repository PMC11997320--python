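"""Agent-based synthetic flock: ground-truth feeding bouts and raw RFID logs.

Generates, per bird, latent covariates (start body weight, daily gain with
a configurable correlation between the two, sex, gait scores) and per
bird-day realized feeding behaviour whose expectations follow linear
predictors with per-bird random intercepts: visit counts are Poisson around
the (positive-truncated) predictor, bout durations are log-normal with mean
tied to the duration predictor, and the number of distinct feeders used
tracks its own predictor. Bouts are placed without overlap inside a daily
active window with a minimum separation larger than the effective gap
threshold, so that downstream segmentation can recover them exactly.

``emit_detections`` turns true bouts into a 1 Hz record stream, optionally
dropping an interior run of seconds per bout (a detection drop-out the
segmenter must re-merge) and appending the reader's 6 s auto-extension
after the last true detection of every bout.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .rfid_io import PenLayout

logger = logging.getLogger(__name__)

#: reference covariate values at which the configured means apply
REF_AGE = 25.0
REF_START_BW = 596.0
REF_BW_GAIN = 91.38


def _default_betas() -> dict[str, dict[str, float]]:
    return {
        "nfv": {"age_days": -2.212},
        "mfbd": {"age_days": 2.192, "start_bw_g": 0.130, "bw_gain_g_d": -0.390},
        "ndf": {"age_days": -0.396, "start_bw_g": -0.011, "bw_gain_g_d": 0.028},
    }


def _default_var_id() -> dict[str, float]:
    return {"nfv": 232.4, "mfbd": 223.5, "ndf": 1.155}


def _default_var_resid() -> dict[str, float]:
    return {"nfv": 368.3, "mfbd": 900.0, "ndf": 4.586}


@dataclass
class FlockConfig:
    """Everything the simulator needs; all defaults give a flock with the
    same statistical structure the analysis pipeline assumes."""

    n_birds: int = 58
    age_start: int = 20
    age_end: int = 30
    layout: PenLayout = field(default_factory=PenLayout.default)
    hatch_date: dt.date = dt.date(2022, 6, 1)
    active_window_start_h: float = 5.0
    active_window_length_h: float = 16.0

    start_bw_mean: float = 596.0
    start_bw_sd: float = 52.0
    bw_gain_mean: float = 91.38
    bw_gain_sd: float = 18.0
    bw_corr: float = 0.30
    p_male: float = 0.5
    gait27_probs: tuple[float, ...] = (0.02, 0.16, 0.53, 0.22, 0.05, 0.02)

    #: daily means at the reference covariates (age 25, BW 596 g, gain 91.38 g/d)
    mean_nfv: float = 56.1
    mean_mfbd_s: float = 103.0
    mean_ndf: float = 9.8
    betas: dict[str, dict[str, float]] = field(default_factory=_default_betas)
    var_id: dict[str, float] = field(default_factory=_default_var_id)
    var_resid: dict[str, float] = field(default_factory=_default_var_resid)
    effect_scale: float = 1.0

    kappa: float = 1.0  # Dirichlet concentration per feeder (site fidelity)
    duration_sigma: float = 0.5  # log-normal shape of bout durations
    min_bout_duration_s: int = 2
    min_between_bout_gap_s: int = 32  # > effective gap threshold + 1
    dropout_prob: float = 0.5
    max_dropout_gap_s: int = 20
    auto_extension_s: int = 6
    truncate_extension: bool = True
    visit_unmonitored: bool = False
    on_infeasible: str = "clip"  # or "error"
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.var_id.values()) or any(v < 0 for v in self.var_resid.values()):
            raise ValueError("variance components must be >= 0")
        if not 0 <= self.p_male <= 1:
            raise ValueError("p_male must be in [0, 1]")
        if abs(sum(self.gait27_probs) - 1) > 1e-9:
            raise ValueError("gait27_probs must sum to 1")
        if not 0 < self.active_window_length_h <= 24:
            raise ValueError("active window must be within 24 h")
        if self.on_infeasible not in ("clip", "error"):
            raise ValueError("on_infeasible must be 'clip' or 'error'")

    @property
    def ages(self) -> range:
        return range(self.age_start, self.age_end + 1)

    def intercept(self, response: str) -> float:
        """Intercept implied by the reference-point mean and (scaled) slopes."""
        ref = {"age_days": REF_AGE, "start_bw_g": REF_START_BW, "bw_gain_g_d": REF_BW_GAIN}
        mean = {"nfv": self.mean_nfv, "mfbd": self.mean_mfbd_s, "ndf": self.mean_ndf}[response]
        b = self.betas[response]
        return mean - self.effect_scale * sum(b.get(k, 0.0) * v for k, v in ref.items())


@dataclass
class GroundTruth:
    """Simulation truth: bouts, per-bird-day targets, preferences, covariates."""

    bouts: pd.DataFrame        # bird_id, age_days, feeder_id, start, duration_s, observable
    bird_days: pd.DataFrame    # bird_id, age_days, lam_nfv, target_mfbd_s, target_ndf, nfv, ndf
    preferences: pd.DataFrame  # bird_id x feeder columns
    covariates: pd.DataFrame   # wide covariate table
    config: FlockConfig

    def observable_bouts(self) -> pd.DataFrame:
        return self.bouts[self.bouts["observable"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# covariate generation
# ---------------------------------------------------------------------------


def draw_bird_covariates(config: FlockConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Wide covariate table for the flock (same schema as ``read_covariates``)."""
    n = config.n_birds
    ids = [f"B{i:03d}" for i in range(1, n + 1)]
    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    cov = np.array(
        [
            [config.start_bw_sd**2, config.bw_corr * config.start_bw_sd * config.bw_gain_sd],
            [config.bw_corr * config.start_bw_sd * config.bw_gain_sd, config.bw_gain_sd**2],
        ]
    )
    latent = rng.multivariate_normal([config.start_bw_mean, config.bw_gain_mean], cov, size=n)
    bw14 = np.clip(latent[:, 0], 300.0, None).round(0)
    gain = np.clip(latent[:, 1], 20.0, None)
    bw35 = (bw14 + 21 * gain).round(0)
    bw21 = np.clip(bw14 + 7 * gain + rng.normal(0, 30, n), 350.0, None).round(0)
    bw27 = np.clip(bw14 + 13 * gain + rng.normal(0, 40, n), 400.0, None).round(0)

    def scores(lam: float) -> np.ndarray:
        return np.minimum(rng.poisson(lam, n), 5)

    gait27 = rng.choice(6, size=n, p=np.asarray(config.gait27_probs))
    gait21 = np.clip(gait27 - rng.integers(0, 2, n), 0, 5)
    gait35 = np.clip(gait27 + rng.integers(0, 2, n), 0, 5)

    table = pd.DataFrame({"bird_id": ids, "sex": sex,
                          "bw_14": bw14, "bw_21": bw21, "bw_27": bw27, "bw_35": bw35})
    for age, hb_lam, fpd_lam in ((21, 0.7, 0.5), (27, 1.1, 0.65), (35, 1.8, 1.0)):
        table[f"hb_left_{age}"] = scores(hb_lam)
        table[f"hb_right_{age}"] = scores(hb_lam)
        table[f"fpd_left_{age}"] = scores(fpd_lam)
        table[f"fpd_right_{age}"] = scores(fpd_lam)
    table["gait_21"], table["gait_27"], table["gait_35"] = gait21, gait27, gait35
    return table


# ---------------------------------------------------------------------------
# behaviour simulation
# ---------------------------------------------------------------------------


def _linear_predictor(config: FlockConfig, response: str, age: float,
                      sw: np.ndarray, wg: np.ndarray) -> np.ndarray:
    b = config.betas[response]
    s = config.effect_scale
    return (config.intercept(response)
            + s * b.get("age_days", 0.0) * age
            + s * b.get("start_bw_g", 0.0) * sw
            + s * b.get("bw_gain_g_d", 0.0) * wg)


def simulate_flock(config: FlockConfig,
                   rng: np.random.Generator | int | None = None) -> GroundTruth:
    """Simulate ground-truth feeding behaviour for a whole flock.

    Identical seeds give bit-identical output. Raises on an infeasible day
    (total requested bout time exceeding the active window) when
    ``config.on_infeasible == "error"``; the default clips the day's bout
    list to what fits, with a logged count.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)

    covariates = draw_bird_covariates(config, rng)
    n = config.n_birds
    sw = covariates["bw_14"].to_numpy(dtype=float)
    wg = (covariates["bw_35"].to_numpy(dtype=float) - sw) / 21.0

    feeders = np.array(sorted(config.layout.feeder_ids))
    if not config.visit_unmonitored:
        feeders = np.array(sorted(config.layout.antenna_equipped))
    prefs = rng.dirichlet(np.full(len(feeders), config.kappa), size=n)
    pref_df = pd.DataFrame(prefs, columns=[f"feeder_{f}" for f in feeders])
    pref_df.insert(0, "bird_id", covariates["bird_id"])

    u = {r: rng.normal(0.0, np.sqrt(config.var_id[r]), n) for r in ("nfv", "mfbd", "ndf")}

    window_s = int(config.active_window_length_h * 3600)
    window_start = int(config.active_window_start_h * 3600)
    gap = config.min_between_bout_gap_s

    bout_rows: list[dict] = []
    day_rows: list[dict] = []
    n_clipped = 0
    for age in config.ages:
        date = config.hatch_date + dt.timedelta(days=int(age))
        day_anchor = np.datetime64(date, "s").astype(np.int64) + window_start
        e = {r: rng.normal(0.0, np.sqrt(config.var_resid[r]), n) for r in ("nfv", "mfbd", "ndf")}
        lam = np.maximum(_linear_predictor(config, "nfv", age, sw, wg) + u["nfv"] + e["nfv"], 0.0)
        nfv = rng.poisson(lam)
        m = np.maximum(_linear_predictor(config, "mfbd", age, sw, wg) + u["mfbd"] + e["mfbd"],
                       float(config.min_bout_duration_s + 1))
        ndf_target = np.rint(
            _linear_predictor(config, "ndf", age, sw, wg) + u["ndf"] + e["ndf"]
        ).astype(int)

        for j in range(n):
            k = int(nfv[j])
            realized_ndf = 0
            if k > 0:
                mu_log = np.log(m[j]) - config.duration_sigma**2 / 2
                durations = np.maximum(
                    np.rint(rng.lognormal(mu_log, config.duration_sigma, k)).astype(int),
                    config.min_bout_duration_s,
                )
                # feasibility: total busy time + minimum separations must fit
                while k > 0 and durations.sum() + (k - 1) * gap > window_s:
                    if config.on_infeasible == "error":
                        raise ValueError(
                            f"infeasible day: bird {j} age {age} needs "
                            f"{durations.sum() + (k - 1) * gap} s > window {window_s} s"
                        )
                    durations = durations[:-1]
                    k -= 1
                    n_clipped += 1
                if k > 0:
                    p_j = prefs[j]
                    # effective support: a site-faithful bird (kappa -> 0)
                    # cannot be forced onto feeders it never uses
                    eligible = np.flatnonzero(p_j > 1e-4)
                    if eligible.size == 0:
                        eligible = np.array([int(np.argmax(p_j))])
                    d_target = int(np.clip(ndf_target[j], 1, min(k, eligible.size)))
                    chosen = rng.choice(eligible, size=d_target, replace=False,
                                        p=p_j[eligible] / p_j[eligible].sum())
                    extra = rng.choice(chosen, size=k - d_target, replace=True,
                                       p=p_j[chosen] / p_j[chosen].sum()) if k > d_target else \
                        np.empty(0, dtype=int)
                    assign = rng.permutation(np.concatenate([chosen, extra]))
                    free = window_s - int(durations.sum()) - (k - 1) * gap
                    cuts = np.sort(rng.random(k)) * free
                    offsets = np.floor(cuts).astype(np.int64) \
                        + np.concatenate([[0], np.cumsum(durations[:-1] + gap)])
                    starts = day_anchor + offsets
                    bird = covariates["bird_id"].iloc[j]
                    for fidx, d, s0 in zip(assign, durations, starts):
                        bout_rows.append({
                            "bird_id": bird,
                            "age_days": int(age),
                            "feeder_id": int(feeders[fidx]),
                            "start": int(s0),
                            "duration_s": int(d),
                            "observable": int(feeders[fidx]) in config.layout.antenna_equipped,
                        })
                    realized_ndf = len(np.unique(assign))
            day_rows.append({
                "bird_id": covariates["bird_id"].iloc[j],
                "age_days": int(age),
                "lam_nfv": float(lam[j]),
                "target_mfbd_s": float(m[j]),
                "target_ndf": int(ndf_target[j]),
                "nfv": int(k),
                "ndf": int(realized_ndf),
            })
    if n_clipped:
        logger.info("clipped %d bout(s) from infeasible days", n_clipped)

    bouts = pd.DataFrame(bout_rows,
                         columns=["bird_id", "age_days", "feeder_id", "start",
                                  "duration_s", "observable"])
    if not bouts.empty:
        bouts["start"] = bouts["start"].astype("datetime64[s]")
        bouts = bouts.sort_values(["bird_id", "start"], kind="mergesort").reset_index(drop=True)
    return GroundTruth(
        bouts=bouts,
        bird_days=pd.DataFrame(day_rows),
        preferences=pref_df,
        covariates=covariates,
        config=config,
    )


# ---------------------------------------------------------------------------
# detection emission
# ---------------------------------------------------------------------------


def emit_detections(truth: GroundTruth,
                    rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Turn true bouts into a 1 Hz detection-record stream.

    Per observable bout: one record per second of presence; with
    probability ``dropout_prob`` one interior run of 1..max_dropout_gap_s
    seconds is dropped (first and last true seconds always kept); after the
    last true detection, ``auto_extension_s`` extension records are
    appended at the same antenna, truncated if the bird's next bout starts
    sooner (when ``truncate_extension``).
    """
    config = truth.config
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    bouts = truth.observable_bouts()
    if bouts.empty:
        return pd.DataFrame({"timestamp": pd.Series(dtype="datetime64[s]"),
                             "bird_id": pd.Series(dtype=str),
                             "antenna_id": pd.Series(dtype=int)})

    d = bouts["duration_s"].to_numpy(dtype=np.int64)
    start = bouts["start"].to_numpy().astype("datetime64[s]").astype(np.int64)
    nb = len(bouts)

    # at most one interior drop-out gap per bout
    can_gap = d >= config.min_bout_duration_s + 2
    has_gap = (rng.random(nb) < config.dropout_prob) & can_gap & (d >= 4)
    max_len = np.minimum(config.max_dropout_gap_s, d - 3)
    gap_len = np.where(has_gap, rng.integers(1, np.maximum(max_len, 1) + 1), 0)
    gap_pos = np.where(has_gap, 1 + (rng.random(nb) * (d - gap_len - 2)).astype(np.int64), -1)

    # extension length, truncated when the bird's next bout begins sooner
    end = start + d - 1
    ext_len = np.full(nb, int(config.auto_extension_s), dtype=np.int64)
    if config.truncate_extension and config.auto_extension_s > 0:
        birds = bouts["bird_id"].to_numpy()
        next_start = np.full(nb, np.iinfo(np.int64).max)
        same_next = np.flatnonzero(birds[:-1] == birds[1:])
        next_start[same_next] = start[same_next + 1]
        ext_len = np.minimum(ext_len, np.maximum(next_start - end - 1, 0))

    # each bout expands to <= 3 contiguous 1 Hz runs: before the drop-out
    # gap, after it, and the auto-extension; runs are already in
    # (bird, time) order because same-bird bouts never overlap
    len1 = np.where(has_gap, gap_pos, d)
    len2 = np.where(has_gap, d - gap_pos - gap_len, 0)
    run_start = np.stack([start, start + gap_pos + gap_len, end + 1], axis=1).ravel()
    run_len = np.stack([len1, len2, ext_len], axis=1).ravel()
    run_bout = np.repeat(np.arange(nb)[:, None], 3, axis=1).ravel()
    nz = run_len > 0
    run_start, run_len, run_bout = run_start[nz], run_len[nz], run_bout[nz]

    total = int(run_len.sum())
    rec_bout = np.repeat(run_bout, run_len)
    off = np.arange(total) - np.repeat(np.cumsum(run_len) - run_len, run_len)
    rec_times = np.repeat(run_start, run_len) + off
    out = pd.DataFrame({
        "timestamp": rec_times.astype("datetime64[s]"),
        "bird_id": bouts["bird_id"].to_numpy()[rec_bout],
        "antenna_id": bouts["feeder_id"].to_numpy()[rec_bout].astype(int),
    })
    logger.info("emitted %d detection records for %d bouts", len(out), nb)
    return out


# ---------------------------------------------------------------------------
# direct Gaussian generator (for parameter-recovery studies)
# ---------------------------------------------------------------------------


def simulate_model_table(
    response: str,
    betas: Mapping[str, float],
    intercept: float,
    var_id: float,
    var_resid: float,
    *,
    n_birds: int = 58,
    ages: range = range(20, 31),
    rng: np.random.Generator | int | None = None,
    config: FlockConfig | None = None,
) -> pd.DataFrame:
    """Bird-day table with a Gaussian response drawn exactly from the
    random-intercept model (the analysis model, not the agent-based one).

    Covariates are drawn per bird as in ``draw_bird_covariates``; the
    response column is named after ``response`` (nfv -> nfv, mfbd ->
    mfbd_s, ndf -> ndf).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    config = config or FlockConfig(n_birds=n_birds)
    config = replace(config, n_birds=n_birds)
    cov = draw_bird_covariates(config, rng)
    sw = cov["bw_14"].to_numpy(dtype=float)
    wg = (cov["bw_35"].to_numpy(dtype=float) - sw) / 21.0
    sex = np.where(cov["sex"].to_numpy() == "female", 1.0, -1.0)
    gait = np.where(cov["gait_27"].to_numpy() <= 2, 1.0, -1.0)

    u = rng.normal(0.0, np.sqrt(var_id), n_birds)
    rows = []
    colname = {"nfv": "nfv", "mfbd": "mfbd_s", "ndf": "ndf"}.get(response, response)
    for age in ages:
        lp = (intercept
              + betas.get("age_days", 0.0) * age
              + betas.get("start_bw_g", 0.0) * sw
              + betas.get("bw_gain_g_d", 0.0) * wg
              + betas.get("sex", 0.0) * sex
              + betas.get("gait_class", 0.0) * gait)
        y = lp + u + rng.normal(0.0, np.sqrt(var_resid), n_birds)
        for j in range(n_birds):
            rows.append({
                "bird_id": cov["bird_id"].iloc[j],
                "age_days": int(age),
                colname: float(y[j]),
                "sex": cov["sex"].iloc[j],
                "gait_class": "GG" if cov["gait_27"].iloc[j] <= 2 else "SG",
                "start_bw_g": float(sw[j]),
                "bw_gain_g_d": float(wg[j]),
            })
    return pd.DataFrame(rows)
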