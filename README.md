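# broilerfeed

Analysis pipeline for RFID feeder-visit logs of group-housed broilers,
paired with an agent-based synthetic-flock simulator that provides ground
truth for testing every stage.

The pipeline turns 1 Hz presence records (timestamp, bird tag, antenna
number) into:

1. **Feeding bouts** — maximal runs of same-bird, same-feeder detections
   merged across record gaps of up to 24 s. Because the reader keeps
   reporting a tag at its last antenna for a further 6 s, the effective
   wall-clock meal criterion is 30 s. A detection at a different antenna
   always closes the current bout.
2. **Daily descriptors** per bird — NFV (number of feeder visits), MFBD
   (mean feeding bout duration, s) and NDF (number of different feeders
   visited), with a pooled 4-SD outlier filter applied per descriptor and
   per observation.
3. **Covariates** per bird — sex, start body weight (14 d), body-weight
   gain ((BW35 − BW14)/21 g/day), summed hock-burn / footpad-dermatitis
   scores, and the good/suboptimal gait dichotomy (27 d score ≤ 2 vs ≥ 3),
   plus a descriptive correlation matrix.
4. **Mixed models** — random-intercept (per bird) linear models for each
   descriptor with sum-to-zero contrasts, REML estimation, Type III
   single-df F/t tests, backward elimination at P > 0.05 respecting
   marginality, and marginal/conditional R². The REML fit is profiled down
   to a one-dimensional variance-ratio optimization, which makes the
   Monte-Carlo validation studies (coverage, selection behaviour) cheap;
   it is cross-checked against `statsmodels` MixedLM in the test suite.

The simulator (`broilerfeed.synthetic_flock`) draws per-bird latent
covariates and realizes bird-day behaviour whose expectations follow the
same linear predictors the models assume, then emits raw 1 Hz detection
streams including within-bout detection drop-outs and the reader's 6 s
auto-extension, so that segmentation can be validated round-trip.

## Command line

```sh
broilerfeed all --seed 1 --out runs/demo          # simulate + full pipeline
broilerfeed simulate --seed 1 --n-birds 58 --out runs/sim
broilerfeed segment --log runs/sim/detections.csv --layout runs/sim/layout.yaml \
    --gap-threshold 24 --extension 6 --out runs/seg
broilerfeed describe --bouts runs/seg/bouts.csv --hatch-date 2022-06-01 \
    --outlier-k 4 --out runs/desc
broilerfeed model --descriptors runs/desc/descriptors.csv \
    --covariates runs/sim/covariates.csv --alpha 0.05 --out runs/model
broilerfeed report --bouts runs/seg/bouts.csv --descriptors runs/desc/descriptors.csv \
    --covariates runs/sim/covariates.csv --out runs/report
```

Every subcommand writes a JSON run report echoing its full configuration;
identical configuration and seed reproduce byte-identical tabular outputs.
Exit codes: 2 = missing input, 3 = validation failure.

## Layout

```
src/broilerfeed/
  rfid_io.py           detection-log and covariate-table I/O, pen layout
  bout_segmentation.py gap-merging segmenter + quadratic test oracle
  descriptors.py       NFV/MFBD/NDF and the k-SD outlier filter
  covariates.py        BW gain, gait classes, leg-score sums, correlations
  mixed_models.py      profiled-REML random-intercept LMM, backward selection
  synthetic_flock.py   agent-based simulator and detection emission
  report_cli.py        click CLI, figures, run reports
```
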