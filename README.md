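# migrainecast

Per-patient migraine forecasting from ambulatory wearable signals.

The pipeline turns raw multi-rate sensor channels — skin temperature (TEMP,
1 Hz), electrodermal activity (EDA, 1 Hz), heart rate derived from a 250 Hz
ECG, and SpO2 (3 Hz) — into ranked ensembles of linear state-space models
that predict a normalized symptomatic pain curve tens of minutes ahead,
with false-positive repair and sensor-fault-aware model selection.

## Modules

| module | role |
|---|---|
| `migrainecast.synthetic` | synthetic ambulatory patient generator with known ground truth (circadian drift, pre-ictal latent driver, noise, gaps, saturations) |
| `migrainecast.pain` | subjective pain annotations → two-semi-Gaussian symptomatic curve |
| `migrainecast.repair` | FIR decimation to a 1-min grid, Gaussian-process gap filling, ECG→HR peak detection |
| `migrainecast.ssm` | subspace (N4SID-style) identification, k-step-ahead prediction, fit metric, (past horizon × order) training grid |
| `migrainecast.ensemble` | linear decider, iterative false-positive repair, cross-validation ranking, top-third average model |
| `migrainecast.evaluation` | event-level TPR/PPV/F-score, sensor-fault suites, SDMS² fallback hierarchy |
| `migrainecast.workflow` | episode split, per-subset study, real-time replay, structured logging |

## CLI

```bash
migrainecast synth --days 14 --migraines 6 --seed 0 --out data/patient0
migrainecast preprocess --indir data/patient0 --out data/frame.csv
migrainecast fit      --frame data/frame.csv --annotations data/patient0/annotations.json --out data/models.json
migrainecast validate --frame data/frame.csv --annotations data/patient0/annotations.json --models data/models.json --out data/ranking.csv
migrainecast evaluate --frame data/frame.csv --annotations data/patient0/annotations.json --out data/metrics.json
migrainecast realtime --frame data/frame.csv --annotations data/patient0/annotations.json --out data/alarms.jsonl
```

All subcommands accept `--config study.yaml` with keys matching
`migrainecast.workflow.StudyConfig` (split fraction, horizons, fit/decider
thresholds, training grid, ...).

## Notes

* Predicted curves are clamped to [−0.2, 1.2] before the probability
  mapping; the linear decider opens a detection at 50 % probability and the
  repair pass removes supra-threshold excursions shorter than 60 min.
* A model's achievable horizon is the largest look-ahead whose repaired
  prediction still fits the symptomatic curve at ≥ 70 %.
* Heavy stages (training grid, cross-validation) accept reduced grids via
  `StudyConfig(ph_values=..., nx_values=...)`; the defaults reproduce the
  full 20 × 10 grid.
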