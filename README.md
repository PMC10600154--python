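# calfmove

Movement personality, plasticity and pen-mate conformity analysis for
penned calves tracked with indoor (UWB-style) positioning sensors — with a
synthetic generator standing in for farm data, so the whole pipeline is
testable offline.

The pipeline mirrors a standard behavioural-repeatability study design:
calves live first in pairs, then move into cohort group pens; 1 Hz
positional tracks are cleaned and reduced to two daily movement metrics,
which feed Gaussian mixed models and a pen-mate similarity test.

## What's inside

| Module | Purpose |
| --- | --- |
| `calfmove.simgen` | Synthetic rosters, daily metric panels drawn from the random-slope mixed-model structure (with known ground truth), and two-state rest/move trajectory simulation with sensor noise |
| `calfmove.preprocess` | Exclusion intervals (half-open, union semantics), out-of-pen filtering, centred 10-s moving-average smoothing, coverage accounting |
| `calfmove.metrics` | Daily distance travelled, residence time (1-m circle, 60-s tolerated excursions, bidirectional scan), CEP and DIST static-tag validation statistics |
| `calfmove.lmm` | REML mixed models: nested cohort + individual random intercepts, correlated individual intercept + housing slope; adjusted repeatability `R = V_ind0 / (V_ind0 + V_e0)` with parametric-bootstrap CIs; intercept–slope (personality–plasticity) correlation; pen-mate carry-over model |
| `calfmove.penmate` | CV of absolute pen-mate intercept differences and its within-cohort permutation test |
| `calfmove.cli` | `calfmove` command: `simulate`, `preprocess`, `metrics`, `analyze`, `penmate`, `run`, `fixtures` |

The model layer is backed by a small profiled-REML engine
(`calfmove._reml`) because the required random-effects structure (cohort
intercept plus correlated per-individual intercept/slope) is not
expressible in statsmodels' `MixedLM`; the engine is validated in the test
suite against statsmodels on the nested-intercept model and against dense
first-principles REML algebra.

## CLI quick start

```bash
# end-to-end demo on synthetic tracks (1 cohort, 4 calves, short days)
cat > demo.yaml <<'YAML'
seed: 5
roster: {n_cohorts: 1, calves_per_cohort: 4}
days_per_housing: 5
day_length_s: 300.0
trajectory_sim: {rest_to_move_rate: 0.05, move_to_rest_rate: 0.05, sensor_noise_sd: 0.1}
model: {boot: 100}
penmate: {B: 1000}
YAML
calfmove run --config demo.yaml --out demo_out
cat demo_out/manifest.json
```

Individual stages work on plain CSV files, e.g.:

```bash
calfmove simulate tracks --config demo.yaml --out sim_out
calfmove preprocess --traj sim_out/tracks_observed.csv --pen group \
    --out clean.csv --report coverage.json
calfmove metrics --traj clean.csv --roster sim_out/roster_calves.csv \
    --out panel.csv --day-length 300 --days-per-housing 5
calfmove analyze --metrics panel.csv --model intercept --metric distance \
    --boot 1000 --seed 1 --out fits/
calfmove penmate --effects fits/effects_intercept_distance.csv \
    --roster sim_out/roster_calves.csv --B 10000 --seed 1 --out penmate_out/
```

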