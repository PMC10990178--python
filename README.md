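# springgait

Spring-mass running-gait analysis: derive temporal and spring-mass variables
(step frequency, swing time, duty factor, peak vertical force, centre-of-mass
displacement, leg compression, leg stiffness) from per-step contact and
flight times, compare two groups of runners across three speeds with a
repeated-measures statistical workflow, and simulate calibrated synthetic
cohorts for testing and power studies.

## What's inside

| Module | Role |
| --- | --- |
| `springgait.gait_model` | Closed-form forward model (sine-wave stance force) and its numerical inverse |
| `springgait.trial_processing` | CSV ingestion, ±5 % trial-speed acceptance, step aggregation, long-format cohort table |
| `springgait.cohort_stats` | Normality/homogeneity checks, split-plot (mixed) ANOVA with Mauchly-gated Greenhouse-Geisser correction, Holm post-hocs, Cohen's d, CIs of mean differences |
| `springgait.synthetic_cohort` | Cohort simulator calibrated by inverting the forward model against published group summaries |
| `springgait.cli` | `springgait` command: `simulate`, `derive`, `analyze`, `report`, `all` |

All internal computation is SI; reporting units (ms, cm, kN/m, %) appear only
at I/O boundaries.

## CLI

```bash
# full pipeline on a simulated cohort (deterministic per seed)
springgait all --seed 1 --out-dir runs/demo

# or step by step
springgait simulate --seed 1 --out-dir runs/demo          # participants.csv, trials.csv
springgait derive --participants runs/demo/participants.csv \
                  --trials runs/demo/trials.csv --out-dir runs/demo   # cohort.csv
springgait analyze --cohort runs/demo/cohort.csv \
                   --participants runs/demo/participants.csv \
                   --alpha 0.05 --out-dir runs/demo       # results_*.csv
springgait report --results-dir runs/demo                 # markdown to stdout
```

`simulate --null` generates a no-group-effect cohort (identical calibration
targets for both groups), used for type-I-error calibration. A YAML config
(`--config`) can override any `SimulationConfig` field; every run writes a
`manifest.json` with seeds, input digests and row counts.

Input schemas (plain CSV):

- `participants.csv`: `participant_id, sex, age_y, height_cm, mass_kg,
  weekly_hours, axis_ei, axis_sn, axis_tf, axis_jp`
- `trials.csv`: `participant_id, requested_speed_ms, measured_speed_ms,
  step_index, tc_ms, tf_ms` (optional `granularity` column: `step` |
  `aggregated`)

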