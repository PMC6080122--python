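# cgmeval

Measurement-performance evaluation of continuous glucose monitoring (CGM)
systems against blood glucose references, packaged as a reusable, tested
pipeline:

* **study_model** — domain types (sensor traces, reference measurements,
  paired observations) and a plain-CSV interchange format. Time is ISO 8601
  UTC at second resolution; glucose is mg/dL throughout (mmol/L offered as a
  reader option, factor 18.016).
* **synthetic** — a synthetic study generator emulating a 14-day,
  20-participant design: true glucose process (baseline + circadian +
  meal responses + OU noise), lagged/noisy/clamped sensors with dropout,
  scheduled duplicate reference measurements with a conditional third
  replicate, induced rapid-excursion mornings with 15-min capillary and
  venous sampling, and therapeutic-decision flags. Fully deterministic
  given seeds.
* **pairing** — the three pairing rules: LOCF (closed 5-min window before
  the reference), scan matching (±3 min, ties toward the earlier scan), and
  minutely linear interpolation (gap-limited, no extrapolation).
* **metrics** — threshold exceedance (strict `>`, with the ISO-style
  "within" complement), MAD (< 100 mg/dL) / MARD (≥ 100 mg/dL) with
  combined and whole-range variants, hourly thinning, sensor-to-sensor
  PAD/PARD, and stratifiers (phase, wear day, glucose range, trend,
  therapeutic decision, reference method).
* **error_grid** — consensus (Parkes) error grid, type 1 variant. Zone
  boundary vertices ship as a versioned CSV (`src/cgmeval/data/`);
  boundary points resolve to the lower-risk zone; inputs outside
  [0, 550] mg/dL are rejected, never clamped.
* **reporting** — exceedance and performance report assembly across
  evaluation units (aggregated / sensor / application site / participant)
  and data sets (complete / in-house / home use / dynamic / therapeutic
  decisions), JSON as the contract plus rendered CSV, and the end-to-end
  pipeline with a manifest.

## CLI

```bash
# full pipeline: simulate -> pair -> evaluate -> report
cgmeval run --out out/ --seed 1 --participants 2 --days 3

# individual stages
cgmeval simulate --config config.yaml --out study/ --seed 1
cgmeval pair --study study/ --mode default --out pairs.csv
cgmeval evaluate --pairs pairs.csv --unit aggregated --dataset decisions --out metrics.json
cgmeval ceg --pairs pairs.csv --out zones.csv
cgmeval report --study study/ --out reports/
```

A config file is YAML with `study:` (StudyConfig fields, optionally a
nested `profile:`) and `models:` (per-system sensor error parameters):

```yaml
study:
  n_participants: 20
  n_days: 14
  visit_windows: [[0, 2], [5, 7], [12, 14]]
  dynamic_days: [1, 6, 13]
  seed: 1
models:
  DG5-like: {lag_tau_minutes: 8, proportional_sd: 0.10, additive_sd_mgdl: 4, dropout_prob: 0.01}
  FL-like:  {lag_tau_minutes: 8, proportional_sd: 0.11, additive_sd_mgdl: 5, dropout_prob: 0.005}
```

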