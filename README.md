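# picuree

A resting-energy-expenditure (REE) prediction pipeline for critically ill
children, exercised end-to-end on synthetic PICU cohorts:

- **`picuree.cohort`** — synthetic cohort and minute-resolution
  calorimetry-series generation with known ground truth (exact-Weir or
  covariate-driven REE mechanisms), structured MCAR missingness, and full
  determinism per seed.
- **`picuree.calorimetry`** — steady-state window detection (≥5 min, <5% RQ
  variation, <10% gas/ventilation variation), RQ plausibility filtering
  (0.67–1.3, strict exclusion), and the abbreviated Weir conversion.
- **`picuree.anthropometry`** — LMS growth z-scores against a bundled
  fixture reference table (same CSV schema as real reference tables) with
  age-availability rules (weight-for-height ≤5 y, weight-for-age ≤10 y) and
  stunting/wasting/overweight/obesity classification.
- **`picuree.equations`** — ten predictive REE equations/formulae behind a
  versioned registry CSV: Harris–Benedict (adult + infant forms), Schofield
  (W, W&H), Oxford (W, W&H), FAO/WHO/UNU, Talbot weight/height lookup
  tables, and the VCO₂-only estimator for ventilated patients.
- **`picuree.twist`** — joint evolutionary input selection and
  distribution-matched train/test splitting: an elitist GA over a
  (feature-mask, split-assignment) chromosome scored by blind MLP
  performance minus a distributional-mismatch penalty.
- **`picuree.ann`** — one-hidden-layer MLP (4 units by default) with owned
  standardization and the train/test reversal protocol (one blind
  prediction per record, fold-isolated scalers and weights).
- **`picuree.evaluation`** — the comparison-statistics suite (MAE, mean
  relative error, two accuracy percentages, Pearson R², two-sample
  variance-ratio F test), variable screening, correlation profiles,
  fit-curve exports, and experiment orchestration over the 24/32-variable
  dataset variants and gas-inclusion ablations.

## CLI

```sh
picuree simulate --seed 1 --out cohort.csv              # synthetic cohort
picuree simulate --config spec.yaml --seed 1 --out cohort.csv
picuree equations --in cohort.csv --out predictions.csv # all ten equations
picuree analyze --in cohort.csv --dataset-variant ds1 --gas-mode vco2 \
    --seed 0 --out report.json                          # full experiment
picuree evaluate --in predictions.csv --true-col measured_ree --pred-col schofield_w
```

Exit codes: 0 ok, 2 configuration error, 3 data error.

## Data files

`src/picuree/data/` holds the versioned equation registry
(`equation_registry.csv`, `talbot_tables.csv`, `equation_constants.yaml`,
each row/entry with its citation) and the synthetic LMS growth fixture
(`growth_reference.csv`). Real growth-reference tables can be dropped in
with the same schema (`metric, sex, grid_value, L, M, S`).
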