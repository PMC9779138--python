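# airseg

Sub-range segmented neural regression for filling gaps in hourly
air-monitoring series.

Automatic monitoring stations record 1-hour averages of pollutant
concentrations (O3, NO, NO2, SO2, CO, PM10) and meteorology (wind speed,
temperature, solar radiation, relative humidity), but the records are never
complete.  Missing concentrations can be approximated by regressing each
pollutant on the co-measured variables.  `airseg` implements a segmented
variant of this idea: instead of a single perceptron over the whole
concentration range, the case set is sorted, cut into k equal-count
sub-ranges, and a dedicated sub-model is trained per sub-range.

Two segmentation schemes are provided:

- **RVS** (real-values sorting) — cases are sorted by the *true* target
  concentration.  An oracle scheme: it cannot route unseen cases, but it
  quantifies the potential accuracy gain of segmentation.
- **PVS** (predicted-values sorting) — a full-range stage-1 model is trained
  first; its predictions define the sort order, the sub-range boundaries and
  the routing rule for unseen cases.

Each model is a fixed-architecture multilayer perceptron (10 logistic hidden
units, 1 logistic output) trained by BFGS on the sum-of-squares loss, capped
at 300 iterations, from Gaussian initial weights, with best-of-5 restart
selection by validation error.  Evaluation reports per-sub-range and overall
MAE/RMSE (the overall value is the equal-weight mean over sub-ranges) plus
percentage changes against the full-range model.  A synthetic generator
produces station-like hourly series (seasonal/diurnal cycles, right-skewed
concentrations, O3–NO anticorrelation, winter PM10–SO2 coupling, realistic
missingness) so the whole pipeline is testable without proprietary
monitoring data.

## Test

```sh
python -m pytest -q
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py`, which checks the calendar/aggregation/partition
identities and the qualitative segmentation properties (RVS error decreasing
in k, RVS at least as accurate as PVS, PVS misclassification growing with k)
on synthetic data at n = 5,000 across 3 seeds.

## CLI

```sh
# synthetic hourly record (urban-like preset, 2 years)
airseg simulate --preset zabrze --years 2 --seed 1 --out sim.csv

# complete-case modeling table for one target
airseg prepare --input sim.csv --target O3 --out table.csv

# fit a segmented model and evaluate it
airseg fit --input table.csv --target O3 --mode pvs --k 4 --seed 1 --out model.json
airseg evaluate --model model.json --input table.csv --out-prefix report

# or run the whole grid (full / rvs / pvs at k = 1, 2, 4, 8) in one go
airseg run --target O3 --preset zabrze --years 2 --seed 1 --out results/
```

`airseg run` writes one report per (mode, k) cell, a percentage-change
comparison table, and a `manifest.json` (config hash + seed fan-out) that
makes every cell exactly reproducible.

## Package layout

- `airseg.data_prep` — CSV ingestion, hourly-grid validation, time encoding
  (linear or cyclic-cosine D/H), complete-case filtering, 70/15/15 splits
- `airseg.mlp` — the perceptron core: scaling, BFGS training, restarts,
  prediction, JSON serialization
- `airseg.segmentation` — sort-and-partition, RVS/PVS/full ensembles,
  boundary routing
- `airseg.evaluation` — MAE/RMSE, overall aggregation, percentage changes,
  report writers
- `airseg.synthetic` — station-like series generator with presets
- `airseg.workbench` / `airseg.cli` — experiment orchestration and the
  `airseg` command
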