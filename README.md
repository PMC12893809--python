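# urbanrange

Analysis toolkit for urban raptor ecology, in two halves:

1. **Juvenile movement** — ingest and quality-filter GPS telemetry, detect
   natal-dispersal onset by a distance-threshold rule, fit continuous-time
   movement models (IID / OU / velocity-correlated OUF) by exact maximum
   likelihood, estimate 50% core foraging ranges with an
   autocorrelation-aware weighted kernel density estimator, extract temporal
   foraging areas (density clusters → 95% minimum convex polygons with
   qualification rules), and relate their occupancy span and area to human
   population density with random-intercept GLMMs tested by parametric
   bootstrap likelihood-ratio tests.
2. **Breeding habitat suitability** — build a multi-scale raster predictor
   stack (50 m rescaling, focal means at 50/200/1000 m, Pearson
   collinearity screening), fit a from-scratch presence/background
   maximum-entropy model (linear/quadratic/product/hinge features,
   L1-penalized Gibbs likelihood, regularization multipliers 1–5,
   10-fold cross-validation on AUC/TSS), binarize at the
   max-sensitivity-plus-specificity threshold, and account suitable area
   overall, per habitat class, and outside 1000 m buffers around occupied
   nests.

A `synthetic` module generates movement tracks (exact OU/OUF transition
sampling on irregular daytime schedules with winter gaps), autocorrelated
landscapes with six habitat classes and water, breeding sites with a known
suitability surface, and GLMM tables — so the entire pipeline is testable
without any proprietary data.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes per-module unit tests, property/invariant tests, and
`tests/test_acceptance.py` with one test per acceptance criterion
(simulation-recovery checks, oracle equivalences, and a 200×199
parametric-bootstrap type-I-error calibration — the calibration takes
several minutes).

## CLI

```bash
# generate synthetic inputs
urbanrange simulate track --seed 3 --n-days 120 --onset-day 30 --out sim_track
urbanrange simulate landscape --seed 3 --out sim_landscape
urbanrange simulate tfa --seed 3 --family poisson --out tfa_table.csv

# run pipeline stages from a YAML config (see urbanrange.pipeline.RunConfig
# for every key and its default)
urbanrange run --config config.yaml --stages simulate,qc,dispersal,ranges,tfa,glmm
urbanrange run --config config.yaml --stages predictors,sdm
```

Each run writes plain-text artifacts (CSV, GeoJSON, Arc/Info ASCII grids,
JSON) plus a `manifest.json` with SHA-256 content hashes; stochastic stages
derive their seeds deterministically from the global seed.

## Layout

```
src/urbanrange/
  geo.py        local transverse-Mercator projection, GeoJSON helpers
  tracking.py   fix ingestion, QC, solar/daylight filter, clipping
  dispersal.py  dispersal-onset detection and track truncation
  ranges.py     variograms, movement-model ML fits, AKDE, contours
  tfa.py        foraging-area clustering, 95% MCP, qualification
  glmm.py       mixed models (exact LMM ML, AGQ Poisson), bootstrap LRT
  habitat.py    raster type + ASCII-grid I/O, rescaling, focal means,
                collinearity filter
  maxent.py     background sampling, feature basis, penalized fitting,
                CV, thresholds, area accounting
  synthetic.py  ground-truth generators
  pipeline.py   stage orchestration and manifests
  cli.py        click entry points
```
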