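# coastrange

Coastal range-edge hindcasting for an annual coastal species on a 1-D chain
of coastal cells. The pipeline couples:

1. **Synthetic coastal data** — a seeded virtual coastline, daily
   SST/wave/wind fields (seasonal cycle, latitudinal gradient, warming trend,
   AR(1) anomalies, heat-wave pulses, upwelling zones), a known-truth
   occupancy history and survey sampling (`coastrange.grid`,
   `coastrange.environment`, `coastrange.synthetic`).
2. **Seasonal extreme-event predictors** — longest runs of days above
   thresholds, seasonal maxima, and a wind-stress/Ekman-transport coastal
   upwelling index (CUI), on seasons that may straddle the calendar year
   (`coastrange.predictors`).
3. **Pseudo-absence generation** — a Mahalanobis/chi-square habitat
   suitability surface plus K-means stratified draws from environmentally
   dissimilar cells (`coastrange.pseudo_absence`).
4. **Monotone boosted-tree niche models** — all weakly correlated predictor
   subsets, hyperparameters tuned by k-fold deviance CV, temporal (train one
   year / test another) transferability scored by the Minimum Predicted Area
   (MPA) criterion at sensitivity ≥ 0.9, ensembling of the most transferable
   models, and per-predictor contribution scores
   (`coastrange.niche_model`).
5. **Occupancy reconstruction** — a dispersal-distance (D) / latency-period
   (L) automaton over binarized suitability, with a (D, L) grid search
   maximizing marginal TSS over occurrence records
   (`coastrange.reconstruction`).
6. **Evaluation** — confusion statistics, TSS, per-year accuracy, occupied
   area through time, and persistence/extinction/recolonization fate maps
   (`coastrange.evaluation`).

All daily series live on a fixed 365-day (no-leap) calendar so seasons are
structurally identical across years.

## CLI

```bash
coastrange simulate --n-cells 100 --years 1986 2014 --seed 1 --out env.nc
coastrange predictors --env env.nc --out stack.csv
coastrange model --stack stack.csv --records records.csv \
    --train-years 2010 2012 --out probs.csv
coastrange reconstruct --suitability suit.csv --records records.csv \
    --d-max 500 --out run
coastrange evaluate --occupancy run_occupancy.csv --records records.csv --out eval
coastrange run-all --config config.yaml --seed 1 --outdir out/
```

`run-all` chains every stage from one YAML config (see
`tests/test_cli.py::test_run_all_end_to_end` for a complete example config).

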