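# vrstress

Predict stress-evoked cardiac vagal withdrawal from high-dimensional
locomotor behavior recorded during exploration of virtual scenes.

Subjects explore three 90-second virtual scenarios — an empty room, an
elevated alley of successively narrower patches, and a dark threat maze —
while head tracking (~90 Hz), lower-body motion capture (~60 Hz), ECG
(500 Hz) and respiration (100 Hz) are recorded. The pipeline:

1. **`vrstress.synth`** — synthetic-cohort generator. A latent standard-normal
   vulnerability trait drives both exploratory behavior (thigmotaxis, center
   avoidance, gait variability, head scanning) and, scaled by a configurable
   coupling, dark-maze cardiac physiology. Every generator returns its
   ground truth (beat times, NN intervals, heel strikes, scan counts) so all
   downstream stages are testable without real data.
2. **`vrstress.cardio`** — FIR decimation, Pan–Tompkins R-peak detection,
   3-SD artifact cleaning with linear interpolation, time-domain HRV
   (RMSSD, SDNN, triangular index with 1/128 s bins), heart rate, and
   respiration rate from bandpassed (0.17–0.73 Hz) peak counting.
3. **`vrstress.ihrv`** — the integrated HRV index: PCA on z-scored
   {HR, RMSSD, SDNN, HRVTi, RR}; the selected component must load ≥ +0.3 on
   all three HRV metrics, ≤ −0.3 on HR, and ≤ 0.2 in magnitude on
   respiration rate (a vagal axis uncontaminated by breathing).
4. **`vrstress.behavior`** — ~65 locomotor features in three families
   (position, gait, movement burst) across the two exploration scenes:
   corner/wall distances, center/periphery occupancy, alley patch dwell and
   crossing latencies, movement focus and concentric-path fraction, head
   scans while walking, heel-strike/stride detection, burst/immobility
   segmentation.
5. **`vrstress.selection`** — zero-variance removal → |Spearman| ≥ 0.1
   screen against the index → per-family cross-validated Lasso; the final
   set is the union of the per-family supports.
6. **`vrstress.model`** — gradient-boosted regression trees (scikit-learn
   engine) with a seeded tree-structured-Parzen-estimator search over
   eta/max_depth/min_child_weight/nrounds, anxiety-stratified or even
   train/test splitting, correlation-based evaluation, and an exact
   path-dependent TreeSHAP implementation (validated in-tree against a
   brute-force Shapley oracle).

## CLI

```bash
vrstress run-all --seed 1 --n 60 --trials 20 --out run/      # full pipeline
vrstress simulate --n 10 --seed 1 --out cohort/              # write sessions
vrstress cardio --session cohort/S0000/dark_maze --out c.json
vrstress features --sessions cohort/ --out features.csv
vrstress ihrv --cardio-csv cardio.csv --model-out m.json --scores-out s.csv
vrstress select --features-csv features.csv --scores-csv s.csv --out sel.json
vrstress evaluate --predictions-csv preds.csv --out eval.json
```

`run-all` writes a complete artifact set (manifest with config hash,
cardio summaries, iHRV model and scores, tagged feature table, selection
report, tuned parameters, SHAP values, evaluation JSON); identical
config + seeds reproduce identical artifacts. All thresholds live in
`vrstress.config.RunConfig` and can be provided as a YAML file via
`--config`.

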