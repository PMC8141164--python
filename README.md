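# restmotion

Resting-hand IMU tremor analysis pipeline for discriminating PD-like from
healthy-like subjects. It covers the full chain:

1. **synthetic** — simulate cohorts of two-IMU recordings (hand + forearm;
   accelerometer, gyroscope, magnetometer; triaxial; 50 Hz × 15 s × 3
   trials). PD-like subjects carry an amplitude-modulated 3.5–7.5 Hz
   oscillation over Gaussian noise (sub-noise-floor for HY = 1 subjects,
   clearly visible for HY = 2); healthy-like subjects carry noise only.
2. **preprocessing** — per-axis zero-phase Butterworth band-pass (1–16 Hz),
   per-sample resultant `sqrt(x² + y² + z²)`, mean subtraction.
3. **features** — 18 features per sensor resultant (RMS, peak, MAV, MAV of
   first/second differences, mean/peak/median/80th-percentile frequency,
   zero crossings, 3.5–7.5 Hz band power, approximate entropy, fuzzy
   entropy, variance, range, IQR, skewness, kurtosis), i.e. 108 per
   subject; per-trial vectors are averaged per subject.
4. **selection** — Z-score normalization and ReliefF ranking (k = 1,
   deterministic pass over all instances), with nested 10%…100% subsets
   (round-half-up: 10 % of 108 → 11 features).
5. **classification** — KNN (k = 3), polynomial-kernel SVM, random forest
   (120 trees) and Gaussian naive Bayes behind one train/predict contract.
6. **evaluation** — stratified ~50/50 subject split (27 → 14/13), tenfold
   cross-validated training accuracy, held-out confusion matrix and
   sensitivity / specificity / precision / accuracy (PD positive), per
   classifier × feature percentage.

## CLI

```sh
restmotion simulate --out cohort/ --seed 7         # recordings as CSV
restmotion preprocess cohort/pd01_trial1.csv --out resultants.csv
restmotion extract cohort/ --out features.csv      # 108-column table
restmotion select features.csv --pct 20 --out selected.csv
restmotion classify features.csv --model svm --pct 20 --seed 7 --out preds.csv
restmotion run-all --config experiment.yaml --out report/ --seed 7
```

`run-all` writes `features.csv`, `report.csv` (classifier × percentage
metrics), `ranking.csv`, `splits.json` and `config.yaml`, each stamped with
the master seed and a config hash; reruns with the same config are
byte-identical. All stage seeds derive from the one master seed.

The YAML config mirrors `restmotion.ExperimentConfig`
(`cohort:`, `entropy:`, `band:`, `classifiers:`, `percentages:`, `folds:`,
`train_fraction:`, `seed:`, …); unknown keys are rejected. Dump a template
with `python -c "import restmotion; restmotion.ExperimentConfig().to_yaml('experiment.yaml')"`.

## Recording text format

UTF-8 CSV per trial: a metadata comment line
`# rate_hz=50 subject=pd01 trial=1 group=PD hy=1`, a header
`time,acc1_x,…,mag2_z` (19 columns), then one row per sample.

## Library use

```python
import restmotion as rm

cohort = rm.generate_cohort(rm.CohortConfig(seed=7))
table = rm.build_feature_table(cohort)                 # 27 x (3 + 108)
report = rm.evaluate_feature_table(
    table, [rm.ClassifierSpec(k, seed=7) for k in ("KNN", "SVM", "RF", "NB")]
)
print(report.table)                                    # 40 metric rows
```
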