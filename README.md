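# settledown

Analysis pipeline for the pre-sleep **settling-down period** in pediatric
wrist actigraphy: the window each night between the end of the bedtime
routine (caregiver diary) and algorithmic sleep onset. The package asks
whether children with caregiver-endorsed tactile **sensory sensitivities
(SS)** move differently during that window than non-sensitive peers
(**NSS**), and which movement features carry the difference.

## What it does

1. **Ingest** epoch-level activity exports (60-s vector-magnitude counts),
   caregiver sleep diaries and group labels — or **simulate** a two-group
   cohort with a seeded generator calibrated to published group statistics.
2. **Score** each epoch sleep/wake with the Sadeh pediatric discriminant

   `PS = 7.601 − 0.065·MW − 1.08·NAT − 0.056·SD6 − 0.703·LG`

   (MW: mean counts in the centred 11-epoch window; NAT: epochs in that
   window with counts in [50, 100); SD6: sample SD of the trailing 6
   epochs; LG: ln(counts + 1); sleep ⇔ PS ≥ 0), delimit nightly rest
   periods with Tudor-Locke-style consecutive-epoch rules, reconcile them
   against the diary under a 30-minute rule, and place sleep onset at the
   first sustained sleep run.
3. **Extract** the settling window [diary settling start, sleep onset) per
   night; children need ≥ 4 valid nights. Duration contrasts are
   summarized with Hedges' g.
4. **Featurize** rolling windows (default 11 min, 1-min stride) into seven
   features: mean magnitude, maximum magnitude, kurtosis, skewness,
   Shannon entropy (bits, over the empirical distribution of count
   values), SD, IQR.
5. **Classify** windows SS vs NSS with random forests (vote-fraction
   scores), stratified 10-fold cross-validation, and a decision threshold
   chosen by Youden's J (= TPR − FPR) on each fold's training scores;
   sweep window/stride over {7, 9, 11, 13} × {1, 3}.
6. **Explain**: permutation feature importance by held-out AUC decrease
   (refit per shuffle), per-child aggregates, Mann-Whitney group tests,
   and standardized OLS regressions of mean settling duration on each
   aggregate (controlling age and sex).

Two cross-validation modes are provided: `paper` (window-level
stratification balanced over subjects — a subject's windows can appear in
both train and test, which is optimistic) and `grouped` (whole subjects
held out, leakage-safe). See `docs/methods.md`.

## Worked example

```bash
settledown simulate --seed 7 -o data/           # synthetic cohort (17 SS / 18 NSS)
settledown extract  -i data/                    # settling windows per night
settledown featurize -i data/ --window 11 --stride 1
settledown classify -i data/ --window 11 --stride 1 --folds 10 --seed 7
```

The `classify` step prints the per-fold table and, on the seed-7 cohort
(12,956 windows from 393 settling periods):

```
average: accuracy=0.858  sensitivity=0.918  specificity=0.735  auc=0.928
```

i.e. about 86% of held-out windows are assigned to the correct group, with
sensitivity (SS is the positive class) 92% and AUC 0.93 under window-level
(`paper`-mode) folds. With `--fold-mode grouped` — no subject shared
between train and test — the same data give `auc=0.687`, the honest
generalization estimate; the gap is the within-subject leakage the
window-level scheme permits.

The same run end-to-end, including the sweep, importance, group tests and
regressions, from a YAML config:

```python
from settledown import CohortConfig, PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(
    synthetic=CohortConfig(nights_range=(13, 13), seed=7),
    out_dir="run_out",
))
print(report.to_markdown())
```

Artifacts (`features.csv`, `cv_report.csv`, `importance.csv`,
`subject_aggregates.csv`, `group_tests.csv`, `regressions.csv`,
`report.md`, `manifest.json`) land in `out_dir`, each CSV carrying a
`# config=<hash> seed=<n>` provenance line.

The same run is available from the shell via a YAML config
(`settledown report --config cfg.yaml`):

```yaml
synthetic:                 # or: data_dir: path/to/csvs
  n_ss: 17
  n_nss: 18
  nights_range: [13, 13]
  seed: 7
sleep_scoring: {onset_run: 5, offset_run: 10, min_rest_minutes: 160}
window: {window_min: 11, stride_min: 1}
rf: {n_trees: 100, seed: 7}
k_folds: 10
fold_mode: paper           # or grouped (subject-held-out)
run_sweep: false
seed: 7
out_dir: run_out
```

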