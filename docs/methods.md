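# Methods

## The analysis

The pipeline quantifies how children with tactile sensory sensitivities
(SS) differ from non-sensitive peers (NSS) during the nightly
settling-down period — the interval between the caregiver-reported end of
the bedtime routine and algorithmic sleep onset — using wrist actigraphy
summarized as vector-magnitude activity counts per 60-s epoch.

Stages: per-epoch Sadeh sleep/wake scoring → Tudor-Locke-style rest-period
delimitation → diary reconciliation → sleep onset → settling-window
extraction → rolling-window features → random-forest classification with
Youden-J thresholding → permutation importance, subject aggregates,
Mann-Whitney group tests and standardized post-hoc regressions.

## Sleep scoring

The Sadeh discriminant `PS = 7.601 − 0.065·MW − 1.08·NAT − 0.056·SD6 −
0.703·LG` scores an epoch sleep iff PS ≥ 0. Numerical conventions pinned
here (the literature leaves them open):

* the series is zero-padded by 5 epochs per side so PS is defined at the
  boundaries;
* SD6 is the sample (n−1) standard deviation of the current and 5
  preceding epochs;
* NAT counts epochs with counts in the half-open band [50, 100).

Rest periods open at the first epoch of a run of ≥ `onset_run` (default 5)
sleep-scored epochs and close at the first epoch of a subsequent run of
≥ `offset_run` (default 10) wake epochs (or the series end); periods
shorter than `min_rest_minutes` (default 160) are discarded. The same
Sadeh labels feed both stages (single scorer). When several rest periods
fall in one night, the longest is kept (tie → earliest) — a deterministic
replacement for manual visual inspection. Defaults follow the cited
consecutive-epoch conventions and are all configurable.

Diary reconciliation: the caregiver-reported sleep onset replaces the
algorithmic rest-period start only when the two differ by **strictly less
than 30 minutes**; at 30+ minutes the algorithm is trusted (caregivers may
not witness actual sleep onset). The rule is applied to the period end as
well when a morning wake report is supplied; the diary dialect shipped
here carries no wake report, so in the file-based pipeline only the onset
side is active.

Sleep onset is the first epoch in the rest period opening a run of ≥ 3
sleep-scored epochs; a night without such a run is invalid and excluded
(logged).

On synthetic nights the recovered onset is systematically ≈ 5 minutes
late: the centred 11-epoch Sadeh window still contains settling-period
activity just after the true onset. This is a property of centred-window
scoring itself, and the recovered-minus-true error it induces is shared by
any real deployment of the algorithm.

## Settling extraction and durations

Diary mode cuts [diary settling start, sleep onset); a fixed-offset mode
cuts [onset − 60 min, onset) for nights without usable diaries. Nights are
rejected (with reason codes) when the diary is missing, the onset precedes
the start, or the window is shorter than 3 minutes (variance features need
≥ 3 epochs). Children with fewer than 4 valid nights are excluded.

Group duration summaries are reported in two framings — per-subject (mean
over each child's nights, then mean/SD over children) and pooled over
nights — because published group tables are often ambiguous between them.
Hedges' g uses the pooled SD and the small-sample correction
`J = 1 − 3/(4·(n1+n2−2) − 1)`. For the published group inputs (52.63 ±
38.31, n=17 vs 26.19 ± 14.20, n=18) this formula gives g ≈ 0.90; source
tables sometimes print 0.95 for these inputs, which this formula cannot
reproduce — the package documents its convention rather than forcing
agreement.

## Window features

Rolling windows of `window_min` minutes advanced by `stride_min` (defaults
11/1; count = ⌊(L−W)/S⌋ + 1). Periods shorter than the window yield no
windows (skipped, not truncated) so all windows share one length and the
entropy bound log2 W is comparable. Feature conventions, pinned:

* skewness m₃/m₂^{3/2} and excess kurtosis m₄/m₂² − 3 from biased central
  sample moments; both defined 0 for constant windows;
* SD with n−1; IQR from linear-interpolation (type-7) quantiles;
* Shannon entropy in bits over the empirical distribution of the exact
  count values in the window — 0 for a constant window, log2 W when all W
  values are distinct. This definition is consistent with published
  per-window entropies approaching log2 11 ≈ 3.459 at the 11-minute
  window length.

## Classification

Windows are classified SS (positive) vs NSS by a random forest whose
score is the fraction of trees voting SS. The decision threshold is not
0.5 but the Youden-J (TPR − FPR) maximizer over the **training** fold's
scores — candidates are midpoints between adjacent distinct scores plus
±∞, ties resolve to the lowest threshold. Stratified 10-fold CV reports
per-fold and averaged accuracy, sensitivity, specificity and AUC.
Hyperparameters (trees × depth, default grid {100, 200, 500} × {3, 5, 10,
unlimited}) can be grid-searched by inner CV on a stratified 4:1 split;
the selected set is then frozen across folds. The window/stride sweep
rebuilds the feature table and reruns CV for each cell of
{7, 9, 11, 13} × {1, 3}.

Two fold modes:

* **paper** (default): each subject's windows are dealt round-robin across
  folds, so every fold sees every subject and label ratios track the
  global ratio. With a 1-minute stride, adjacent windows share 10 of 11
  epochs, so train and test folds contain near-duplicate rows; this
  window-level scheme is therefore structurally optimistic — a null cohort
  with no group difference still scores AUC ≈ 0.9. It is retained as the
  default because it reproduces the published analysis design, with the
  bias stated.
* **grouped**: stratified group k-fold holding out whole subjects — the
  honest generalization estimate, and the mode in which the null
  calibration is meaningful (null AUC ≈ 0.5; calibrated cohort ≈ 0.73).

## Importance and statistics

Permutation importance follows the refit-from-scratch protocol: on a
stratified 4:1 split, each feature column is shuffled across all rows (10
repeats by default), the forest is refit on the shuffled training rows,
and importance is the baseline-minus-shuffled held-out AUC. With seven
partially redundant features the absolute decreases are small; the
*ranking* is the informative output.

Per-child aggregates: mean window magnitude, mean over nights of the
per-night maximum window magnitude, median window entropy, and mean/SD of
nightly durations. Group contrasts use the Mann-Whitney U (pairs with
x > y plus half-ties) with a signed z from the tie-corrected normal
approximation, no continuity correction; both U and z are reported
explicitly because group tables in this literature sometimes print the z
under a "U" heading. Post-hoc models are OLS of mean settling duration on
the group indicator plus one aggregate, controlling age and sex (F=0);
standardized betas are b·sd(x)/sd(y) with n−1 SDs; no multiple-testing
correction is applied.

## Synthetic cohort generator

The generator emulates the study conditions: 17 SS / 18 NSS children aged
6–10, ~2 weeks of continuous wear (10–14 nights; the reference
configuration fixes 13), 60-s epochs, a caregiver diary with Gaussian
reporting noise (SD 5 min, rounded to the minute) and 10% missing nights.
Each day has three regimes: daytime activity (gamma, mean 1500
counts/min), the settling window, and sleep (exponential, mean 10
counts/min — low enough that Sadeh scores sleep, as it must).

**Settling durations** are log-normal (positive, right-skewed; the SS
group's SD ≈ its mean rules out a normal), with half the log-variance
between children and half between nights. **Settling epochs** follow a
burst mixture: an epoch is motionless (count 0) with probability
`still_prob`, otherwise draws an exponential baseline, and independently
with probability `burst_prob` adds a movement burst of exponential scale
`burst_scale_counts`. The baseline mean is solved so the analytic epoch
mean equals the configured target exactly.

Defaults are calibrated to the published group statistics: durations
52.63 ± 38.31 (SS) and 26.19 ± 14.20 (NSS) minutes; epoch means 2481.27
and 1964.06 counts/min. The burst shape parameters are the generator's
free choices and were fixed once, by a screen over candidate
parameterizations, to reproduce the published *qualitative* structure of
the group difference: equal stillness (0.10) and near-equal baselines
(≈ 896 counts/min) in both groups, with the contrast carried entirely by
burst structure — SS bursts rare and large (p = 0.25, scale 6700), NSS
frequent and moderate (p = 0.40, scale 2890). Under this design the
window-level CV AUC is ≈ 0.93 and maximum magnitude is the top-ranked
permutation feature ahead of SD and IQR, matching the reported findings;
designs with unequal baselines instead make the window *mean* the
dominant unique signal.

**Small-cohort conditioning.** Child-level random effects (duration
factors, and activity-level factors with cv 0.10) are renormalized so the
cohort-weighted group mean equals the configured target exactly — the
generator conditions on the group means it is calibrated to, so that a
35-child cohort reproduces them to within night- and epoch-level noise.
The renormalization couples the children of a cohort; for studying the
sampling behaviour of between-group tests (e.g. type-I error of the
Mann-Whitney on per-child aggregates), `draw_settling_durations(...,
renormalize=False)` yields fully independent children, under which the
test's measured size is nominal (≈ 5%).

**What the generator does not emulate**, and hence what passing tests do
not show about real data:

* No circadian structure beyond the three-regime day; no naps, no
  off-wrist time by default (an optional flag inserts zero-count gaps).
* The published per-subject *median entropy* contrast (3.43 vs 2.67 bits)
  is not reproduced — both synthetic groups sit near the entropy ceiling.
  Reproducing it would require strong between-child stillness
  heterogeneity, which under the window-level CV scheme would let the
  forest classify even a null cohort above chance, destroying the null
  calibration; the entropy contrast was sacrificed.
* The per-night maximum magnitude overshoots the published subject-level
  values (≈ 20k vs ≈ 10.7k counts for SS): matching the window-level
  discriminative structure with exponential burst tails inflates
  night-level extremes.
* Between-child variance of the aggregates is smaller than published
  (activity-level cv 0.10), a deliberate choice for the same
  null-calibration reason.

## Problem sizes and numerical choices

The reference configuration (35 children × 13 nights, 11/1 windows,
~13k windows, 100-tree forests) runs each full stage in seconds to a few
minutes on one CPU; the test suite's stochastic checks use 3–5 seeds and
3–5 permutation repeats at that scale. Forest randomness derives from a
single pipeline seed via documented sub-seeding (fold index / repeat
index offsets), so every reported number is reproducible from the config
hash + seed recorded in each artifact.

Degenerate inputs are handled explicitly: constant windows have
skew/kurt/entropy 0; a variable constant across both groups yields NaN in
the group-test table; a singular regression design yields an all-NaN
model column; a night without a sustained sleep run is excluded with a
reason code.

## Known limitations

* The paper-mode CV estimate is optimistic by construction (near-duplicate
  overlapping windows across folds); grouped mode is the honest figure.
  Both are reported.
* Sadeh onset carries a ≈ +5 min bias on bursty-to-quiet transitions.
* The generator's burst mixture is an assumption about within-night
  dynamics; published sources specify only period-level summaries.
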