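# Methods

## Signal model

A recorded tapping trial is modelled as a 1-D amplitude series: the
Euclidean distance between the thumb-tip and index-tip landmarks
(tracker indices 4 and 8) over all three coordinates, including the
relative-depth z. No aspect-ratio correction is applied to the
normalized image coordinates; distance extraction is symmetric in the
two points and invariant to rigid translation of the hand. Each hand's
series is max-normalized (`100·x/max`), so 100 marks that hand's widest
opening; all features live on this percent scale.

Taps are local maxima with topographic prominence ≥ 0.3 **on the
unit-normalized (0–1) signal** — equivalently 30 percent-points. The
threshold is deliberately applied on the unit scale: a prominence of 0.3
on a 0–100 signal would accept frame-level noise as taps. Detection is
`scipy.signal.find_peaks` with the prominence criterion; plateau maxima
are reported at their leftmost sample (deterministic tie-break), and
valleys are the leftmost minima between consecutive accepted peaks. The
implementation is verified in the test suite against an exhaustive
O(n²) prominence enumeration, exactly, including ties. No smoothing is
applied before detection (an optional moving average can be added by the
caller; default off). Frames with missing tip landmarks fail the core
pipeline by default (`missing="fail"`); a drop policy exists for
adapter use.

## Synthetic tapping generator

The generator inverts the measurement chain: commanded kinematics in,
signals out, so every downstream stage can be validated against ground
truth.

* **Waveform.** Raised-cosine open–close cycles between a valley at 2%
  of full stretch and the commanded peak; smooth and band-limited at
  30 fps, with the peak frame rescaled to carry exactly the commanded
  amplitude. The series opens at the full-stretch posture (frame 0 at
  exactly 100%) and descends monotonically into the first valley. A
  boundary sample can never be a topographic peak, so the posture
  anchors max-normalization — commanded percent amplitudes survive the
  normalization — without being counted as a tap. A short (~2 frame)
  valley tail is reserved at the end of the window so the last cycle's
  descent completes and its peak keeps full prominence.
* **Commanded peaks.** For tap i of T: `amp_mean + d·((T+1)/2 − i) + ε`,
  with `ε ~ N(0, amp_sd²)` and d the per-tap decrement, so the mean over
  taps equals `amp_mean` and the expected first-minus-tenth difference
  is exactly 9d. Peaks are clipped to [valley+2, 100] — a hand cannot
  exceed its recorded full stretch — which introduces a small (<0.5
  percent-point) truncation bias at patient-level amplitude noise.
* **Timing.** The window (10 s × 30 fps = 300 frames) minus lead-in and
  tail is divided into T cycles with normally jittered durations
  (CV `timing_jitter_cv`, default 0.08), largest-remainder rounding, and
  a 3-frame minimum per cycle; parameters that cannot fit raise an
  infeasible-parameters error. Optional halts (probability `halt_prob`
  per inter-tap interval, default 0) insert 0.3–1.0 s pauses at valley
  level.
* **Noise.** Additive frame-level Gaussian noise (`noise_sd_pct`,
  preset default 1%).
* **Seeding.** One global seed fans out through a `SeedSequence` into
  independent per-subject streams; cohorts are bit-identical across
  runs.

### Group presets

The `clinical` preset pair encodes group-level summary statistics
typical of video-based tapping studies of PD patients and healthy
controls: per-hand tap-count mean (SD) of 24.6 (7.3) right / 24.6 (7.2)
left for controls versus 17.9 (7.8) / 17.9 (5.6) for patients; amplitude
means 85.4 (6.9) / 83.2 (8.0) versus 71.4 (16.0) / 75.3 (10.7);
amplitude-SD (TV) 7.9 (3.9) / 8.0 (4.0) versus 14.4 (10.0) / 13.1
(8.2); first-to-tenth decrements 2.6 (15.6) / 0.4 (11.3) versus 20.5
(28.5) / 17.6 (24.6); and inter-hand tap-count gaps of 0.4 versus 2.8.
Sampling choices where only a mean (SD) is published:

* Tap counts: normal draw, rounded, clipped to ≥ 5. The left count is
  the right count offset by the drawn asymmetry with a random sign, so
  both hands share the group mean (as the published means do).
* Asymmetry: half-normal scaled to the group mean, rounded — a
  non-negative integer, mostly 0/1 for controls.
* Per-tap decrement: the group first-to-tenth decrement draw divided
  by 9.
* Amplitude noise: the published TV includes the variance contributed by
  the decrement trend, so the commanded residual noise is
  `sqrt(max(TV² − d²(T²−1)/12, 0.25))`; the *extracted* TV then matches
  the published statistic rather than overshooting it.

What the generator does **not** emulate: tremor-frequency content,
camera motion and perspective, occlusion or tracking dropout,
within-trial fatigue beyond the linear decrement, and correlations
between features beyond those induced by the trend/asymmetry model.
Passing tests therefore demonstrate that the pipeline recovers commanded
kinematics and separates groups under these idealized conditions — not
that the classifier metrics transfer to real video. One consequence of
the idealization is visible and realistic: severely decremented noisy
hands can drop taps below the prominence threshold, so extracted patient
tap counts run slightly below the commanded mean.

## Features

TS = peak count; TA = mean peak amplitude; TV = SD (n−1 denominator);
AmpD-k = first minus kth peak amplitude for k = 5, 7, 10 (all three
decrements are computed and fed to the classifier); TD = absolute
inter-hand tap-count difference (absolute, because published control
means are small but positive, inconsistent with a signed mean near
zero). The earliest detected peak is tap 1; no warm-up peak is
discarded. With fewer than k peaks, AmpD-k saturates to the last peak so
vectors stay complete; hands with < 2 peaks get TV = AmpD = 0 plus a
quality flag, and subjects with a flagged hand are excluded from the
feature table with a logged warning. The flattened 13-feature order is
fixed in `FEATURE_COLUMNS` as a versioned I/O contract.

## Classification protocol

Stratified 5-fold outer CV estimates performance; within each outer
training set a stratified 3-fold grid search selects hyperparameters by
mean inner accuracy, the winner is refit on the full outer-train set and
scored on the held-out fold. The inner splits are materialized
explicitly from the outer-train subset, and an audit hook exposes every
index set, so the no-leakage property is asserted, not assumed. A
degenerate inner split (single-class training part) is re-drawn once
with a shifted seed before failing. Grids are small, standard desk-scale
defaults (see `DEFAULT_GRIDS`); scale-sensitive families (LR, SVM, KNN)
are standardized by a scaler fit on the outer-train fold only. The
positive class is bradykinesia; AUC uses the model's native score
(probability where available, margin distance for the SVM) with midrank
tie handling. `train_auc` on the outer-train set probes overfitting.
Metric summaries are `mean ± sd` with 95% CIs from
`mean ± t(0.975, n−1)·sd/√n`; AUC is the mean across outer folds (not a
pooled-prediction AUC), matching the per-fold ± sd reporting convention.
One master seed fans out to split, model and Shapley seeds.

Feature influence is the mean absolute Shapley attribution of the
decision score, estimated by permutation sampling (default 30
permutations × ≤ 40 training instances per fold, background = the
outer-train set), averaged over folds. The estimator is validated in the
tests against the closed-form Shapley values of a linear score and the
symmetry property for duplicated features.

## Rater agreement

Consensus per video is the modal 0–4 rating; ties break toward the
higher severity (screening favours sensitivity). The binary bradykinesia
label is consensus ≥ 1. Krippendorff's alpha is computed from the
coincidence matrix over all units with ≥ 2 ratings, with the nominal
(0/1) or ordinal (cumulative-margin squared) difference function —
ordinal is the default for 0–4 scores, nominal is appropriate for the
binary flag. The 95% CI is a percentile bootstrap over items (1000
iterations, resampling videos with replacement); replicates with
undefined alpha are skipped and counted, warning above 5%.

## Problem sizes and tolerances

Acceptance-style checks run at desk scale chosen for tight Monte-Carlo
error at interactive runtimes: 300 hands (or 150 subjects) for parameter
recovery, giving standard errors of ~0.4 taps / ~0.9 amplitude points,
with a ±3·SE acceptance band; classification uses the canonical
47-control / 53-patient cohort. Exact contracts (peak detection versus
the brute-force oracle, alpha versus pair enumeration, CI arithmetic)
are tested to machine precision (1e-12) rather than statistically.

## Known limitations

* The prominence threshold's scale convention (unit versus percent) is a
  modelling decision, documented above; both conventions appear in the
  field's descriptions.
* The generator's inter-tap-interval variability and halt statistics are
  free parameters with no published anchor; they default to mild jitter
  and no halts and are recorded per subject in the cohort manifest.
* AUC ~0.97 on the synthetic cohort exceeds what mixed real video data
  yields (~0.91), as expected: preset groups are cleanly parameterized
  and feature noise is independent across subjects.
* The vision stage (palm detection, landmark regression) is out of
  scope; the package starts at landmark time series.
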