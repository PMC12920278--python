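# Methods

`oxipulse` implements an automatic screening pipeline for obstructive sleep
apnea (OSA) from the two signals a fingertip pulse oximeter provides: the
raw photoplethysmogram (PPG) and the oxygen saturation trace (SpO2). The
pipeline detects 60-second segments containing apnea/hypopnea events,
aggregates segment decisions into an estimated apnea–hypopnea index (AHI),
and screens subjects for moderate-to-severe OSA (AHI >= 15). This note
documents the model, the synthetic data it is validated on, and the design
decisions taken where the procedure was genuinely open.

## Rationale

SpO2-based screening catches desaturating events but misses hypopneas that
terminate in a cortical arousal without significant desaturation. Arousals
carry a sympathetic surge that (a) transiently constricts peripheral
vessels, dropping the PPG pulse wave amplitude (PWA), and (b) shortens the
pulse-to-pulse interval (PPI). Features of PWA and PPI therefore carry
information about exactly the events SpO2 misses; the pipeline quantifies
how much they add.

## Signal processing

* **PPG conditioning.** The AC-coupled PPG (working rate 128 Hz; higher
  input rates are polyphase-resampled) is band-passed 0.7–20 Hz with a
  zero-phase 4th-order Butterworth filter. Zero-phase (forward–backward)
  filtering is used so beat times are not shifted; the order is a
  conventional choice.
* **Artifact rejection.** On non-overlapping 60-s windows, samples with
  |x − window mean| > 1.5 × window SD are flagged; beats whose peak or
  trough lands on a flagged sample are excluded from beat statistics. A
  zero-variance window flags nothing (the threshold degenerates).
* **Pulse detection.** Systolic peaks are local maxima at least
  60/180 s apart whose prominence exceeds 0.3 × a rolling 80th-percentile
  prominence (an adaptive threshold that tracks slow amplitude drift). Each
  peak's trough is the preceding minimum within half a maximal pulse
  interval. Beat times are refined to the midpoint of the half-amplitude
  crossings, where the waveform slope is steep, making beat timing robust
  to noise on a rounded systolic peak. PWA = peak − trough; PPI = time
  between successive systolic fiducials.
* **Beat cleaning (NN intervals).** PPIs outside 0.33–2.0 s, or deviating
  more than 30% from the median of the 5 preceding accepted intervals, mark
  the terminating beat invalid. No interpolation is done at this stage;
  "NN" statistics use only intervals whose two bounding beats are valid.
* **Uniform resampling.** Beat-indexed PPI and PWA sequences are cubic-spline
  interpolated onto a 4 Hz grid (standard practice for pulse-rate-variability
  spectra); invalid-beat gaps are bridged by the spline. SpO2 is used at its
  native 16 Hz.

## Segmentation and labeling

Recordings are tiled into non-overlapping 60-s windows (trailing partial
window discarded; half-open [start, start+60)). A window is **positive**
when apnea/hypopnea annotations occupy at least 10 s of it — cumulatively
across events by default, with a single-event mode available since the two
readings differ only for clustered short events. A window carries an
**arousal** tag when any arousal annotation intersects it. Windows with
fewer than 5 valid NN intervals, under half their beats valid, or missing
SpO2 coverage are flagged low-quality and excluded (counts are logged).

## Features (37 per segment)

* **PPI time-domain (13):** Mean_NN, Max_PR, Min_PR (bpm), SDNN, CVNNI,
  SDSD, CVSD, NN50, pNN50, NN20, pNN20, RMSSD, Range_NN.
* **PPI nonlinear (3):** sample, fuzzy and dispersion entropy of the 4 Hz
  PPI series. Parameters (m = 2, r = 0.2 × SD, delay 1, fuzzy exponent 2,
  c = 6 classes, normalized dispersion entropy) are the standard choices in
  the HRV-entropy literature; the matching convention (Chebyshev distance,
  d <= r, common template basis for lengths m and m+1) is fixed in
  `oxipulse.entropy` and enforced against brute-force oracles in the tests.
* **PPI frequency-domain (7):** VLF (0.003–0.04 Hz), LF (0.04–0.15 Hz),
  HF (0.15–0.4 Hz) band powers from a Welch PSD (120-sample sub-windows,
  50% overlap, linear detrend — at least 3 averages per segment), LFnu,
  HFnu, LF/HF, and normalized spectral entropy over 0–2 Hz. On a 60-s
  window the VLF band lies below the spectral resolution; the nominal band
  is integrated through an interpolated PSD and the value is
  resolution-limited by construction.
* **PWA (7):** Max, Min, SD, CV of beat-wise PWA; VLF/LF/HF band powers of
  the 4 Hz PWA series (pulse amplitude variability).
* **SpO2 (7):** Min, Mean, SD, Variance of the 16 Hz trace; sample, fuzzy
  and dispersion entropy of a 1 Hz mean-decimated version (at 16 Hz the
  entropies would mostly measure oversampling redundancy; 60 samples at
  1 Hz satisfy the m = 2 length requirement).

PWA- and PPI-family features are min–max scaled **within each subject**
(constant columns map to 0), so amplitude effects are compared without
fixed thresholds; SpO2 features keep their physical scale. Per-subject
scaling uses only that subject's own segments, so it leaks nothing across
the cross-validation boundary.

## Classifier and cross-validation

Five feature combinations are supported: SpO2, PWA+SpO2, PPI+SpO2,
PWA+PPI, PWA+PPI+SpO2. For each, a support vector machine is evaluated
under **subject-grouped nested 5-fold cross-validation** (all of a
subject's segments stay on one side of every split). Within each training
fold, in order:

1. **RFECV**: recursive feature elimination (one feature per step) ranked
   by random-forest importance, scored by inner 5-fold AUC; the smallest
   subset within one standard error of the best score is kept (parsimony
   rule). Constant columns are dropped first. The forest refit on the
   selection provides the feature-importance report.
2. **Random undersampling** of the majority class to exact balance
   (segments are ~20–35% positive).
3. **SVM tuning**: the 4-cell grid {C: 0.1, 1} × {RBF, polynomial} is
   enumerated exhaustively (a randomized search over 4 cells degenerates to
   enumeration) with another inner 5-fold CV on AUC; features are z-scored
   with training-fit scalers inside the pipeline. Polynomial degree is 3
   and gamma the standard 1/(n_features · var) — unconstrained choices set
   to library defaults.

The whole procedure is deterministic given one seed; per-stage seeds are
derived by stable hashing of stage names, so any stage can be rerun in
isolation. One deliberate reading: undersampling balances the rows the SVM
sees, while the forest inside RFECV sees the unbalanced training fold.

## Evaluation

Per-fold segment metrics (accuracy, sensitivity, specificity, precision,
AUC from the continuous decision score) are aggregated as mean ± SD, with
recall additionally stratified by the arousal tag of positive segments.
Per subject, the estimated AHI is the count of positive-classified
segments divided by total recording hours — recording time, not sleep
time, which is a known source of underestimation — and the screening
decision is estimated AHI >= 15, scored against the reference AHI with a
2×2 confusion matrix, per-subject sensitivity/specificity, and the Pearson
correlation of raw AHI values, optionally within comorbidity strata. A
repeated-measures ANOVA plus Bonferroni-corrected paired t-tests over
per-fold metric vectors compares feature sets.

## Synthetic data generator

No public dataset pairs raw oximeter PPG with event annotations, so the
package ships a generator whose outputs carry ground truth for every
downstream stage:

* **Beats.** Intervals follow 60/pulse-rate modulated by respiratory sinus
  arrhythmia (0.25 Hz, ±3%), a low-frequency baroreflex-like oscillation
  (0.09 Hz, ±2%) and white jitter (SD 1%).
* **Pulse morphology.** Each beat contributes a single-lobe fast-rise/
  slow-decay kernel (time-warped squared sine through a symmetric tanh
  shaper) spanning 92% of the beat interval. The shaper flattens both
  extremes so that clean peaks and troughs stay inside the 1.5 SD artifact
  envelope — with a spikier kernel the artifact rule would discard a large
  fraction of perfectly clean beats, which no real pipeline tolerates.
  Rendered beats get amplitude modulation (±5% slow + 3% noise), additive
  Gaussian noise, and a moving-average baseline subtraction that leaves a
  zero-mean AC waveform.
* **Events.** Exactly `event_rate_per_h × duration_h` apneas/hypopneas are
  scheduled in evenly spaced, jittered slots (so the reference AHI is exact
  rather than Poisson-distributed); durations are 10–30 s (apnea) and
  10–25 s (hypopnea). By default 15% of events are apneas (clinical cohorts
  of this kind are hypopnea-dominant) and 30% of hypopneas are
  arousal-only, i.e. non-desaturating.
* **Arousal response.** Apneas and arousal-only hypopneas always terminate
  in an arousal (annotated 3 s before event end, 10 s long); desaturating
  hypopneas do so half the time. During the arousal window PWA is
  multiplied by (1 − pwa_drop_frac, default 0.4) and PPI by
  (1 − ppi_shortening_frac, default 0.15), recovering exponentially with a
  15 s time constant; beat-to-beat jitter is inflated in proportion to the
  configured PPI response, so short-term variability rises around arousals
  and a zero-effect configuration silences every coupling at once.
* **SpO2.** Baseline 97% with red-noise wander (SD 0.3%, 30 s correlation)
  keeps negative-segment SpO2 features informative but non-degenerate.
  Desaturating events dip by `desat_depth_pct` (default 4 points, scaled
  0.7–1.0× by event duration; hypopneas at 60% of apnea depth): saturation
  starts falling mid-event, reaches its nadir 20 s after the event ends
  (circulation delay) and recovers exponentially (tau 20 s). Values are
  clipped to [50, 100]%.
* **Cohorts** draw per-subject AHI uniformly within severity bins
  (<5 / 5–15 / 15–30 / >30) apportioned by largest-remainder rounding;
  the default mix (12.2 / 24.4 / 35.6 / 27.8%) mirrors a hospital sleep-lab
  case mix, and each subject gets a fair-coin comorbidity flag.

**What the generator does not emulate:** sleep stages and stage-dependent
arousal rates, event clustering, central/mixed apneas, sensor-contact
drift, motion artifacts, and the within-subject PPG-magnitude drift that
makes amplitude features noisier in real recordings. Passing tests
therefore demonstrate that the pipeline recovers planted structure of the
kinds listed above — not that it attains any particular performance on
hospital data.

## Problem sizes and numerical choices

The validation cohort is 12 subjects at 2 h each (≈ 1 440 segments,
~33% positive), chosen as the smallest cohort on which subject-grouped
5-fold CV is meaningful while the full nested procedure stays cheap; the
negative control repeats it with all arousal/desaturation couplings
disabled, where held-out AUC sits at chance. Oracle-label AHI recovery is
checked on 8 h recordings so that segment-discretization error (an event
can straddle a window boundary and yield 0 or 2 positive windows) averages
out; it stays within ±20% per subject. Random forests use 50 trees (100 in
no way changes selections on these problem sizes). Entropy sentinels:
zero-variance series return 0; an undefined SampEn (no template matches)
returns NaN and flags the segment low-quality. Undefined normalized band
powers (LF+HF = 0) and spectral entropy of a zero-power series are NaN
sentinels with the same effect.

## Known limitations

* EDF fixtures are written by a minimal in-package writer (standard EDF,
  1-s records, 16-bit) — sufficient for round-tripping synthetic fixtures,
  not a general EDF+ implementation (no annotations channel, integer rates
  only).
* The artifact rule inevitably interacts with pulse morphology: waveforms
  with crest factor above 1.5 would lose clean beats. Real recordings with
  large motion artifacts inflate the window SD and mask this; the generator
  instead keeps clean crest factors below threshold.
* AHI from recording time (not sleep time) systematically underestimates
  in subjects with low sleep efficiency; by design, matching the screening
  procedure being modeled.
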