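# Methods

`mciscreen` implements a multimodal screening protocol for mild cognitive
impairment (MCI) that combines three data streams recorded while an older
adult performs immersive scene-description language tasks: a four-channel
wearable EEG (TP9, AF7, AF8, TP10 at 256 Hz), the task speech recording,
and two VR-derived timing parameters.  This note describes the models and
estimators, the defaults and why they were chosen, what the synthetic
cohort emulates, and the limits of what the test suite shows.

## EEG feature bank (80 features)

Recordings are preprocessed with a zero-phase 0.1–45 Hz band-pass.  The
filter is applied as an FFT-domain mask with raised-cosine transitions
(low edge ramps from 0.05 to 0.1 Hz, high edge from 45 to 47 Hz) rather
than a recursive filter: a high-order IIR high-pass at a normalized
frequency of ~8·10⁻⁴ is numerically unstable under forward–backward
filtering in double precision, while the FFT mask is exactly zero-phase,
length-preserving and removes DC.  Optional artifact handling offers
amplitude rejection (drop 1 s segments exceeding a configurable µV
threshold, default 200 µV, reported as rejected spans) and an ICA hook
that delegates to FastICA, zeroing components whose excess kurtosis
exceeds 5 (blink/EMG-like heavy tails); recordings under 10 s fall back
to amplitude rejection with a warning.

Five band definitions are fixed: δ 1–4, θ 4–8, α 8–13, β 13–30,
γ 30–45 Hz (half-open intervals `[low, high)`).  Per channel and band the
bank computes:

* **Mean power (MP)** — the time-average power of the band-limited
  signal, estimated as the Welch density integrated over the band.  With
  this convention a sinusoid of amplitude A inside the band has mean
  power A²/2, which makes the estimator auditable analytically.  A
  per-Hz density variant is available via `mean_power(..., per_hz=True)`.
* **Signal energy (SE)** — the sum of squared samples of the
  band-filtered series (zero-phase 4th-order Butterworth per band; band
  edges of 1 Hz and above are numerically safe for the IIR form).
* **Spectral entropy (ShE)** — Shannon entropy, base 2, of the in-band
  Welch densities renormalized to a probability distribution; bounded by
  log₂(#in-band bins), 0 for a single-bin spectrum.
* **DASM / RASM** — left-minus-right and left-over-right band power for
  the homologous pairs TP9/TP10 and AF7/AF8 (left = TP9, AF7).  RASM
  floors its denominator at 10⁻¹² of the right channel's total power and
  flags the value instead of emitting an infinity.

Welch settings: 4 s Hamming windows, 50% overlap, one-sided density.
The window length is set by the narrowest band: the Hamming main lobe at
4 s is 1 Hz wide, so edge leakage out of the 3 Hz delta mask is a few
percent; 2 s windows would lose ~10% of delta power across the mask
edges.  Features are computed over the whole task recording (no
epoching), matching one vector per participant × task.

With 4 channels × 5 bands for MP/SE/ShE and 2 pairs × 5 bands for
DASM/RASM the bank has exactly 80 named features
(`MP.TP9.theta`, `DASM.TP9-TP10.alpha`, …), and 4·3·B + 2·2·B for B
bands.

## Speech feature bank (49 features)

Frames are 25 ms Hamming windows every 10 ms after 0.97 pre-emphasis.
The bank has four blocks:

* **Contour summaries (28)** — min, max, range, mean, sample std
  (ddof=1), skewness and excess kurtosis of the F1, F2, F3 and pitch
  tracks over voiced frames.
* **Jitter (5)** — local, local absolute, rap, ppq5, ddp over the pitch
  periods of the longest uninterrupted voiced run; formulas are the
  standard period-perturbation quotients documented in
  `jitter_measures`, with ddp computed as 3·rap (an exact algebraic
  identity).  A whole-recording option exists.
* **Duration summaries (12)** — min, max, range, mean, sum, std of pause
  durations and of per-interval effective speech durations.
* **Rhythm ratios (4)** — long-pause/speech-interval count ratio,
  short-pause/speech-interval count ratio, total transcript characters,
  articulation rate (characters per second of effective speech).

Voice activity detection is energy-based on 10 ms non-overlapping
frames: a frame is speech when its log energy exceeds
`max(silence_floor, min(noise_floor + 15 dB, peak − 12 dB))`, where the
noise floor is the 5th percentile of frame energies and the silence
floor is −55 dBFS.  The peak-headroom cap keeps recordings that are
speech throughout detectable; the absolute floor keeps silent recordings
silent.  Sub-100 ms gaps are smoothed over, speech blips under 100 ms
removed, and only gaps of ≥ 150 ms between speech intervals count as
pauses; the short/long boundary is 1.0 s (within- vs between-sentence
pauses).  The 10 ms VAD frames keep interval-boundary bias within one
hop.  Leading and trailing silence belongs to neither class.

Pitch uses the normalized autocorrelation per 40 ms frame, search range
60–400 Hz, voicing threshold 0.45; among peaks within 85% of the best
peak the shortest lag wins (suppressing octave-down errors), refined by
parabolic interpolation.  Formants come from linear-prediction root
finding on pre-emphasized voiced frames: model order 2 + fs/1000,
autocorrelation method via Levinson recursion, poles kept when the
implied bandwidth is < 400 Hz, lowest three resonances assigned F1–F3
(ascending); frames with fewer than three resolvable resonances are
skipped and counted.

Transcript characters are counted per Unicode code point excluding
whitespace and punctuation — the character is the natural production
unit for a Chinese-speaking cohort, and the rule is CJK-safe.

Missing values never shrink the vector: unmeasurable entries are 0 with
a named quality flag, so feature tables keep 49 columns on any input.

## Digital cognitive parameters

Two per task: total test time and recording duration (seconds).
Cleaning imputes missing cells with the stratum mean (group × task by
default, to avoid pulling one group's central tendency into the other; a
pooled mode exists), flags and winsorizes values whose robust z
(median/1.4826·MAD) exceeds 3 — capping instead of dropping keeps every
participant available for leave-one-out evaluation — and flags rows
where the recording outlasts the test.  Cleaning is idempotent.

## Selection

Band selection scores all 31 non-empty subsets of the five bands by
repeated leave-one-out accuracy of a classifier (RBF SVM by default) on
the band-restricted EEG features, and returns the argmax; ties break
toward fewer bands, then lower frequencies, and the rule is recorded.
Since leave-one-out has no fold randomness, "repeats" re-seed the
classifier (default 50; fidelity runs can use 1000).  Feature-subset
selection is RFECV: recursive elimination of one feature per step with
stratified 5-fold accuracy scoring, keeping the subset size with the
best mean score; the estimator must expose importances (tree, forest or
gradient boosting — the RBF SVM is rejected with a pointer to usable
kinds).

Two leakage policies: `global` mode selects once on the full cohort and
reports leave-one-out accuracy on the same data (how such protocols are
commonly reported; optimistic); `nested` mode redoes selection inside
every training fold (unbiased, much slower).  Reports always state the
mode.

## Classification and fusion

Four classifier families with fixed hyperparameters: decision tree;
random forest with 150 trees; RBF-kernel SVM (features standardized with
training-fold statistics; Platt-scaled probabilities for fusion);
XGBoost with gamma 0, learning rate 0.3, 120 estimators.  Evaluation is
leave-one-out cross-validation repeated with re-seeded classifiers,
averaging accuracy, precision, recall and F1 per repeat; MCI is the
positive class.  Modality fusion concatenates the selected per-modality
columns in the order EEG, speech, digital.  Cross-task decision fusion
weights each task's class scores by that task's share of the summed task
accuracies and sums before the argmax; exact ties resolve to the
screening-conservative HC label and are flagged.  The cross-task
"all tasks" evaluation concatenates the tasks' fused vectors (a pooled
mode is a straightforward variant).

## Synthetic cohort

Clinical recordings of this kind are not shareable, so the generator
produces a full cohort — manifest, EEG CSVs, WAVs, transcripts, timing
tables, plus a per-participant `truth.json` sidecar — whose group
effects follow the reported directions:

* EEG per band is FFT-masked Gaussian noise scaled to an exact target
  variance, making planted powers directly auditable.  Resting-state
  band powers default to (30, 15, 20, 8, 3) µV² for δ…γ with lognormal
  per-subject scatter (σ = 0.25) and a 1.1 left/right power ratio (so
  asymmetry features have nonzero truth).  Under the task, low
  frequencies rise ×1.2 in both groups; MCI gets an extra ×1.6 on theta
  and ×1.25 on delta — theta dominant, matching the band reported as
  clearest.
* Speech is a jittered glottal pulse train (per-subject F0 ~150 ± 20 Hz,
  1% period jitter) through a fixed all-pole vocal tract (resonances
  700/1220/2600 Hz), emitted in bursts separated by short or long
  pauses.  MCI participants speak ×0.65 as long, draw fewer short pauses
  (probability 0.7 → 0.4), produce ×0.65 the characters per second, and
  take ×1.4 the test time.  Lognormal between-subject scatter
  (σ ≈ 0.2–0.25) keeps the group distributions overlapping — planted
  standardized differences are ≈ 1.5–2, clearly significant at the
  default cohort size rather than trivially separable.
* Defaults mirror the study scale: 44 MCI + 42 HC, two tasks.  Tests and
  the acceptance script run scaled sizes (typically 10 + 10
  participants, 10 s task EEG, ~6 s of speech per task) chosen as the
  smallest cohorts on which selection and fusion behave stably.

Generation is byte-deterministic given the config.

What the generator does **not** emulate: real EEG artifacts (blinks,
EMG, electrode pops), 1/f spectral shape, natural-language content,
coarticulated formant dynamics, or recording-channel variation.  Passing
tests therefore demonstrate that the pipeline recovers known effects
embedded in clean, in-model data — not clinical performance.  The
headline accuracies on the synthetic cohort (often ≥ 0.9 at strong
planted effects) are properties of the simulation, not estimates of
screening accuracy on patients.

## Numerical choices and degenerate inputs

* Stereo WAVs are averaged to mono; 16/24-bit PCM normalized to [-1, 1].
* Zero in-band power yields spectral entropy 0 with a warning; RASM with
  a floored denominator is flagged; empty contours/series flag all their
  summary statistics; jitter requires ≥ 5 voiced periods.
* Group statistics use Student's t when an F-test accepts equal
  variances at 0.05 and Welch's t otherwise (the variance-heterogeneity
  corrected form), chi-square for categorical variables; raw p-values
  carry the significance stars, with Benjamini–Hochberg adjusted values
  alongside.
* Leave-one-out requires n ≥ 4 and both classes; a classifier/combination
  whose every task accuracy is 0 falls back to uniform decision weights
  with a logged warning.
* All randomness flows from explicit seeds; reports embed the resolved
  configuration, its hash, the seed and the package version, and equal
  hashes imply identical reports.

## Known limitations

* `global`-mode selection is optimistically biased by design; use
  `nested` mode for unbiased estimates (cost: selection inside every
  fold).
* Welch band powers on short records carry ~5–10% sampling variability
  per channel in the narrow delta band; recovery contracts are stated on
  channel-averaged ratios.
* The formant tracker assumes an all-pole vocal tract and clean audio;
  nasals and noisy recordings will produce skipped frames.
* Jitter is computed from frame-level pitch periods (40 ms frames
  spanning several glottal cycles), which attenuates true cycle-to-cycle
  perturbation relative to cycle-marking methods; the measures remain
  valid comparatively (0 for periodic input, monotone in planted
  jitter), but their absolute scale is conservative.
* The ICA hook separates at most 4 components (4 channels) and relies on
  a kurtosis heuristic; it is a hook for an established decomposition,
  not a validated artifact-removal pipeline.
* On the synthetic cohort at desk scale (~30 participants), tri-modal
  fusion beats the mean of the single modalities in every seed we
  measured, but the strongest single modality (speech, in this
  simulation) matches or beats the fused vector in roughly a quarter of
  seeds — per-modality RFECV can admit features that dilute an already
  dominant modality at small n.  Fusion's advantage is an average-case
  property here, not a per-seed guarantee.
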