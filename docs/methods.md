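# Methods

This note documents the models, numerical choices and known limitations of
`seegstate`. It is the design record a maintainer should read before
changing defaults.

## Signal model and preprocessing

A recording is a channels × samples matrix in microvolts at 1000–2000 Hz,
with each channel assigned to a depth-electrode shaft and a contact index.
Two families of derived traces are computed, in a fixed, logged order:

* **Band power** (high-gamma 60–140 Hz, beta 13–30 Hz, alpha 8–12 Hz):
  comb notch → Laplacian re-reference → Butterworth band-pass → Hilbert
  transform → squared magnitude. The squared Hilbert envelope of a
  band-passed sinusoid of amplitude *A* is *A*², which the unit tests pin.
* **ERP**: comb notch → 0.5 Hz high-pass → Laplacian re-reference.

Numerical choices:

* All IIR filtering is **zero-phase** (forward–backward, `sosfiltfilt`) by
  default. This is an offline pipeline; causal filtering would delay the
  high-gamma envelope by a group delay comparable to the 50 ms window step
  and misalign the 300–1000 ms active window across bands. Causal mode is
  available via `zero_phase=False`.
* The comb notch is a cascade of second-order IIR notches at 50, 100, … Hz
  up to Nyquist with Q = 35 (≈1.4 Hz stopband at 50 Hz) — narrow enough to
  leave the beta and high-gamma bands essentially untouched.
* "6th-order Butterworth band-pass" is interpreted as the overall filter
  order (a 3rd-order low/high prototype pair).
* The 80 ms Gaussian smoothing kernel has total support 80 ms and
  σ = support/6 (the conventional ±3σ truncation), normalized to unit area;
  epochs are reflect-padded so length is preserved.
* Laplacian reference: interior contacts subtract the mean of their two
  shaft neighbours; shaft ends fall back to a bipolar reference against the
  single neighbour; single-contact shafts are dropped with a warning.
* Samples are 0-based; all time intervals are half-open `[start, end)`.

## Epoching and normalization

Trials are cut to −200…+1000 ms around stimulus onset; the −200…0 ms
pre-stimulus segment is the baseline. Two z-scoring modes exist:

* `per_trial` — each trial z-scored against its own baseline (baseline mean
  0, SD 1 to 1e-6 before smoothing). Used for trace inspection and epochs.
* `pooled` — each channel z-scored with baseline statistics pooled over all
  its trials. **The channel-selection statistic uses this mode.** With
  per-trial scoring every idle-period mean is identically zero, so the
  shuffled-label null of the permutation test is not exchangeable and its
  p-values are strongly anti-conservative; pooled scoring restores
  calibration (verified by a Kolmogorov–Smirnov uniformity test on 500 null
  channels in the acceptance suite).

A residual, much smaller miscalibration remains because the active window
(700 ms) and the idle window (200 ms) average different numbers of
effectively independent samples; the rank test sees this variance mismatch
as a slight excess of small p-values (~8 % below 0.05 instead of 5 % on
null data). This is a property of rank tests under unequal group variances,
not of the implementation.

## Channel and feature screening

Per channel: *z* = concat(per-trial active means, per-trial idle means) is
Spearman-correlated with −1/1 labels; 1000 label shuffles (200 in the test
suite for runtime) form the surrogate distribution. The reported p is the
two-sided tail probability of the observed r under a normal fit to the
surrogates; an empirical-tail p and a one-sided option are available.
Bonferroni correction divides α = 0.05 by the number of channels tested per
trace kind. At most the ten smallest-p significant channels are kept; ties
break by larger |r|, then channel id.

Feature dimensions are screened with the same machinery per column (shared
shuffle streams across columns for speed; each column's marginal p is
unchanged), keeping the ten smallest-p columns overall. PCA (fitted on
training rows only) retains the minimal number of components whose
cumulative explained variance exceeds 0.95.

## Windows, features and the continuous stream

Sliding windows start at 0 and advance in 50 ms steps ("overlap time of
50 ms" is read as the *step*: the observed ±tens-of-ms onset-timing
resolution is unattainable with 350–450 ms steps; the literal reading is
available via configuration). The four operators per window are
A = mean, RMS = √mean(x²), k = OLS slope against time in seconds (so values
are fs-independent), and L = Σ|x[i+1] − x[i]|.

Classification runs on the *continuous* stream, but z-scoring is defined
against pre-stimulus baselines. The pipeline bridges this by normalizing
each continuous trace with per-channel baseline statistics pooled over the
pre-stimulus segments of the **training folds only** (rebuilt per CV
rotation and cached); feature selection and PCA are likewise fitted per
rotation on training rows. A window's label is the ground-truth state at its
midpoint (majority-overlap labelling available).

## GMM-HMM detection

* Transition matrix: empirical pair counts of the training label sequence,
  counted within contiguous segments only (never across the gap between the
  two training folds); zero-count rows fall back to uniform with a warning.
  The initial distribution is the empirical state frequency.
* Emissions: per-state Gaussian mixtures with full covariances,
  BIC-selected component count in 1…5, covariance floor 1e-6 of the mean
  feature variance, seeded initialization. Too few rows per state cap the
  mixture size with a warning.
* Decoding: max-product (Viterbi) in log space by default — both it and a
  forward-filtering argmax (available as `mode='filter'`) satisfy the
  transition-times-emission recursion; the joint path yields contiguous
  periods, which the period-level metrics need. Exact ties resolve to idle,
  then to the lower state index (the state alphabet is ordered idle-first).
  The decoder is oracle-tested against exhaustive path enumeration.
* Baselines: LDA, SVM and random forest classify windows independently with
  class-frequency weighting.
* Cross-validation: the window stream is split into three consecutive equal
  segments (boundaries ⌊n/3⌋, ⌊2n/3⌋); each rotation trains on two and
  predicts the third, so training and test windows never overlap.

## Period-level evaluation

Runs of identically-labelled windows become periods spanning
`[mid_first − step/2, mid_last + step/2)` — midpoint attribution localizes
period edges to ±half a step (±25 ms at the default step). Matching rules:

* detected ∩ actual ≠ ∅ → TP, with onset/end differences (detected −
  actual);
* unmatched actual → FN; unmatched detected → FP;
* |onset diff| > 400 ms adds an FP; |end diff| > 400 ms adds an FN;
* a detected period penetrating k ≥ 2 actual periods counts 1 TP +
  (k−1) FP, onset against the first actual, end against the last;
* symmetrically, extra detections on an already-matched actual period count
  as FPs (the converse case is not otherwise specified; symmetry with the
  penetration rule is the design choice);
* TN: idle gaps between actual active periods (within the session span)
  that do not *fully contain* any detected interval. Full containment, not
  overlap, is used: otherwise every true positive with a few tens of
  milliseconds of boundary jitter would void its neighbouring gap and TNs
  would be nearly impossible. This makes the (TP+TN)/(TP+FP+TN+FN) accuracy
  well defined; the counting unit is a documented design choice.

Chance levels shuffle the window labels used for feature screening and
classifier training (the evaluation always uses the actual labels), rerun
the per-fold fitting, and take the 95th percentile (linear interpolation) of
each indicator over the permutations; undefined indicators enter as 0.

**Known degeneracy:** under a dense periodic paradigm (active states cover
~25 % of the session every ~2.8 s), a shuffled-label classifier emits very
few detections, and a single chance detection that happens to overlap an
actual period within the 400 ms rule scores precision = 100 %. The
permutation null of period-level *precision* therefore has a large atom at
100 % and its 95th percentile saturates there; precision cannot be
"strictly above chance" in this regime no matter how good the detector is.
Sensitivity and accuracy chance levels are well behaved (≈7 % and ≈52 %
respectively on the default session). Sparser paradigms (long inter-trial
intervals) do not show the saturation.

## Synthetic sessions

The generator emulates the auditory-name paradigm: n trials of two stimulus
types in equal counts and pseudo-random order; onset gaps =
cue + preparation + stimulus + inter-trial interval with uniform jitter.
Defaults follow the strongest studied configuration: 120 trials, 1 s
stimuli, 1100–1300 ms jittered ITI, 100 ms cue, 500 ms preparation, 1 kHz,
20 channels on two 10-contact shafts, five responsive channels.

* **Background**: per-channel 1/f-shaped noise (10 µV RMS, flattened below
  1 Hz), 50 Hz line interference (5 µV), white sensor noise (2 µV).
* **High-gamma responses**: band-limited 60–140 Hz noise multiplied by a
  Tukey-tapered envelope over [onset+300, onset+1000) ms and added to the
  channel; Hilbert power of the response scales with gain² (a multiplicative
  envelope, not an additive sinusoid, so power-trace analyses see it
  correctly). `gain` multiplies the channel's baseline band RMS.
* **ERP responses**: a fixed-polarity slow monophasic deflection plus
  damped <15 Hz sinusoids. The monophasic component is essential: a pure
  damped oscillation has near-zero window mean, invisible to the
  mean-amplitude channel statistic; real auditory ERPs have non-zero-area
  components.
* **Spatial modes**: `focal` adds the response to the named channel only
  (and a zero-gain profile leaves the signal bit-identical). Focal sources
  leak −1/2 of the response into shaft neighbours after Laplacian
  re-referencing, which makes neighbours genuinely responsive. `spread`
  (the session default) writes the least-squares preimage of the shaft
  Laplacian onto the whole shaft, emulating a volume-conducted source that
  re-referencing focalizes back onto the planted contact; the preimage is
  inexact (the Laplacian is singular) and leaves a uniform ≈12 % amplitude
  residual across the shaft, i.e. ≈1.4 % of the planted response power.
* Ground truth marks [onset+300, onset+1000) ms per stimulus with the
  stimulus type; everything else is idle.

What the generator does **not** emulate: epileptiform artifacts, volume
conduction between shafts, non-stationary background power, latency jitter
of the evoked response, and realistic effect-size distributions. No
subject-level SNR is reported for the real recordings, so synthetic gains
are free parameters: absolute performance numbers from this generator are
calibration-dependent and say nothing quantitative about patient data —
passing tests demonstrate correctness and qualitative behaviour
(detectability, calibration, HMM-vs-baseline precision ordering), not
clinical performance.

Two study conditions are fixed by calibration and then left alone:
* the default session (gain 3) — responses strong enough that selection and
  detection should be near-ceiling;
* the classifier-comparison condition (40 trials, 2.5–3.5 s ITIs,
  10 channels on two shafts, 4 responsive channels at gain 1.3) — a
  moderate-SNR, idle-dominated regime where window-independent classifiers
  emit sporadic false detections in the long idle stretches and the HMM's
  transition prior suppresses them, reproducing the precision ordering
  (HMM ≫ LDA/SVM/RF) with sensitivity ≥ 90 %.

## Problem sizes in the test and acceptance runs

To keep desk-scale runtimes, the suite uses 200 label permutations for
channel screening (the analysis default is 1000), 100 for feature screening
and chance levels, 30–40-trial sessions where only calibration is at stake,
and the full 120-trial session for the end-to-end and three-class runs.

## Limitations

* The permutation chance level for period-level precision is degenerate
  under dense paradigms (see above).
* The channel test is mildly anti-conservative from the active/idle window
  length mismatch (see above); Bonferroni correction in the selection stage
  absorbs this in practice.
* AR(100) spectra on 150–500 ms windows are heavily regularized by the
  biased autocovariance; their "amplitude" (√PSD) band contrasts are
  correspondingly compressed.
* The comparator extractors (AR/STFT/Morse wavelet) are evaluated per band
  and are much slower than the time-domain operators (per-window model
  fits); they are not vectorized.
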