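# Methods

This note records the models, conventions and numerical choices behind
`earsleep`, in the order the pipeline applies them, together with what
the synthetic fixtures do and do not establish.

## Signal conditioning

The classification path conditions one channel as *decimate → segment →
amplitude-reject → band-pass*:

* **Decimation** to 200 Hz by an integer factor (zero-phase Chebyshev-I
  anti-alias filter via `scipy.signal.decimate`; stopband > 40 dB at the
  output Nyquist). Non-integer factors are refused rather than resampled.
* **Segmentation** into non-overlapping 30-s epochs (6000 samples at
  200 Hz); a trailing partial window is discarded.
* **Amplitude rejection** drops epochs whose absolute amplitude *exceeds*
  ±400 µV — the inequality is strict, so an epoch peaking at exactly
  400 µV is kept. Rejection runs on the decimated, not-yet-band-passed
  signal by default: filtering first can shrink an artifact below the
  threshold and hide it. The opposite order is available via
  `PreprocessConfig(reject_stage="post_filter")` since the choice is a
  genuine convention, not a derivable fact.
* **Band-pass** 0.5–30 Hz, 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`) so that zero phase distortion leaves
  spindle timing intact. The quoted corners are the −3 dB points of the
  single-pass design; the two-pass cascade doubles that to −6 dB at the
  corners. A separate 1–20 Hz "scoring" band (with a per-subject low
  cutoff of 1 or 2 Hz) is kept in the configuration for emulating
  manual-scoring display preparation.
* **Amplitude-range normalisation** between an ear and a reference
  channel matches the robust (2nd–98th percentile) spans by an affine
  map. A min–max span would be controlled by single artifact samples; a
  percentile span is stable. The median is used as the matching centre.

## Spectral edge frequencies

PSDs are Welch estimates with 4-s Hann windows at 50% overlap, giving
0.25 Hz resolution at 200 Hz. Nothing deeper than variance stabilisation
motivates 4 s: over a 30-s epoch it averages ~14 segments while still
resolving the 0.5 Hz band edge. SEFr is evaluated on the discrete grid:
restrict to the closed band, accumulate bin powers, return the first
grid frequency whose cumulative sum reaches r% of the band total (ties
break by ≥, no interpolation). SEF is therefore exactly reproducible by
a cumulative-sum loop, scale-invariant, monotone in r, and confined to
the band. Zero-power bands yield NaN features; such epochs are dropped
before classification with a logged count.

## Multi-scale fuzzy entropy

Scale τ replaces the series by means of τ consecutive samples
(`floor(N/τ)` values); FE at each scale uses embedding dimension m = 2,
fuzzy power n = 2 and tolerance coefficient 0.15. Conventions that the
literature leaves open, fixed here:

* **Variant**: de-meaned templates, Chebyshev distance, similarity
  exp(−dⁿ/r), self-matches excluded, and the same template count
  (N − m − 1) for both embedding dimensions.
* **Tolerance**: the epoch is divided by its scale-1 standard deviation
  once, and r = 0.15 is applied at every scale. This is algebraically
  the "r = 0.15 × SD of each epoch" rule, makes FE exactly invariant
  under amplitude scaling, and deliberately lets the variance shrinkage
  of coarse-graining lower the entropy of noise-dominated signals —
  the mechanism behind the falling wake profile below. Recomputing r
  per scale (`FEParams(r_per_scale=True)`) isolates pure structure
  instead.
* **Performance**: the O(N²) pair loop is numba-compiled (~0.5 s for a
  6000-sample epoch across all 15 scales on one core) and is tested to
  agree with an independent `scipy.spatial.distance.cdist` reference to
  1e-10.

Degenerate inputs (constant series, or too few coarse samples) give NaN
rather than an exception, mirroring the SEF missing-value policy.

## Classification and evaluation

Features are min–max scaled to [0, 1] with statistics computed on the
training folds only; held-out values may leave [0, 1] and are not
clipped. A training-constant column is mapped to 0.5 with a warning
(it carries no information either way). Scaling inside each fold is the
correctness-first choice; a single global pre-CV scaling is config-gated
(`CVConfig(scaling="global")`) for comparability with pipelines that
normalise before splitting.

The classifier is an RBF-kernel SVM in scikit-learn's native one-vs-one
multi-class scheme. No hyperparameter values are canonical for this
problem; the defaults are C = 1 and γ = 1/30 (one over the feature
count), with an optional inner 3-fold grid search (C ∈ 10⁻¹…10³,
γ ∈ 10⁻³…10¹) that never touches the outer test folds. Folds are
stratified (default k = 5, seed 42) because N3 is typically scarce;
a class with fewer members than k raises with guidance rather than
producing empty-class folds. Held-out predictions are pooled across
folds into a single confusion matrix and scored once — staging studies
report one matrix per task, and pooling is what makes the per-class
counts in that matrix meaningful.

Agreement metrics (SE, PR, AC, π_e, κ) are computed from integer
marginal sums with one floating division each, so hand-evaluable
matrices reproduce their exact rational values (e.g. κ = 0.7 from
[[40, 10], [5, 45]]). Landis–Koch bands are closed on the right
(κ = 0.80 → "Substantial"). Undefined quantities (absent class,
single-class marginals) are NaN with a warning, never silently 0.

Three tasks are built in: wake vs sleep ({W} vs {N1, N2, N3}),
W-N1 vs N2-N3, and 4-class. REM does not enter classification (the
staging model is trained on nap-style recordings without REM); REM or
unscored epochs in a hypnogram are rejected with an explicit error.
The predicted hypnogram written by the pipeline encodes each predicted
class by its first member stage, so collapsing it under the same task
recovers the predicted class sequence exactly.

## Synthetic generator

Each stage is a sum of band-limited Gaussian oscillations (white noise
shaped by a 4th-order Butterworth band-pass, scaled to a target RMS,
with the filter's edge transient trimmed), a 1/f^β background flattened
below 0.5 Hz, and — for N2 — Hann-enveloped 13 Hz spindle bursts
(Poisson count, mean 4 per epoch, 1 s long). Epochs are generated at
1200 Hz and 30 s; recordings derive one sub-seed per epoch from the
master seed, so any epoch can be regenerated in isolation and seeded
runs are bit-reproducible end to end.

The shipped per-stage amplitudes are tuned fixtures — chosen once so
that the defining stage contrasts hold for every seed — not estimates
of any real dataset:

| stage | delta | theta | alpha | beta | background (β, RMS) | spindles |
|-------|------:|------:|------:|-----:|---------------------|----------|
| W     | 3     | 4     | 16    | 24   | 0.0, 34             | —        |
| N1    | 8     | 18    | 8     | 3    | 1.0, 12             | —        |
| N2    | 18    | 12    | 4     | 2    | 1.0, 10             | yes      |
| N3    | 45    | 8     | 3     | 1.5  | 1.2, 10             | —        |

(RMS µV per component; delta 0.5–2, theta 2–7, alpha 8–13,
beta 16–30 Hz.)

The contrasts these defaults guarantee: alpha power above delta power
in W and the reverse in N3; N3 slow-wave peaks above 75 µV after a
0.5–2 Hz band-pass; scale-1 fuzzy entropy lower in N3 than in W; and a
wake entropy profile that falls from τ = 1 to τ = 15. The last contrast
dictates the broadband character of the wake recipe: wake EEG owes its
irregularity to beta-band and EMG-like wideband activity, which is
exactly what coarse-graining averages away, whereas an alpha-dominated
recipe would alias its rhythm into the coarse scales and the profile
would rise instead. Note that after the 0.5–30 Hz band-pass every
stage's profile rises over the first few scales (a 200 Hz series
band-limited to 30 Hz is oversampled, so scale-1 entropy starts low);
the wake contrast is asserted between the endpoints.

**What the synthetic study does not show.** The generator produces
stationary, spectrally clean, perfectly labelled stages: no scorer
disagreement, no stage transitions within an epoch, no K-complexes,
no REM, no movement or electrode artifacts beyond the injected
amplitude plateaus. Near-perfect cross-validated accuracy on it
demonstrates that the pipeline is implemented correctly and that its
features separate the canonical spectral signatures — not that real
single-channel staging reaches such accuracy. On real recordings the
N1/N2 boundary in particular is spectrally blurred and N1 sensitivity
is known to drop far below the other stages.

## Problem sizes

The shipped study uses 360 epochs (3 hours of signal) with the class
imbalance W:82/N1:57/N2:172/N3:49, scaled from a reference pool of 293
scored epochs; rejection bookkeeping is demonstrated on 90-epoch
(45-min) recordings with 5 injected 500 µV artifact epochs; oracle
agreement for fuzzy entropy uses 50 series of length 300; the
shuffled-label control uses a class-balanced 160-epoch subset and 20
permutations. These sizes give stable means (the chance control's
standard error is ≈0.8 percentage points) while keeping a full rerun in
the minutes range on a single core.

## Known limitations

* EDF writing supports integer sampling rates and whole-second
  recordings (one data record per second); the EDF annotations channel
  is not parsed.
* Only integer decimation factors are supported; arbitrary resampling
  is out of scope.
* No temporal smoothing of the predicted hypnogram (no HMM/sequence
  model) and no per-subject (leave-one-subject-out) validation — epochs
  are pooled, as the cross-validation design assumes exchangeable
  epochs.
* The fuzzy-entropy kernel is exact O(N²); epochs much longer than 30 s
  or rates much above 200 Hz will be slow.
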