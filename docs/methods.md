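# Methods

This note records the models, conventions and numerical choices behind
`vdt2`, and what the synthetic-data experiments do and do not demonstrate.

## Vowel synthesis

`synth_vowel` renders a sustained vowel as a glottal-like pulse train:
one smooth pulse `u·exp(1−u)` per cycle (attack time = mean period / 8),
placed at its exact fractional sample onset. Successive periods and
cycle amplitudes are perturbed by i.i.d. truncated (±3) standard normals.
The perturbation draws are scaled by √π/2 so that the *expected* local
jitter and local shimmer of the ground-truth sequences equal the
requested `jitter_frac` / `shimmer_frac` (for i.i.d. normals,
E|z_{i+1} − z_i| = 2/√π; without the calibration a requested 2 % would
measure as 2.26 %). White noise is added at the requested
harmonic-to-noise power ratio, computed against the *AC* (zero-mean)
power of the pulse train — a one-sided pulse train carries roughly half
its power at DC, which the autocorrelation harmonicity measure never
sees, and scaling against total power would make every synthesized HNR
read ~3 dB low.

Design choices made here: the smooth pulse (rather than a sharp
exponential impulse) keeps the sampled cycle peak insensitive to
sub-sample pulse position, which matters because the extractor measures
shimmer from cycle peaks; a full glottal-flow model would add realism the
ground-truth contract does not need.

Defaults follow the recording protocol the package models: 4 s
recordings at 44.1 kHz.

## Feature extraction

The 14 measures use the Praat-convention formulas, written out in
`vdt2.acoustic`. The algorithms themselves are standard:

* **Pitch** — frame-wise normalized autocorrelation (40 ms window, 10 ms
  hop, search band 75–500 Hz covering the cohort's ~120–245 Hz F0 range)
  with the unbiased `n/(n−k)` lag correction, candidate local maxima,
  parabolic lag interpolation, and an octave cost of 0.05 per octave.
  The octave cost is required: for a periodic signal the corrected
  autocorrelation at 2T can exceed the value at T by a few hundredths, so
  an unpenalized argmax produces octave-down errors. Frames whose peak
  correlation falls below 0.45 are unvoiced; meanF0/stdevF0 use voiced
  frames only.
* **Cycle marking** — contour-guided peak picking on a lightly smoothed
  (~0.3 ms moving average) signal with parabolic sub-sample refinement;
  the search window is ±25 % of the local contour period and cycles
  deviating more than 25 % from the contour are discarded (octave/outlier
  guard, threshold configurable). Cycle amplitude is the raw-signal peak
  in a window centred on each mark: extending the window to the next mark
  would include the neighbouring pulse's rising edge and systematically
  flatten shimmer. At least 12 cycles are required (apq11 needs 11-point
  windows).
* **HNR** — per-frame `10·log₁₀(r/(1−r))` from the autocorrelation peak
  near the pitch lag, averaged over frames and clipped to [0, 40] dB.
  HNR frames use 80 ms windows, longer than pitch frames: with ~6+
  periods per window the edge bias of the estimate stays well below the
  noise term being measured. On synthesized signals the estimate is
  within ~0.5 dB of the injected value for targets in 10–25 dB.
* **Intensity** — frame RMS in dB with full-scale amplitude 1.0 mapped
  to 1 Pa re 20 µPa (a full-scale sine reads 90.97 dB). Absolute SPL is
  unrecoverable from uncalibrated WAV, so values are comparable only
  within this fixed offset convention; frames more than 60 dB below the
  loudest frame are excluded as silence.
* Stereo input is averaged to mono; localabsJitter is reported in
  seconds (sub-millisecond for speech, hence a table rounded at three
  decimals prints it as 0.000).

What the oracle-equivalence tests show: on clean synthesized vowels at
2 % injected perturbation, all nine jitter/shimmer measures computed from
marked cycles agree with the same formulas applied to the ground-truth
sequences to ~1 % (the test tolerance is ±15 %). Under added noise the
cycle-peak measures inflate (noise adds to peaks), which is a property of
peak-based perturbation measurement generally, not of this
implementation; equivalence is therefore asserted on clean signals.

## Synthetic cohorts

`sample_cohort` draws per-recording feature vectors from per-(group,
vowel, feature) Gaussians whose moments come from a packaged reference
table (two groups × six vowels × 14 features), truncated to physical
bounds (F0 ≥ 50 Hz, non-negative perturbation measures). Gaussians
truncated at the bound are the minimal assumption given only means and
SDs; for features whose mean sits within ~1.4 SD of zero (the jitter and
shimmer means), truncation shifts the realized mean upward by a few
percent of an SD — the law-of-large-numbers tests therefore check cells
whose bounds lie ≥3 SD away, where the bias is far below the 3-SE
tolerance.

A fraction `subject_effect_rho` (default 0.5) of each feature's variance
is a per-(subject, feature) offset shared across that subject's
recordings, making subject-level splitting meaningfully different from
row-level splitting. Cross-feature correlation is not modelled by
default (the reference table carries no covariance information); a
single shared latent factor is available via `feature_cov`.

Two cells need special handling:

* The reference table's control /i/ column is identical to the T2DM /i/
  column for all 14 features — almost certainly a transcription artefact
  in the source table. The fixture stores it verbatim and
  `GroupStats.anomalies()` flags it; generated /i/ recordings carry no
  between-group signal.
* localabsJitter is printed as 0.000 ± 0.000 (rounding). A literal
  zero-variance column would break training-set z-scoring, so the
  generator reconstructs it per row from the physical identity
  localabsJitter = localJitter / meanF0, giving ~7·10⁻⁵ s values that
  still round to 0.000 at three decimals.

Default composition (32 + 15 subjects, six vowels × two repetitions, 22
recordings dropped uniformly at random by simulated cleaning → 542 rows)
matches the study conditions the package models. The dropout is uniform
because no per-class retention breakdown is available.

**What passing tests do not show about real data:** generated features
are conditionally Gaussian, cross-sectionally independent given the
subject effect, and stationary across repetitions. Real dysphonic voice
features are skewed, mutually correlated (jitter variants correlate
strongly), and drift within sessions. Classifier performance on this
cohort therefore bounds what the *pipeline machinery* does, not what
acoustic screening achieves clinically.

## Validity statistics and the information model

Welch's unequal-variance t-test is the default (group sizes 32 vs 15 and
unequal spreads); Student's pooled test is available. Bonferroni uses
m = 14. Cohen's *d* is (mean_control − mean_T2DM)/pooled SD, positive
when controls are higher (meanF0) and negative for patient-elevated
perturbation measures. Tests pool all vowels by default (one row per
feature); a per-vowel option exists. The distribution-difference
statistic bins both groups on a shared equal-width grid over the pooled
range (default 20 bins) and takes half the L1 distance between the bin
proportions — the discrete total-variation distance, in [0, 1].

The information model counts one bit for the screening decision
(I_same = log₂2) against I = log₂(14 × 2 × N) bits contributed by N
people's 28 feature values, giving the efficiency ratio
η(N) = 1/(log₂N + C). The constant is conventionally used at two
decimals, C = 4.81 (= round(log₂28, 2)), which reproduces the published
percentages η(1) = 20.79 % and η(50) = 9.57 %; with the full-precision
constant η(1) evaluates to 20.80 %. `info_eta(..., exact_constant=True)`
exposes the full-precision variant. (At N = 30 the formula gives
10.29 %; a published 10.28 % appears to be a rounding slip and is not
asserted anywhere.) A feature "meets the threshold" when its
total-variation statistic reaches η(N).

## Feature selection

Equation-of-record normalization is the training-set z-score; validation
and test rows reuse the training μ and σ (leakage guard, tested).
"Lasso" is the classical L1-penalized least-squares fit of the 0/1 label
(an L1-logistic variant is available), with the penalty chosen by 5-fold
cross-validation over 50 log-spaced values in [10⁻⁴, 1]. RFE wraps a
200-tree Random Forest, dropping the least impurity-important feature
per iteration down to k = 6 (cross-validated size selection when k is
unset). Fusion is the plain set union, reported in canonical feature
order — the only reading under which the packaged reference subsets
(12 Lasso + 6 RFE) combine to the packaged 13-feature joint set. The
specific subsets selected on synthetic cohorts vary with the draw and
are not asserted; the packaged reference subsets serve the worked
example.

## The classifier

Architecture and objective are described in the README. Numerical and
design specifics:

* **Soft routing** is what makes the tree differentiable end-to-end and
  hence trainable as one L-BFGS-B problem; a hard-routing predict mode
  (follow the argmax gate) exists for inspection.
* **"4 layers"** is read as four *internal* levels → 15 internal nodes,
  16 leaves; depth is a constructor argument.
* **Attention** is a per-node softmax over features (a convex
  combination, directly interpretable as each feature's contribution at
  that node); a sigmoid-gate variant sits behind `attention="sigmoid"`.
* **Objective** — mean binary cross-entropy with probabilities clipped
  at 10⁻¹²; optional ridge on w and θ only (default 0). Attention logits
  are never penalized: shrinking them drives every node toward uniform
  attention, erasing exactly the structure the mechanism is for.
* **Gradients** are analytic (subtree value recursion; softmax Jacobian
  applied in closed form) and verified against central finite
  differences to 10⁻⁵ relative.
* **Optimizer** — L-BFGS-B, maximum 200 iterations, projected-gradient
  tolerance 10⁻⁵ (a quoted "learning rate" of 10⁻⁵ for a quasi-Newton
  method is interpreted as this tolerance; L-BFGS-B has no step-size
  hyperparameter). `ftol` is set to 10⁻¹⁴ so the gradient tolerance
  governs. Fits are deterministic given seed and data.
* **Initialization** — all parameters i.i.d. N(0, 0.1²) from a seeded
  generator (seed 42 by default).
* A probability exactly at the 0.5 threshold predicts the positive
  class (documented tie-break).

Structural identities tested: leaf path probabilities sum to 1 within
10⁻¹² for any parameters; a depth-1 tree with saturated leaves reduces
to logistic regression on attention-scaled features within 10⁻⁹; feature
permutation consistency; a depth-2 student refit to a depth-2 teacher's
labels reaches ≥0.9 AUC (n = 2000).

## Evaluation

Splitting is by subject, stratified by group, at 6:2:2 with
largest-remainder rounding of subject counts; remainder ties go to the
*later* partition, protecting the test set (47 subjects split 28/9/10).
T2DM is the positive class, so recall is sensitivity to disease. AUC is
the rank-based (Mann–Whitney) statistic with midrank ties, tested
against brute-force pairwise concordance. Predictions are per-recording
by default.

On the default synthetic cohort (seed 42) the end-to-end pipeline
reaches 0.627 test accuracy. That exceeds the 0.6 property-test floor
but is far from ceiling, and the 10-subject test split makes specificity
and AUC noisy: the generator's between-group effects are modest (|d| ≲
0.6 per feature), /i/ carries no signal at all, and the unpenalized
561-parameter tree overfits 320 training rows (training loss 0.298).
This is the honest behaviour of the method under the stated conditions,
not a tuned showcase.

## Problem sizes

Tests run at desk scale on one CPU: 4 s / 44.1 kHz signals for the
oracle-equivalence checks (~600 cycles), 16 kHz for short smoke signals,
n = 10,000+ draws for the law-of-large-numbers checks, 1000 replicates
for the t-test type-I simulation, n = 2000 for teacher–student recovery,
and the full 542-row cohort for the pipeline. The full suite completes
in well under a minute apart from WAV-level tests.

## Known limitations

* The extractor is built and validated for clean sustained vowels; it is
  not a general pitch tracker (no voicing transitions, no octave-jump
  repair beyond the octave cost, no spectral-domain HNR).
* Perturbation measures from marked peaks inflate under additive noise;
  comparisons across recordings assume comparable noise floors.
* Absolute intensity is convention-bound (see above).
* The cohort generator's independence and Gaussian assumptions
  (documented above) make its classification task easier in some ways
  and harder in others than real voice data; no claim about clinical
  performance follows from it.
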