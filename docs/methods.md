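# Methods

`eegmvpa` implements a time-resolved multivariate analysis of animacy
categorization in epoched EEG, comparing healthy controls (HC) with mild
cognitive impairment (MCI) patients, together with a synthetic cohort
generator that makes every stage testable without patient recordings. This
note documents the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not establish.

## Study design assumed by the pipeline

A session comprises `n_runs = 13` runs; in each run all 32 natural-image
stimuli (16 animal, 16 non-animal) appear once in random order, so each
stimulus accrues 13 repetition trials. Acquisition uses 63 scalp
electrodes plus a reference (recorded as channel 33) and three EOG
channels at 1200 Hz; epochs span −100 ms to +800 ms around stimulus onset.
All of these are `SyntheticDesign` fields and can be changed coherently.

Epoch windows are half-open, `[start, end)`, with the `t = 0` sample
counted on the post-stimulus side: (−100, 800) ms at 1200 Hz gives exactly
1080 samples, and 900 samples after resampling to 1000 Hz.

## Synthetic cohorts

The generator writes, for every trial of stimulus *s* (class *c*) in
group *g*,

    x(ch, t) = A_g · k_g(t) · w_{g,c}[ch] + A_stim · k_g(t) · u_{g,s}[ch] + ε(ch, t)

* `k_g(t)` — temporal kernel: a half-cosine ramp from the group's onset
  latency to its peak latency, then a mirror-image decay back to zero.
  Only the onset/peak semantics are constrained by the analyses; the
  half-cosine is the simplest smooth unimodal choice.
* `w_{g,c}` — unit-norm class spatial patterns, built as a shared random
  topography ± half a class-contrast vector. All pattern vectors live in
  the subspace orthogonal to the all-ones channel vector, so average
  re-referencing leaves the signal untouched.
* `u_{g,s}` — stimulus-identity patterns that make individual stimuli
  pairwise discriminable. Each set is centered across stimuli, so it
  contributes nothing to the across-stimulus mean response.
* `ε` — white Gaussian noise per channel and sample (`noise_sd`, default
  1, defining the baseline-SD unit in which amplitudes are expressed);
  an AR(1) temporal-correlation option (`ar_coeff`) is available because
  real EEG noise is autocorrelated and filter/resampling behavior should
  be exercised on both.

Group effects and defaults (`GroupEffectSpec`):

| parameter | default | meaning |
|---|---|---|
| onset latency | HC 100 ms, MCI 139 ms | kernel rise point |
| peak latency | HC 200 ms, MCI 239 ms | kernel maximum (39 ms MCI delay) |
| signal amplitude | HC 1.0, MCI 0.9 | evoked peak in baseline-SD units |
| stimulus amplitude | 0.5 | scale of `u_{g,s}` |
| pattern divergence | 0.3 | see below |
| latency jitter | 10 ms SD | per-subject latency shift |
| amplitude jitter | 0.1 SD | per-subject multiplicative amplitude |

Amplitudes are free parameters (no per-subject effect sizes are available
to emulate); the defaults are chosen so that HC animacy decoding is
clearly above chance at the study's trial counts while single trials stay
noise-dominated, which is the regime the analysis methods assume.

`pattern_divergence` ∈ [0, 1] makes the two groups' *patterns* differ
while their *mean* responses can remain identical. It (a) rotates the MCI
class-contrast vector away from the HC one by `divergence × 90°` inside
the subspace orthogonal to the all-ones vector, (b) mixes each MCI
stimulus-identity direction toward an independent random direction by the
same angle, and (c) interpolates per-stimulus gains (uniform on
`1 ± stimulus_gain_spread`, default spread 0.5) toward an independent draw
by the same fraction. The gain part
is what moves pairwise-decoding RDMs: pair discriminability is driven by
the distance between the two stimuli's patterns, and in 63 dimensions the
distances between randomly re-mixed unit directions concentrate tightly,
so direction changes alone leave RDM cells nearly unchanged, while gain
divergence changes realized pairwise distances robustly. Every gained set
is re-centered across stimuli, so mean-matching is unaffected.

`mean_matched = True` additionally forces equal amplitudes/latencies
across groups and disables between-subject jitter; the noise-free mean
evoked response of the two groups is then identical by construction
(asserted to < 1e-10), which is the fixture for the ERP-vs-pattern
dissociation experiments.

The continuous-session generator adds eye blinks as a Poisson process
(rate in events/min) of 300 ms raised-cosine transients, projected onto
the EOG channels (weights 1.0/0.9/0.8) and onto frontal electrodes
(prefrontal 0.5, anterior-frontal 0.3, frontal 0.15) — enough structure
for the ICA cleanup stage to have a measurable target.

What the generator deliberately does not emulate: volume conduction from
realistic sources (no head model), 1/f spectra and oscillatory rhythms,
non-stationary noise, artifacts other than blinks, and behavioral
responses. Passing tests therefore demonstrate that the analysis code does
what it claims under its own statistical assumptions, not that those
assumptions hold in any particular real recording.

## Preprocessing

Six stages in fixed order: (1) average re-reference and reference-channel
removal, (2) ICA-based EOG cleanup, (3) epoching, (4) baseline
z-normalization, (5) 50 Hz low-pass, (6) resampling to 1000 Hz. The
normalize-before-filter order is kept exactly as listed even though the
reverse is more common — order fidelity over convention.

* The re-reference mean is computed over the 63 recording scalp channels
  (EOG and the reference excluded), so the retained channels sum exactly
  to zero at every sample.
* ICA uses FastICA with a fixed seed and at most 20 components on the
  scalp channels only. The single component with the largest |Pearson r|
  against any EOG trace is removed by subtracting its outer-product
  contribution from the data — not by reduced-rank reconstruction, which
  at 63 channels would silently discard the variance the 20-component
  model never captured. Non-convergence degrades to a warning and
  unchanged data.
* Baseline normalization subtracts the pre-stimulus mean and divides by
  the pre-stimulus SD per trial and channel (zero-SD guards divide by 1
  with a warning); the operation is idempotent.
* The low-pass is a 4th-order Butterworth applied forward-backward
  (zero-phase) by default, because latency comparisons are a primary
  outcome and a causal filter would shift peaks; a causal option exists
  for sensitivity checks. Resampling is polyphase (1200→1000 Hz is 5/6);
  anti-aliasing is provided by the preceding 50 Hz low-pass.

## Time-resolved animacy decoding

Features at time *t* are the 63 channel values at that single sample. Per
repetition: stimuli (with all their trials) are randomly partitioned, per
class, into bins of 2, 3 or 4 stimuli (each repetition draws one size at
random; a "separate" mode runs each size and averages); when the class
size is not divisible, a random remainder is left out for that repetition.
Each bin's trials are sub-averaged into one exemplar, and a linear SVM
(libsvm via scikit-learn, C = 1, equal class weights) is scored by
leave-one-bin-out cross-validation with *paired* folds — each fold holds
out one bin of each class. The accuracy at *t* is the mean over
repetitions (study scale 10,000; tests use 15–100, which changes only the
Monte-Carlo error of the mean).

Because a stimulus and all its repetition trials land in exactly one bin,
no stimulus ever appears on both sides of a fold. Note a property that
matters when interpreting single subjects: conditioned on one dataset, the
null decoding accuracy fluctuates with an SD of roughly 0.14 at 16
stimuli/class (the effective sample is stimuli, not trials or
repetitions); it is unbiased at 0.5 across datasets, and cohort-level
inference (bootstrap over subjects against 0.5, Benjamini–Hochberg FDR
across time) is the supported way to claim significance.

Peak = earliest argmax of accuracy over post-stimulus samples; onset =
first FDR-significant post-stimulus sample (an explicit `None` when
nothing is significant). Group peak-latency comparison: statistic
median(MCI) − median(HC), bootstrap over participants (80% per-group
subsampling without replacement), one-sided add-one p-value, percentile
95% CI, bootstrap-SD SE.

## Pairwise-decoding RDMs

RDM cell (i, j) at time *t* is the leave-one-trial-out CV accuracy of a
linear SVM separating the two stimuli's repetition-trial patterns
(symmetric, zero diagonal, 496 informative cells at 32 stimuli). Group
comparison uses the Euclidean distance between the upper triangles of the
group-mean RDMs per time point; the maximum over time is tested by
permuting subjects' group labels at that time point (the selection of the
maximum is not corrected for, so the p-value at the max is mildly
anti-conservative when few time points are scanned — raw distances are
always reported alongside).

Scaled distances use the monotone family
`f(d) = log(1 + (d − d_min)/κ) / log(1 + (d_max − d_min)/κ)` with κ fitted
so the baseline anchor (mean pre-stimulus distance by default) maps to a
configurable image. A concave log map cannot place the baseline below its
linear image `(d_base − d_min)/(d_max − d_min)`; infeasible requests fall
back to the linear map with a warning. Raw distances are authoritative;
the scaling exists for display.

Cell-wise comparison: rank-sum across subjects per upper-triangle cell,
FDR over all cells. MDS uses classical (Torgerson) initialization refined
by SMACOF with a fixed seed; stress is reported.

## HC vs. MCI classification

A subject's activation pattern at *t* is the 63 × 32 matrix of
trial-averaged channel responses per stimulus (rows restricted to a
channel group when requested), flattened into a feature vector. Each
bootstrap draw subsamples 80% of each group without replacement and scores
a linear SVM by leave-one-subject-out CV with paired folds: one held-out
subject from each group per fold, the rest training. Plain one-at-a-time
LOSO is deliberately not used: with a mean-sensitive classifier the
training set is always short one member of the held-out subject's class,
which biases null accuracy far below chance (measured ≈ 0.1 at 8 + 8
subjects); pairing the held-out subjects makes every test set
class-balanced so the bias cancels and the null sits at 0.5. Reported
accuracy is the resample mean; significance against 0.5 uses the add-one
bootstrap p-value; FDR across time where a time course is scanned.
RDM-based group classification feeds each subject's RDM upper triangle
through the same machinery. Feature standardization across subjects is off
by default (a flag exists).

## Inference conventions

All resampling p-values use the add-one rule
`p = (count on the null side + 1)/(n + 1)`, so the smallest attainable
value at 10,000 resamples is 1/10001 ≈ 0.0001 and no p-value is ever 0.
The permutation test switches to exhaustive enumeration whenever the
number of distinct relabelings is at most `n` (the p-value is then the
exact tail proportion). Rank-sum and signed-rank use scipy's exact
small-sample distributions where available and tie-corrected normal
approximations otherwise; all-tied data returns p = 1 with a warning.
FDR is Benjamini–Hochberg throughout; the correction family is time
points within a region for time courses, regions at a fixed time point
for topography-style maps, and all 496 cells for RDMs. Summary-statistic
group-comparability checks use the pooled two-sample t-test (Welch behind
a flag).

## Problem sizes used in the test suite

The suite verifies statistical behavior on scaled-down instances chosen
to keep a full run on one CPU within minutes: simulated cohorts at 100 Hz
(analyses at ≥ 10 ms resolution do not need more), 8 + 8 stimuli where the
stimulus count is not itself under test, 6–10 subjects per group, 15–100
bin randomizations and 200–1000 bootstrap/permutation resamples.
Structural checks (trial bookkeeping, 1080-sample epochs, 63 × 32
activation patterns, 32 × 32 RDMs) run at the full design constants.

## Known limitations

* The exact resampling scheme behind participant "bootstrap without
  replacement" is underdetermined; the 80% subsample fraction is a
  convention, exposed as a parameter.
* The distance-scaling anchors map is a display convention; only raw
  distances are comparable across analyses.
* The bootstrap-against-baseline test is anti-conservative for small
  cohorts when the observed sample happens to sit off the baseline;
  calibration is exact only for the permutation and rank tests.
* The generator's linear signal-plus-noise model cannot probe failure
  modes arising from non-linear or non-stationary structure in real EEG.
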