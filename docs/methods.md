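# Methods

This note documents the models, estimators and numerical conventions the
package implements, the generative model behind the synthetic data, and the
design choices made where the underlying procedures admit more than one
reading.

## Task model

Eight cues form a 2×2×2 factorial (texture ∈ {solid, hollow}, shape ∈
{circle, square}, color ∈ {blue, red}). The texture is the *context*: it
selects which feature dimension (shape or color) is task-relevant; the value
on that dimension selects the response rule (face vs. scene); the rule plus
the probe category determines the yes/no response. Transitions between
consecutive trials are labeled EDS (context changed), IDS (context kept,
relevant-dimension value changed — which necessarily switches the rule) or
Stay (same rule; the cue may still change on the irrelevant dimension).
`label_transition` is verified against a brute-force re-derivation over all
64 ordered cue pairs and several counterbalanced mappings.

The sequence generator targets the design mix Stay/EDS/IDS = 0.5/0.25/0.25
(204/102/102 trials per subject at 8 runs × 51 trials). Uniform cue
randomization would produce ~50% EDS, so the generator instead consumes an
exact largest-remainder quota of transition conditions, then picks the cue
realizing the drawn condition that currently has the lowest usage count
(ties broken randomly), keeping the 8 cues and 2 probe categories
near-balanced. The first trial of each run is condition-unlabeled — no
cross-run transitions. Timing: cue 0.5 s, probe 2.5 s, inter-trial interval
1.5 + Exp(3.0) s truncated at 10.5 s (range 1.5–10.5 s, mean ≈ 4.3 s — an
exponential jitter reproduces both the stated range and a mean near 4.5 s,
which a uniform draw cannot).

## Synthetic data generator

Each dataset carries its generative `SyntheticBrain`, so recovery can be
scored exactly. Signal model per run (TR = 1.8 s):

* **Seed voxels** (default V = 200, partitioned into 9 named nuclei):
  condition-specific evoked amplitudes `O*` convolved with a nucleus-specific
  double-gamma HRF, plus background fluctuations, nuisance signals and white
  measurement noise. The HRF is *piecewise-linear on the FIR knot grid*
  (the double-gamma sampled at 0, 1.8, …, 14.4 s and linearly interpolated),
  so evoked responses lie exactly in the tent-basis span and noiseless GLM
  recovery is exact rather than approximate. An undershoot-gain parameter
  (default 1; a "deep undershoot" preset sets 3 for medial/posterior nuclei)
  scales the post-peak undershoot.
* **Background**: K = 10 shared latent sources with random voxel loadings
  *plus* per-voxel private fluctuations (SD 0.5). The shared latents give the
  principal-component regression meaningful low-rank structure; the private
  component keeps the seed background full rank, which makes the noiseless
  connectivity recovery identity exact (with a strictly low-rank background,
  regression can only recover the projection of the true weights onto the
  latent subspace).
* **Cortical targets** (default P = 100): the seed signal (evoked +
  background) propagated through the ground-truth weight matrix `W*`, plus
  optional target-intrinsic evoked responses (`cortical_evoked_sd`, default
  0, i.e. cortical patterns are exactly `W*ᵀO*`), nuisance and noise.
* **Hubs**: a configurable subset of nuclei (default AN, MD, VL, PuM)
  receives graded context-condition (EDS) amplitudes, |amplitude| =
  gain·(1+|N(0,1)|) with gain 4, and weight rows whose scale is proportional
  to that amplitude. Hubness is therefore *joint* in evoked amplitude and
  connectivity, and graded rather than flat: the designed ground truth is
  that removing the strongest-evoked voxels damages the prediction most,
  which is what the virtual-lesion analysis is meant to detect. With flat
  hub amplitudes the top lesion windows would be statistically
  interchangeable and that property would not be identifiable.
* **QC series**: framewise-displacement-like values |N(0, 0.1)| with
  occasional spikes above the 0.4 mm censoring threshold (rate 2%) to
  exercise the censoring path.
* **Behavior**: per-subject mean RT = exp(N(log 0.99, 0.18²) + N(0, 0.05²))
  + condition shift (defaults 0.17/0.08/0 s for EDS/IDS/Stay); accuracy a
  binomial proportion around 0.97 + shift (−0.03/−0.02/0) with 102/102/204
  trials. Effects plant the orderings the task is known to produce; the
  subject SD matches the scale of the reported condition SDs (~0.2 s).

What the generator does **not** emulate: spatial smoothness and
autocorrelation of fMRI noise, temporally autocorrelated (1/f) noise,
susceptibility artifacts, nonlinear HRF effects, trial-by-trial amplitude
variability, and behavioral RT/accuracy coupling. Passing tests therefore
demonstrate correctness of the estimators under the stated signal model,
not robustness to every property of real data.

## GLM

FIR ("tent") basis: 9 piecewise-linear knots at 0–14.4 s post cue, one
column per (condition, knot), plus per-run Legendre drift up to order 2.
Estimation is OLS on the frames retained after FD > 0.4 mm censoring;
censoring more than a third of frames raises a QC warning (the
subject-exclusion rule). A one-step Cochrane–Orcutt AR(1) prewhitening is
available (`prewhiten=True`) but off by default: the group statistics
computed downstream are t-based contrasts across subjects and are
insensitive to this within-subject refinement. Rank-deficient designs raise
an error naming the dependent columns (QR with pivoting).

Trial-wise betas use the least-squares-sum scheme: per target trial, one
regressor for the trial, one summing all remaining trials, plus baseline
and nuisance; the trial's response shape is the canonical double-gamma on
the tent knots. The scheme equals per-trial least squares exactly when
trials do not overlap, and recovers the target amplitude exactly whenever
the non-target amplitudes share a common value (the model LSS assumes).

The evoked scalar per voxel and condition is the **mean of the 9 knot
betas** (the same 9-TR average used for RSA patterns); peak and area
summaries are selectable. Group contrasts are paired-difference one-sample
t maps; cluster correction binarizes at a voxel-wise p, labels
face-adjacent components (6-connectivity; opposite signs never merge) and
drops clusters below a configured minimum size (58, 343 and 42 are the
conventional constants for the analyses this chain mirrors; Monte-Carlo
cluster-size estimation is out of scope, so sizes are configuration, not
inference).

## Background connectivity

PCA across seed voxels on GLM residuals (censored frames excluded;
per-voxel centering handles constant series), all `min(V, T−1)` components
by default ("maximum available"), target residuals regressed on component
scores, coefficients projected back to voxel space. No variance-based
truncation, no shrinkage. With the full component set this is the
minimum-norm multivariate least-squares solution and equals ordinary
multivariate OLS whenever the seed data have full row rank (asserted to
1e-6 against direct `lstsq` on random instances). Raw (non-residual) series
are refused unless explicitly forced, since background connectivity is
defined on task-regressed data.

## Activity flow

`P_ctx = O_seed · W_FC` per half; halves are the first vs. last half of the
run list (runs 1–4 vs. 5–8 by default; any split can be passed). Raw
accuracy is the plain mean (not Fisher-z) of the two fold correlations on
z-scored patterns — with only two folds and |r| typically far from 1 the
difference is negligible, and the plain mean matches the stated averaging.
Noise ceiling: `vU = var(pred_h1)`, `vE = var(pred_h1 − pred_h2)`,
`r_nc = vU/(vU+vE)`, implementing the stated definition literally: `vE` is
*not* halved, so with independent halves `r_nc → 1/3` rather than 1/2, and
normalized accuracies can exceed 1 under heavy noise. The alternative
(`vE/2`, exact variance decomposition) is deliberately not applied; the
normalized accuracy is a reliability-corrected score, not a bounded
proportion.

Permutation nulls (default 5,000 draws): `shuffle_evoked` permutes the
entries of `O_seed`; `shuffle_fc` permutes **all elements** of `W_FC`
jointly (not within rows). The same permutation is applied to both halves
so a permuted "subject" stays internally consistent; p-values use the
(1 + #{null ≥ observed})/(n_perm + 1) correction and can never be zero.

Virtual lesions zero the evoked entries (both halves) of a 20%-wide window
of voxels ranked ascending by the split-half mean |evoked| (stable sort;
ties broken by voxel index). Window starts step the 1st–80th percentile
with a nearest-rank start index, clamped so the final window covers exactly
the strongest 20% of voxels. The per-nucleus attribution assigns each voxel
the mean reduction of the windows containing it and averages within
nucleus; the few voxels in the top percentile covered by no window are
excluded, and empty nuclei report NaN. Degenerate lesions (all voxels
removed → constant prediction) are flagged and scored as accuracy 0.

ROI-restricted (voxel-to-voxel) prediction is the same machinery with
targets = voxels of one region; seed-generic use (e.g. a basal-ganglia
label volume) only changes the label array.

## RSA

Neural RDMs are spatial Mahalanobis distances between the 8 cue patterns
(knot-mean betas), with the voxel covariance from GLM residuals —
Ledoit–Wolf shrinkage by default (voxel counts routinely exceed residual
frames at ROI scale), the sample covariance without shrinkage when frames
are plentiful, and a diagonal variance estimate as the documented fallback.
Model RDMs code each factor ±1 per cue, interactions as elementwise
products, and dissimilarity 1 where the (product) codes differ. The
**Decision** model required a choice: the literal "same motor response for
every probe" reading collapses onto the Task model (two cues share the rule
iff they always share the response), so Decision is coded as the integrated
task identity — two cues are identical iff they share the context *and* the
context-relevant feature value (four classes of two cues), the most
fine-grained representation that determines the full response mapping. The
full 13-model set is collinear with the intercept (two dependencies
involving Decision); `fit_rdm_regression` raises naming the dependency, and
`full_rank_models()` provides the maximal independent subset (the 5 primary
models plus 6 controls). Group inference: one-sample t per region×model,
Benjamini–Hochberg FDR across regions within model (q = 0.05 default).

## Decoding

Spherical searchlights (default radius 6 mm on 2.5 mm voxels — the radius
is a length, and is configurable) clipped to the mask; every in-mask voxel
is a center. Decoding is L2-regularized logistic regression (C = 1) with
feature standardization fitted inside each training fold;
cross-validation leaves one run out, and single-class training folds are
skipped with a warning. Accuracy is the mean over test folds. Group
inference tests accuracy > chance per voxel with sign-flip permutations on
accuracy−chance (one-sample t as fallback — the choice is configurable
because group-null construction is underdetermined in this literature),
then applies the same face-adjacency cluster correction as the GLM module.
Note the sign-flip p is bounded below by 1/(n_perm+1): reaching a 0.001
voxel threshold needs ≥ 1,000 permutations.

## Behavioral statistics

One-way repeated-measures ANOVA with F = MS_condition / MS_(condition ×
subject); the reported effect size is generalized η² — for this design
SS_cond / (SS_cond + SS_subject + SS_error) — which reproduces the scale of
the published η² values (partial η² does not; e.g. F(2,116) = 156 implies
partial η² ≈ 0.73 but generalized η² ≈ 0.11). Paired t-tests multiply p by
the number of comparisons (capped at 1). Cohen's d divides the mean
difference by the pooled SD of the two conditions — not the SD of the
differences — because that formula reproduces the published d values from
the published means/SDs. Trial-level RT summaries exclude incorrect trials.
The workbook reader returns tidy subject×condition tables and lists the
available sheets when a requested sheet is missing. F = t² for two
conditions is asserted exactly, and the ANOVA is cross-checked against an
independent implementation (pingouin) in the tests.

## Problem sizes and tolerances in the test suite

The validation suite runs the fidelity analysis at V = 200 seed voxels,
P = 100 targets, 8 runs (noiseless; normalized accuracy ≥ 0.99, permutation
p ≤ 0.002 at 500 draws); lesion specificity over 100 replicates at V = 150,
P = 80; RDM recovery exactly (1e-10) noiseless and within 2 SE over 200
noisy replicates; connectivity equivalence to 1e-6 over 20 random 10×200
instances; decoding calibration over 60 null simulations on a 27-voxel
mask plus 100 group-null cluster replicates on a 216-voxel mask. These
sizes were chosen so the whole suite completes in about a minute while
keeping every check statistically meaningful; all estimators accept
arbitrary sizes.

## Known limitations

* OLS with optional AR(1) replaces generalized least squares with a full
  ARMA(1,1) noise model; group maps use one-sample t rather than a
  mixed-effects model with per-subject variance weighting.
* Cluster-extent thresholds are configuration constants, not estimated from
  the spatial autocorrelation of the data.
* The noise-ceiling definition (unhalved `vE`) makes normalized accuracy an
  unbounded score under heavy noise.
* Crossvalidated (crossnobis) distances, multiclass decoding and directed
  connectivity are out of scope.
* The synthetic generator's noise is white in space and time; estimator
  performance on real, spatially and temporally correlated noise will be
  less favorable than the synthetic benchmarks suggest.
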