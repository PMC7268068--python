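# Methods

`fearpattern` simulates and analyses a discriminative fear-conditioning fMRI
experiment end to end.  This note describes the generative model, the
analysis procedure, the numerical choices, and what the simulations can and
cannot establish about real data.

## The experimental design

The task crosses stimulus (the two members of a sound pair, S1/S2),
complexity (simple monophones vs. complex triads) and context (reinforcement
vs. instructed nonreinforcement) within subjects.  In the reinforcement
context S2 is the CS+ (followed by an aversive electric US on half of its
presentations) and S1 the CS−; in the nonreinforcement context the
physically analogous pair are the neutral sounds NS1/NS2.  The generator
produces 8 blocks of 24 trials in alternating contexts; within each block the
first 12 trials are one complexity and the last 12 the other, with the two
pair members appearing 6 times each in a seeded random permutation.  Sounds
last 4 s; inter-trial intervals are drawn uniformly from {7, 9, 11} s.  Each
of the 8 stimuli therefore appears 24 times, and 12 of the 24 CS+ per
complexity are reinforced.

Counterbalancing flags (`start_context`, `simple_first`, CS/NS octave
assignment analogues) are configuration options rather than group-level
balancing machinery.  The trial order is one fixed seeded permutation shared
by all simulated participants, as in a design optimised once and reused;
reinforcement positions are redrawn per participant (which positions were
reinforced is not constrained by the design, so the seeded-random choice is
the natural one).  Sequence optimisation for design-matrix efficiency is not
implemented; the decoding pipeline does not depend on it.  Onset bookkeeping
is cumulative (onset(k+1) = onset(k) + duration + ITI), with an optional
`block_gap` (default 0 in simulation).

## Generative voxel-pattern model

Each sound pair (context × complexity) is separated by a *stimulus contrast*
vector whose norm is `stimulus_amp` (scaled by `complex_attenuation` for
triads); the mean pattern of S1/S2 is the baseline −/+ half that contrast.
The CS pair additionally carries a *threat contrast* of norm `threat_amp`,
the model's stand-in for an acquired representation of the CS–US
association.  Contrast vectors are independent Gaussian directions
(`gaussian_random`) or mutually orthogonal (`orthogonal` mode, QR of a seeded
Gaussian matrix).  Trial patterns are the condition mean plus i.i.d. Gaussian
noise of standard deviation `noise_sd` per trial and voxel.

Two structural consequences drive all calibration tests:

* with `threat_amp = 0` the CS and NS pairs are exchangeable — every pair is
  separated by exactly `stimulus_amp`, so any CS-vs-NS difference in excess
  accuracy is a false positive of the pipeline;
* with `stimulus_amp = 0` as well, the data are pure noise and any non-zero
  group-mean excess accuracy reflects bias.

Defaults (units are arbitrary pattern amplitude against `noise_sd = 1`):
`stimulus_amp = 1.0`, `complex_attenuation = 0.6` (so simple pairs decode
better than complex pairs, the qualitative complexity effect),
`threat_amp = 1.2`.  The threat amplitude was fixed by an a-priori power
analysis: at the reference sample size of 20 participants the context effect
(CS pairs decode better than NS pairs) should be detected essentially always,
mirroring a study powered for that effect; 1.2 gives ~100% detection at
n = 20 (0.8 gives only ~64%).  The resulting group CS-minus-NS excess
difference is ≈ 8 accuracy points.  `threat_shared` controls whether simple
and complex sounds share one threat contrast (cross-decodable) or carry
independent ones (default: independent, i.e. no stimulus-invariant threat
code).

"Hemispheres" are two independent voxel sets with shared parameters — the
minimal choice that makes hemisphere a null factor.  Voxel coordinates
default to a compact cuboid on a 1.5 mm isotropic grid.

Time-series mode renders the trial amplitudes through the HRF at TR 2.5 s
(`simulate_timeseries`), with optional white or AR(1) scan noise, sinusoidal
drift, and US-evoked responses; the GLM stage then re-estimates the
amplitudes.  The generator does not model hemodynamic nonlinearity, motion,
physiological noise, or tonotopy: passing tests establish the statistical
logic of the pipeline, not robustness to those real-data features.

## Beta-series GLM

One HRF-convolved unit stick per trial, one regressor per run collecting the
US events (runs default to consecutive block pairs; a run without US events
contributes no column), and a discrete-cosine drift set implementing the
high-pass filter (cutoff 128 s; the number of non-constant columns is
floor(2·duration/cutoff)).  The HRF is the standard double gamma (response
delay 6 s, undershoot delay 16 s, unit dispersions, undershoot ratio 1/6,
32 s support), normalised to unit peak; convolution runs on a microtime grid
of TR/16 and is sampled at scan onsets.  Estimation is ordinary least squares
per voxel via the pseudoinverse; rank deficiency falls back to the
minimum-norm solution with a logged warning.  Reinforced-trial betas are
estimated but excluded from all decoding.  Motion regressors, autocorrelation
whitening and regularised single-trial variants are out of scope.

## Decoding

Per participant and hemisphere: discard reinforced trials, z-score every
voxel across the retained trials of the whole experiment (z-scoring over
retained trials only, since reinforced-trial estimates are never analysed),
then decode S1 vs S2 within each context × complexity cell with a
linear-kernel SVM (C = 1, no class weighting — the field-standard minimal
choice).  Folds follow the running-index rule: the i-th chronological
occurrence of each stimulus enters the test set of fold i mod 3, spreading
training and test over the experiment.  The retained reinforcement-context
cell has 24 CS− and 12 CS+, so each fold trains on 24 trials (16 CS−, 8 CS+)
and tests on 12 (8 CS−, 4 CS+).

Because of this imbalance the classifier's chance level is well above 1/2
(≈ 56% at the default conditions), so chance is estimated empirically:
labels are permuted over the retained trials (multiset preserved), folds are
recomputed by the same running-index rule, and the procedure is re-run —
1000 permutations by default.  The reported quantity is *excess accuracy*,
raw minus permutation mean.  NS cells have 48 trials and no discards; to
mirror the CS analysis, one of NS1/NS2 is chosen at random and 12 of its
trials dropped before decoding, averaging both the raw accuracy and each
permutation value over repetitions of this subsampling (100 by default), so
raw and chance are computed over identically distributed trial sets.

Cross-decoding trains on all 36 retained CS trials of one complexity and
tests on the other (both directions, no folds); the NS control labels trials
by the required key press, matched across complexity, and subsamples both
sets to the CS-like counts.  Its chance level permutes the training-set and
test-set label vectors independently (each multiset preserved) and evaluates
against the permuted test labels — the closest analogue of the
within-condition procedure for a train/test split.

Prediction ties (decision value exactly 0) go to the training-majority
class, deterministically.

### Numerical determinism of the SVM

Two engines produce identical decision values: a direct call into the libsvm
solver bundled with scikit-learn (default; ~25× faster for the many small
fits this pipeline runs) and the public `sklearn.svm.SVC` wrapper.  Training
rows are put into a canonical order (label, then feature values) before every
fit.  This matters: libsvm terminates at a finite tolerance, so its solution
depends weakly on row order, and that dependence is systematically different
for design-ordered true labels than for uniformly permuted labels.  Without
canonicalisation this produces a small but measurable bias (~0.2 accuracy
points) in excess accuracy under the null; with it, the classifier is a
function of the training multiset only and the raw-vs-permuted symmetry is
exact.

## Searchlight

A sphere of radius 5 mm (a "10 mm diameter" light, boundary inclusive) at
1.5 mm spacing contains 171 voxel offsets.  Every in-mask voxel is a centre;
the sphere ∩ mask voxels form the feature set for the identical decoding
procedure, including a per-centre permutation chance (default 100
permutations, reduced relative to the ROI analysis for tractability).  A
centre with fewer than `min_voxels` (default 1) neighbours is skipped; an
isolated centre decodes on its own voxel.  An optional mask-normalised
Gaussian smoothing (e.g. 8 mm FWHM) is provided for group-level display;
random-field inference is out of scope.

Localisation is only well-posed when the per-voxel signal is strong enough
for the classifier at the given trial count: a contrast of norm 4 spread
over 81 voxels (per-voxel d′ ≈ 0.35) is essentially invisible to an SVM
trained on 24 trials, while the acceptance simulation implants per-voxel
d′ ≈ 0.8 and localises cleanly.

## Group inference

Excess accuracies form a balanced participant × context × complexity ×
hemisphere table.  The default factorial model is the classical
repeated-measures ANOVA (each effect tested against its effect-by-subject
stratum, denominator df = n−1).  A pooled-error variant — OLS with
participant intercepts, all effects against one pooled residual — is also
provided; on balanced tables it reproduces the Wald F of a sum-coded
random-intercept mixed model essentially exactly (REML variance components
equal the ANOVA estimators under balance), which is the correspondence the
package's equivalence test pins down.  At n = 20 the pooled denominator df
is 133.  The stratified and pooled F generally differ (different error
strata); the stratified form is the default because its small-sample
calibration does not rest on pooling homogeneity.  Unbalanced tables are
rejected with a pointer to `mixed_effects_model`, which handles them.
Satterthwaite degrees of freedom are not reimplemented — the pipeline
guarantees balance, under which the RM-ANOVA df are exact.

Cross-decoding inference uses stimulus class (CS vs response-matched NS) ×
direction, on hemisphere-averaged cells.  Post hoc paired comparisons use
the Wilcoxon signed-rank test: exact null distribution for n ≤ 25 without
zeros or ties, normal approximation otherwise; an all-zero difference vector
returns p = 1 with a warning.

## Seeding and reproducibility

A master seed is expanded through `numpy.random.SeedSequence`: participant p
receives child p, whose grandchildren seed the stages (reinforcement
assignment, per-hemisphere basis and noise, decoding, cross-decoding) in a
fixed order.  Any stage can be reproduced in isolation; identical
configuration and seed yield byte-identical result tables.

## Problem sizes used by the test suite and acceptance script

Simulations are scaled to desk size by reducing voxel counts, permutation
counts and group sizes, never by changing the design counts: the null
calibration uses 2000 groups of 6 participants (12 voxels/hemisphere, 8
permutations, 1 subsample repetition); signal recovery uses 30 groups of 20
participants; the acceptance script's headline group is 12 participants at
60 voxels, 200 permutations and 10 subsample repetitions.  Permutation and
subsampling counts are unbiased at any size — reducing them widens the
noise on each cell's chance estimate without shifting it, which the
calibration tests confirm.

## Known limitations

* The noise model is i.i.d. Gaussian (optionally AR(1) in time); real BOLD
  noise is structured, so absolute accuracy levels are not predictions.
* The empirical chance level and its spread depend on the data: the
  simulation reproduces the qualitative imbalance effect (chance ≈ 56%, far
  from 50%) but cell-to-cell chance variability is far smaller than in
  heterogeneous real data.
* Hemisphere is simulated as a null factor; the pipeline can detect
  hemisphere effects but the generator never produces one.
* Real-data mode (NIfTI betas + mask + events TSV) exercises the same code
  paths but has only been validated on synthetic volumes.
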