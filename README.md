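# fearpattern

Simulation and multivoxel decoding pipeline for discriminative
fear-conditioning fMRI experiments.

## The problem

In discriminative fear conditioning, one sound (CS+) is partially paired
with an aversive stimulus (US) while a similar sound (CS−) is not; a second,
instructed-safe context presents a physically analogous neutral pair
(NS1/NS2).  The scientific question is whether early sensory cortex encodes
the learned CS–US association itself — over and above the physical stimulus
difference.  The analysis operationalises this as a contrast of decodability:
if trial-wise BOLD patterns discriminate CS+/CS− *better* than NS1/NS2,
under identical task demands and comparable physical differences, the extra
discriminability reflects the threat association.

Getting this right requires some statistical care, which is what this
package implements as a reusable, tested pipeline:

* **Beta series.** Trial-wise response amplitudes `β` are estimated from a
  GLM with one HRF-convolved stick regressor per trial, a per-run US
  regressor, and a discrete-cosine high-pass set:
  `Y = Xβ + ε`, solved per voxel by OLS.
* **Imbalanced cross-validation.** Reinforced CS+ trials are discarded
  (US-contaminated), leaving 24 CS− vs 12 CS+.  A running index over each
  stimulus sends every third occurrence to the test set, so each of 3 folds
  trains on 24 trials and tests on 12, spanning the whole session.
* **Permutation chance.** With 2:1 training imbalance a linear SVM's chance
  level is well above 1/2, so a binomial test is invalid.  Chance is the
  mean accuracy over label permutations (folds recomputed per permutation),
  and the reported statistic is the **excess accuracy**
  `acc(true labels) − mean(acc(permuted labels))`.
* **NS matching.** Neutral-sound cells are randomly subsampled to the same
  {24, 12} class counts, averaging over repetitions.
* **Cross-decoding.** Train on all CS of one complexity (monophones or
  triads), test on the other, to probe stimulus-invariant threat codes; the
  NS control matches labels by the required key press.
* **Searchlight.** The same decoder inside a 10 mm diameter sphere at every
  grid voxel maps local association information.
* **Group inference.** Excess accuracies enter a context × complexity ×
  hemisphere repeated-measures model, with Wilcoxon signed-rank post hocs.

A synthetic-data generator with known ground truth (physical stimulus
contrasts for every pair; a threat contrast only for the CS pair) makes every
stage testable: null conditions are exchangeable by construction, and signal
conditions have known recoverable structure.  Real per-trial beta images
(NIfTI) with a mask and a BIDS-style events TSV run through the same entry
points.

## A worked example

```python
from fearpattern import (DesignParams, SynthParams, assign_reinforcement,
                         decode_participant, generate_design,
                         make_pattern_basis, simulate_betas)

design = assign_reinforcement(generate_design(DesignParams(seed=0)), seed=1)
params = SynthParams(n_voxels=60, seed=2)
betas = simulate_betas(design, make_pattern_basis(params), params, rng=3,
                       participant="sub-01", hemisphere="left")
print(decode_participant(betas, n_perm=200, n_subsample_reps=10, rng=4).round(3))
```

prints

```
participant hemisphere          context complexity  raw_accuracy  chance_mean  chance_sd  excess_accuracy
     sub-01       left    reinforcement     simple         0.750        0.560      0.096            0.190
     sub-01       left    reinforcement    complex         0.583        0.554      0.098            0.029
     sub-01       left nonreinforcement     simple         0.547        0.562      0.029           -0.015
     sub-01       left nonreinforcement    complex         0.558        0.559      0.030           -0.001
```

Read this as: the permutation chance sits near 0.56 (not 0.50 — the price of
the 2:1 class imbalance), and only the CS pairs, which carry the simulated
threat association, decode clearly above it.  `run_pipeline(RunConfig(...))`
scales this to a group, adds cross-decoding, and fits the factorial model;
see `examples/` for one short script per capability (design generation,
decoding, the GLM round trip, searchlight mapping, group inference) and
`docs/methods.md` for the model and all numerical choices.

A thin CLI wraps the same functions:
`fearpattern run-all --config config.yaml --seed 1 --out results/`.

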