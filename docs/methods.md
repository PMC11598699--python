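# Methods

This note documents the models, the synthetic data generator, the
evaluation protocols and the numerical choices behind `neurofp`, and what
the test suite does and does not establish.

## Fingerprints

A run is a `T × P` ROI time-series matrix sampled every `tr_s` seconds
(default 1.4 s; the sampling interval only enters through the conversion
`n_samples = floor(seconds / tr_s)` applied to all segment lengths). The
pipeline is:

1. **Bandpass** the full run to 0.01–0.1 Hz with a 4th-order Butterworth
   filter applied forward and backward (zero phase). The filter design is
   a standard choice for resting-state band-limiting; zero phase avoids
   introducing lag structure into the correlations. Filtering happens once
   per run, *before* cropping, so short segments do not inherit filter
   edge transients.
2. **Crop** (training only): a contiguous segment of the requested length
   with a uniformly random start index. No padding — a segment longer than
   the run is an error.
3. **Pearson correlation** across channels, then **vectorization** of the
   strict upper triangle in row-major order (length `P(P−1)/2`; 741 for
   `P = 39`). The ordering convention is internal — every comparison in
   the package uses the same one.

Pearson correlation is invariant to per-channel affine maps, so z-scoring
never changes a fingerprint; the test suite asserts this at `1e-10`. The
`zscore` operation exists for numerical hygiene and data export, and
fingerprints may be computed on raw cropped segments without loss.
Constant channels make the correlation undefined and raise errors naming
the channel rather than propagating NaNs.

## Models

Both deep models share a feed-forward backbone: input → 512 → 256, each
hidden layer followed by batch normalization and ReLU (batch-norm before
the nonlinearity; the activation is ReLU — standard for this family of
fingerprinting networks). The stack is implemented in numpy inside the
package (`neurofp.nn`): the networks are small enough that explicit
forward/backward passes train in seconds on one CPU, and the
implementation is exactly reproducible under a seed.

- **DLM-CE**: linear head with one logit per training subject, softmax,
  categorical cross-entropy. (A "binary cross-entropy over softmax
  outputs" variant is available via `ModelConfig.binary_ce` for strict
  comparability with formulations phrased that way; with one-hot targets
  the two differ only in the non-target terms.)
- **DLM-TL**: the 256-unit backbone output is L2-normalized directly — no
  extra projection layer — and trained with the summed hinge triplet loss
  over mined triplets. Mining is semi-hard: for each ordered same-subject
  pair `(a, p)` the closest negative strictly farther than the positive is
  selected (a semi-hard pick when it also lies inside the margin band
  `d_ap < d_an < d_ap + α`); when no negative is farther than the
  positive, the hardest negative overall is used as a fallback. Batches
  keep all of a subject's instances together so every anchor has a
  positive.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999) at learning rate 1e-3,
50 epochs, batch size 276 by default. Each epoch draws
`crops_per_epoch = 4` fresh random crops of every training run
(crop → FC inside the input pipeline), so augmentation is re-randomized
at every gradient step. Evaluation uses full-length fingerprints.
When validation runs are supplied to the triplet trainer, a full-length
validation triplet loss is tracked per epoch and the best epoch's weights
are restored.

Parameters that matter, with defaults:

| parameter | default | role |
|---|---|---|
| `margin_alpha` | 0.2 | triplet margin on squared distances |
| `segment_length_s` | `"full"` | augmentation crop length (seconds) |
| `epochs` / `crops_per_epoch` | 50 / 4 | gradient steps = epochs × crops × batches |
| `learning_rate` | 1e-3 | Adam step size |
| `batch_size` | 276 | per-step sample count (full cohort batch at 138×2) |

The margin default follows the convention of the metric-learning
literature. Note that with unit-norm embeddings squared distances live in
`[0, 4]`, and on noisy cohorts identification is measurably sensitive to
the margin (larger margins such as 1.0 keep more triplets active and can
substantially improve accuracy); `margin_alpha` is the first knob to tune
on hard data.

## Identification rules

- **Correlation baseline**: query FC vector vs. every target-session
  vector; predicted subject = argmax |r| (a `signed` flag uses raw r).
  Exact score ties — a measure-zero event in floating point — are broken
  deterministically by sorted (subject, run) order with a warning.
  "All possible comparisons" defaults to all ordered pairs of distinct
  single sessions (12 for 4 runs); a multi-target mode pools all other
  sessions as targets instead. Both modes are provided because either
  reading of "one or more target sessions" is defensible.
- **Embedding identification**: an anchor succeeds when its minimum
  squared distance to a positive (another run of the same subject) is
  smaller than to every negative. The predicted label for the macro
  precision/recall/F1 is the subject of the global nearest neighbour.
  Chance level is per-anchor `n_positives / n_candidates` and varies with
  the evaluation-set size, so tests compare against binomial quantiles of
  that rate rather than a fixed constant.

## Evaluation protocols

- **LRO** (leave-run-out): train on half of each subject's runs, test on
  the rest; all `C(4,2) = 6` combinations × 10 repetitions = 60 runs by
  default.
- **LSO** (leave-subject-out): shuffled k-fold over subjects (6 folds of
  23 at 138 subjects, i.e. 115 train / 23 test), repeated; only the
  triplet model supports this regime. Every held-out subject needs at
  least two runs for the identification rule to apply.
- **Permutation t-test**: two-sided, pooled-variance t statistic, null
  built by reassigning the pooled values to groups of the original sizes.
  Exhaustive enumeration is used automatically when the number of distinct
  assignments is at most `n_perm` (p = exceedance fraction); otherwise
  `n_perm` random reassignments with the add-one convention
  `p = (1 + #exceed)/(1 + n_perm)`, which cannot return zero. An unpaired
  test is the default; a paired sign-flip mode exists because replicates
  of two methods often share fold structure. With few replicates the
  smallest attainable p is bounded below (2/20 at 3 + 3 values), which the
  acceptance script's output reflects.
- **Sweeps**: segment length (accuracy vs. crop length, with per-length
  permutation tests of each triplet variant against LRO cross-entropy),
  split ratio (19 training fractions from 5% to 95%), and dataset size
  (train count shrunk by 10% per step from 92/46 down to 8/4 at a fixed
  2:1 ratio; "10% increments" is implemented as multiply-by-0.9-and-round,
  with the grid echoed in the result). Every sweep records per-replicate
  accuracies so mean ± sd are independently recomputable.
- **UMAP**: 2-D projection of embeddings with n_neighbors = 15, euclidean
  metric, learning rate 1, seeded.

## Synthetic cohorts

The generator emulates a multi-subject resting-state cohort — by default
4 runs per subject, 39 ROIs, 15-minute runs — with identity planted in the
covariance, the property all three identification methods rely on.
Subject correlation matrices come from the factor model
`C_s = B0·B0ᵀ + δ²·Bs·Bsᵀ + ε₀·I` (shared loading `B0`, subject loading
`Bs`, diagonal ridge ε₀ > 0 guaranteeing positive-definiteness cheaply),
normalized to correlation form. Each run adds a run-specific factor term
`ρ²·Cr·Crᵀ` before renormalizing, draws i.i.d. Gaussian samples with the
resulting correlation, and applies a variance-preserving channelwise AR(1)
recursion (φ = 0.4) to give the series low-frequency content; identical
AR weights across channels leave the cross-channel correlation intact, so
the run-level target remains the ground truth.

Defaults δ = 1.0, ρ = 0.3 put the correlation baseline in the
0.85–1.0 accuracy range on 20-subject cohorts across seeds — identifiable
but not saturated. The test suite also uses a well-separated cohort
(δ = 2.0, ρ = 0.05) where identity recovery should be near-perfect, and
the noisy default cohort at 300-s runs where the augmentation effect is
visible. Separation is monotone: baseline accuracy rises with δ and falls
with ρ (asserted over seeds).

What the generator does **not** emulate: BOLD spectral shape, scanner
artifacts, motion, physiological noise, or hemodynamic responses. Samples
are Gaussian — Pearson FC is distribution-light, and the bandpass stage is
still exercised, but passing tests demonstrate correctness of the methods
under the stated covariance model, not performance on real fMRI. Absolute
accuracies on synthetic cohorts are not comparable to values measured on
real data; only the qualitative orderings (augmentation helps, deep models
beat the baseline when trained with augmentation, metric learning
transfers to unseen subjects) are expected to carry over.

## Problem sizes

The suite and the acceptance script run at desk scale: 20–30 subjects,
300-s runs, 50 epochs, 3–5 replicates per condition — sizes chosen so the
full study re-runs in minutes on one CPU while keeping every protocol
(fold structure, augmentation, mining, permutation testing) identical to
the full-scale setting. The structural counts of the full-scale protocols
(60 LRO runs, 741 edges, 115/23 LSO folds, 19 split ratios, the 92/46 →
8/4 size grid) are asserted directly on the split/grid constructors, which
are pure functions of the cohort dimensions.

## Numerical choices and edge cases

- Correlations are clipped to [−1, 1] and symmetrized after `corrcoef` to
  absorb floating-point overshoot; diagonals are set to exactly 1.
- A fully-rectified (all-zero) encoder output has no direction; `encode`
  maps it to a fixed point on the unit sphere instead of dividing by ~0.
- Zero-variance channels and vectors raise errors naming the offender.
- Determinism: a cohort is a pure function of its config (per-run streams
  are derived from the seed and the subject/run labels, independent of
  call order); training is reproducible given the config seed (weights)
  and the generator passed in (crops, batching, mining) on fixed hardware.
- Report files store per-query records as CSV with summary statistics in
  schema-tagged header comments; a stored accuracy that disagrees with
  its own records fails loading.

## Known limitations

- The triplet model's accuracy on hard cohorts is margin-sensitive (see
  above) and semi-hard mining with a hardest-negative fallback can
  stall on very noisy data — both are documented behaviours of this loss
  family, not bugs; the margin is exposed for tuning.
- LRO evaluation of the cross-entropy model scores test runs through the
  class head, so it cannot rank subjects absent from training; only the
  triplet model is evaluated under LSO.
- Cross-hardware bit-identity of trained weights is not promised (BLAS
  reduction order); same-machine runs with the same seeds are identical.
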