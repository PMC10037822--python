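# Methods

## Problem

Given two co-administered drugs, predict which of a fixed set of
interaction *event types* their combination produces (e.g. "the
metabolism of drug A is decreased").  Each drug is described by three
sets of binary descriptor tokens — chemical substructures, protein
targets and metabolizing enzymes — and the task is a single-label
multiclass classification over drug pairs.  The reference benchmark
(572 drugs, 65 event types, 37,264 known interactions listed in both
drug orders for 74,528 directed pairs) is heavily imbalanced: the top
three events cover roughly two-thirds of all samples.

## Feature construction

One-hot descriptor vectors are sparse and high-dimensional, so each
drug is instead represented by its *similarity profile*: for every
modality `m` and every roster drug `j`, the Jaccard similarity

    J(A, B) = |A ∩ B| / (|A| + |B| − |A ∩ B|)

between the drug's token set and drug `j`'s.  Stacking the three
modalities gives an `n_drugs × 3` matrix per drug; a pair input is the
ordered stack of two such matrices (`2 × n_drugs × 3`; `2 × 572 × 3`
on the reference roster).

Conventions:

- `J(∅, ∅) := 1` — two drugs unannotated in a modality are treated as
  indistinguishable there, avoiding 0/0.  A warning is emitted the
  first time this triggers.
- Roster order and vocabularies are canonical (lexicographic), so
  feature matrices are bit-reproducible across machines.
- A drug's own similarity column is kept (self-similarity 1).
- Featurization is transductive: a query drug not on the training
  roster is still represented by its similarities *to* the roster.

## Architecture

Two weight-sharing CNN branches (a Siamese twin) encode the two drugs;
their embeddings are fused by element-wise addition and classified by
an MLP.  Additive fusion plus full weight sharing makes the network
exactly symmetric in drug order at evaluation time; this is tested to
machine tolerance.

Backbone (per branch): five 1-D convolutions along the profile axis
with the 3 modalities as input channels of layer 1; channel counts
64/128/128/128/256; kernel length 3, stride 1, zero "same" padding
(length preservation is what makes the residual addition type-check);
rectifier activations after layers 1–4.  The rectified output of layer
2 is added to the rectified output of layer 4 (residual connection:
layers 3–4 learn a correction term `y = σ(f(x)) + x`), which requires
equal channel counts at layers 2 and 4 — validated at construction.
Layer 5 is followed by batch normalization (batch statistics during
training, running averages with momentum 0.1 and ε = 1e-5 in
evaluation) and pooling.

Pooling is `global_average` by default, mapping `256 × n_drugs` to a
length-256 embedding and keeping the head roster-size-agnostic; a
`flatten` mode is provided for parity with head widths quoted for
flattened inputs.  Head: two rectified hidden layers of widths 2048
and 256, then a linear layer over `n_classes` (65 by default) with a
softmax readout.  No dropout and no inter-layer pooling are used.

Parameters are initialized with fan-in-scaled uniform draws
(`U(±sqrt(1/fan_in))`), zero biases, from a seeded generator.  The two
branches run as one concatenated batch through a single parameter set,
so batch-norm statistics are shared and order-invariant, and gradient
accumulation across branches falls out of the concatenation.

All layers (convolution via im2col, batch norm, linear, rectifier,
pooling) are implemented directly on NumPy arrays with explicit
backward passes; gradients are verified against central finite
differences in the test suite.

## Loss, augmentation, optimization

**Focal loss.**  `FL(p_t) = −(1 − p_t)^γ log(p_t)` with γ = 2,
generalized to soft targets as `−Σ_c t_c (1 − p_c)^γ log p_c` so that
mixed labels remain meaningful; γ = 0 recovers cross-entropy exactly
(asserted to 1e-12).  Probabilities are clipped at 1e-12 before the
logarithm.  The down-weighting of well-classified samples is what
makes the extreme event imbalance tractable.

**Mixup.**  Each mini-batch is convexly combined with a permuted
counterpart batch from the same training fold (resampled every epoch),
inputs and one-hot labels alike, with a single coefficient
λ ~ Beta(0.5, 0.5) per batch (per-sample mode available).  The
symmetric Beta(0.5, 0.5) has mean 0.5, balancing the two streams in
expectation.

**RAdam.**  Adam moments (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with the
variance-rectification rule: the approximated SMA length
`ρ_t = ρ_∞ − 2 t β₂ᵗ/(1 − β₂ᵗ)` gates the update — adaptive with
rectification factor `r_t` when `ρ_t > 4`, plain momentum otherwise
(the first four steps at β₂ = 0.999).  The implementation is checked
against an independently transcribed scalar reference to 1e-10 over
100 steps.

**LookAhead.**  Slow weights are interpolated toward the fast weights
every k = 5 inner steps with factor 0.5, and the fast weights reset to
them.  Validation and inference use the slow weights — the stabilized
set, which is also the set the wrapper's own evaluation protocol uses.

**Cross-validation.**  Stratified-by-event K-fold (K = 5).  Events
with fewer samples than K cannot appear in every fold and are kept in
the training split of each fold, with a warning.  Fold scores are
averaged arithmetically into the final report.  Learning rate (1e-3
default), batch size (256 default) and epoch count (100 default) are
exposed in `TrainConfig`.

## Evaluation

Accuracy from argmax predictions, plus micro-averaged AUPR, AUC,
precision, recall and F1: the one-vs-rest binarized label matrix is
flattened against the flattened score matrix into one binary problem.
AUPR uses the average-precision (step-interpolated) estimator; AUC
resolves ties by average rank.  For single-label multiclass
predictions micro precision = recall = F1 = accuracy, an algebraic
identity used as an internal consistency check.  A per-event table
reports the six one-vs-rest metrics and their mean per event; events
absent from the truth vector are flagged undefined, and the ranking
areas are reported as missing (with a warning) when the truth vector
is single-class.

## Synthetic benchmark

The generator plants a recoverable signal with the benchmark's
qualitative statistics, so that the full pipeline is testable without
any download:

- Drugs belong to latent clusters; each cluster owns a *disjoint* core
  token set per modality (12 tokens by default) and each drug adds a
  few drug-specific tokens (4 by default) from the remaining
  vocabulary.  Within-cluster similarity therefore exceeds
  between-cluster similarity in expectation.
- The event of a pair is a deterministic function of the *unordered*
  cluster pair (respecting the symmetry of interaction labels), built
  once per seed: cluster pairs, sorted by realized pair count, are
  allocated to events so realized event masses track a power law with
  exponent 1.2 — chosen so the top three of ten events carry ≈ two
  thirds of the samples, mirroring the benchmark skew.  A configurable
  fraction of labels can then be randomized (`noise_rate`, 0 by
  default).
- Each unordered pair is emitted in both orders with the same label.

Default size: 60 drugs, vocabularies 200/150/80, 6 clusters, 10
events, all 1,770 unordered pairs (3,540 directed samples).  A
nearest-centroid oracle that knows the cluster-pair groups reaches
accuracy 1.0 on the noise-free default — an upper bound a trained
network should approach but not, in expectation, exceed.

What the generator does *not* emulate: real chemistry (tokens are
abstract), correlated modalities, annotation sparsity patterns, or
label noise structure of curated databases.  Passing tests demonstrate
that the pipeline recovers a planted, learnable signal under the
published training protocol — not benchmark-level performance on real
data, which requires the external dataset and long training.

## Problem sizes and numerical choices

- The end-to-end recovery check trains 5 folds on the default
  synthetic fixture with a reduced-width model (channels 8/16/16/16/32,
  MLP 64/32), 60 epochs, batch 64, learning rate 2e-3 — widths scaled
  to the 60-drug fixture while keeping the published depth, residual
  topology, loss, augmentation and optimizer stack unchanged.
- Probabilities are clipped at 1e-12 before logarithms; softmax is
  max-shifted; batch norm uses ε = 1e-5.
- Determinism: every stochastic component (initialization, shuffling,
  mixup draws, fold splits) flows from explicit seeds; repeated runs
  with the same seed produce identical metrics on a fixed BLAS
  configuration.

## Known limitations

- Training is CPU-bound NumPy; the full 572-drug benchmark is
  supported by the loaders and CLI but takes hours, so published
  headline scores are not recomputed here.
- The checkpoint format stores the roster drug-id order but not the
  descriptor sets; featurizing new queries requires the descriptor
  file used at training time.
- Batch-norm running statistics make training-mode forward passes
  stateful; only evaluation mode is guaranteed order-invariant to
  machine precision.
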