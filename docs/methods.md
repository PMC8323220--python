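# Methods

## Problem and model

`critens` classifies short, unsegmented text (the motivating case is
clinical-trial eligibility-criteria sentences, written in Chinese and
annotated into several dozen categories) under severe class imbalance.
The classifier is a soft-voting ensemble of K character-level
convolutional models. Each single model is:

1. **Input layer.** Characters are mapped to ids over a vocabulary built
   from the training split (reserved ids: PAD = 0, UNK = 1) and looked up
   in a trainable embedding table. Each ensemble member owns an
   independently seeded table — this is the ensemble's diversity
   mechanism, standing in for a bank of heterogeneous pre-trained
   encoders. The contract (text → L × dim real matrix) admits external
   encoders, but none is required.
2. **Sequence-modeling layer.** One 1-D convolution per kernel width
   w ∈ {3, 4, 5}, a rectifier, and a max-pool per filter over the windows
   that overlap at least one real (non-PAD) position. The pooled outputs
   concatenate into the feature representation r, of dimension
   d = 3 × filters per width. r is simultaneously the classifier input
   and the representation the metric loss acts on.
3. **Output layer.** A linear map to class scores x = W r + b and a
   softmax p = softmax(x).

## Objective

With D(r_i, r_j) = (1/d)‖r_i − r_j‖²₂ the dimension-normalized squared
Euclidean distance, and S_k the set of batch members of class k:

- intra-class loss: the mean of D over all unordered same-class pairs,
  `L_intra(k) = 2/(|S_k|² − |S_k|) Σ_{i<j} D(r_i, r_j)`;
- inter-class loss: the mean hinge over cross-class pairs,
  `L_inter(p, q) = 1/(|S_p||S_q|) Σ max(0, m − D(r_i, r_j))`;
- metric loss: `L_metric = Σ_k { L_intra(k) + λ Σ_{i≠k} L_inter(k, i) }`.
  The inner sum visits each unordered class pair twice; it is computed
  exactly as written (no halving) — λ absorbs the constant;
- focal loss on the true-class probability p_t:
  `FL = −(1 − p_t)^γ log p_t`, batch-averaged; γ = 0 recovers
  cross-entropy;
- combined objective: `L = FL + μ · L_metric`.

Defaults: γ = 2, λ = 0.1, μ = 1, margin m = 0.1. The metric loss is
computed within each mini-batch over the classes present there; the
full-corpus pairwise sum would be quadratic in corpus size, and batch
scope is standard metric-learning practice. Classes with fewer than two
batch members contribute zero intra-class loss (the pair mean is undefined
there); empty classes contribute zero inter-class loss. Probabilities are
clamped to [1e-12, 1] inside logarithms; natural log throughout.

All gradients are derived by hand (the package trains with NumPy, no
autograd) and are validated against central finite differences in the
test suite to relative 1e-3 per sampled coordinate.

## Ensembling and evaluation

Members are combined by equal-weight soft voting: the prediction is the
argmax of the member-mean probability vector, ties to the lowest class
index. Evaluation uses one-vs-rest confusion tallies per class: accuracy
(fraction correct), macro precision, macro recall, and macro F1 (the
unweighted mean of per-class 2PR/(P+R)); a class with a zero denominator
scores 0 for that quantity. Two classifiers are compared by a paired
two-sided t-test on per-class F1 (identical vectors give t = 0, p = 1;
nonzero constant differences give p = 0 as the degenerate-variance limit).
Reported "precision"/"recall" are macro averages; the per-class table is
always emitted so other conventions can be recomputed.

## Synthetic benchmark

Real eligibility-criteria corpora are not redistributable, so the
generator emulates their structure: `n_classes` categories whose expected
sizes follow a Zipf law (class k ∝ (k+1)^−a), texts that are space-free
concatenations of 3-character pseudo-tokens (mirroring unsegmented
Chinese), drawn from a class-private vocabulary except that each token is
replaced by a shared noise token with probability `noise_rate`. Splits
are stratified per class (classes with < 3 records go entirely to train).
With `noise_rate = 0` the private vocabularies are disjoint and the corpus
is linearly separable — the upper-bound fixture, on which training is
required to reach ≥ 0.95 validation macro F1.

Benchmark defaults (`SyntheticSpec()`): 8 classes, 2000 samples, Zipf
exponent 1.5 (largest class ≈ 1000, smallest ≈ 45), 20 private and 50
shared tokens, noise rate 0.3, token lengths 4–12, splits 60/20/20.

What the generator does **not** emulate: real lexical semantics, synonymy
or polysemy across classes, sentence syntax, label noise, and duplicated
sentences across splits (duplicates are allowed, never deduplicated).
Passing directional tests on this benchmark shows the optimization and
ensembling machinery behaves as designed, not that the method attains any
particular score on real clinical text.

## Training

Adam (β = 0.9/0.999), batch size 128, 12 epochs, seeded shuffling, global
gradient-norm clip at 5.0, weight decay 1e-4 on convolution and classifier
weight matrices. The PAD embedding row is frozen at zero. The returned
checkpoint is the epoch with the best validation macro F1 (earliest wins
ties). Training is bitwise deterministic for fixed inputs and seed on a
fixed platform.

The default learning rate is 3e-3 for the from-scratch character
embeddings: at 1e-3, training on the benchmark had clearly not converged
within the 12-epoch budget (validation macro F1 still rising through
0.43), while at 3e-3 it converges comfortably. Fine-tuning externally
pre-trained encoders conventionally uses 2e-5; that setting is documented
on `TrainConfig` but is not the default.

Desk-scale model size: embedding dim 16, 16 filters per width (d = 48),
L = 64 with left-edge truncation. These sizes keep a full 5-member
benchmark fit around a minute on one CPU while leaving the benchmark
non-trivial.

## Numerical and design choices

- Convolution right-pads each sequence by w − 1 PAD (zero-embedding)
  positions and excludes windows lying entirely over padding from the
  max. This makes r exactly invariant to appending PAD — a tested
  invariant. (Strict valid-window convolution would violate it for texts
  of length within w − 1 of L.)
- ReLU before pooling, the standard multi-width text-convolution design.
- Batches are plain shuffles, not class-balanced: focal loss is the
  imbalance remedy under study.
- Margin m is one value for all members by default but configurable per
  member.
- Labels are strings on disk, dense indices in memory, assigned by
  lexicographic sort of distinct names — reproducible with no side file.

## Known limitations

- On this benchmark the members already reach macro F1 ≈ 0.93–0.97, so
  the metric term has little headroom to improve F1; its reliable,
  strongly confirmed effect here is geometric (mean same-class feature
  distance ≈ 0.014 vs cross-class ≈ 0.18 on the test split). Across
  training seeds the F1 effect of the metric term is mixed — it can
  slow convergence within the 12-epoch budget for some seeds — and the
  suite documents one such directional check failing honestly.
- Single-CPU NumPy training; no GPU path, no learning-rate schedules,
  no early stopping beyond best-epoch selection.
- The t-test pairing unit is per-class F1; with few classes the test has
  low power.
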