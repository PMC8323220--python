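# critens

Ensemble character-level classification of imbalanced short text, built
for the kind of corpus found in clinical-trial eligibility screening:
tens of categories, heavy class imbalance, short unsegmented sentences.

Each of K single models embeds characters with an independently seeded
trainable table, extracts a feature representation r with multi-width
(3/4/5) convolutions and masked max-pooling, and classifies with a linear
softmax head. Training minimizes

    L = FocalLoss + μ · L_metric

where `FocalLoss = −(1 − p_t)^γ log p_t` down-weights easy samples under
class imbalance (γ = 2), and the metric loss shapes the feature space with
the dimension-normalized squared distance D(r_i, r_j) = (1/d)‖r_i − r_j‖²:
same-class pairs are pulled together (mean pairwise D per class) and
cross-class pairs are pushed beyond a margin m via
`max(0, m − D)` (λ = 0.1, m = 0.1, μ = 1). The K softmax outputs are
combined by soft voting — the argmax of their mean — and evaluated with
accuracy, macro precision/recall, and macro F1 from one-vs-rest confusion
counts, plus a paired t-test on per-class F1 for model comparison.

Because real eligibility-criteria corpora are not redistributable, the
package ships a synthetic generator that reproduces their structure:
Zipf-imbalanced class sizes, space-free multi-character pseudo-tokens,
class-indicative vocabularies mixed with shared noise tokens at a
configurable rate. The network and all gradients are implemented in NumPy
and verified against finite differences and brute-force oracles in the
test suite.

## Worked example

```python
import numpy as np
from critens import EnsembleTextModel, SyntheticSpec, generate_synthetic_corpus

records, schema = generate_synthetic_corpus(SyntheticSpec(seed=1))
model = EnsembleTextModel(records, schema, n_members=5)
results = model.fit(seed=1)
print(results.summary())
```

prints

```
Ensemble text classification results
============================================================
categories: 8    members: 5    seed: 1
loss: focal(gamma=2.0) + mu=1.0 * metric(lambda=0.1, m=0.1)
------------------------------------------------------------
model             accuracy   macro P   macro R  macro F1
char-emb-0          0.9749    0.9745    0.9678    0.9703
char-emb-1          0.9875    0.9822    0.9735    0.9771
char-emb-2          0.9875    0.9867    0.9803    0.9827
char-emb-3          0.9674    0.9758    0.9380    0.9549
char-emb-4          0.9925    0.9947    0.9866    0.9902
------------------------------------------------------------
soft-vote           0.9774    0.9841    0.9730    0.9777
macro-F1 gain over member mean: +0.0026
feature distances (test): intra 0.0124 < inter 0.1843
============================================================
```

The members each classify the 399 held-out texts of the 8-class benchmark
with macro F1 0.95–0.99; soft voting edges out the member mean, and the
metric term has clustered the feature space — same-class representations
sit an order of magnitude closer (0.012) than cross-class ones (0.184).

The same pipeline is scriptable from a shell:

```
critens generate --config spec.yaml --out corpus.jsonl
critens train    --config run.yaml  --corpus corpus.jsonl --out m0/
critens ensemble --models m0 m1 m2 m3 m4 --corpus corpus.jsonl --split test --out pred.tsv
critens evaluate --truth corpus.jsonl --split test --pred pred.tsv --out report.json
```

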