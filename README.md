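# ddisiam

Prediction of drug–drug interaction (DDI) *event types* — which of a
fixed catalogue of pharmacological outcomes (e.g. "the metabolism of
drug A is decreased") a drug pair produces — with a Siamese
convolutional network over multimodal similarity-profile features.

**Who it is for.**  Researchers benchmarking multiclass DDI event
prediction who want a transparent, dependency-light, fully seeded
reference implementation: the network, its focal loss, mixup
augmentation and RAdam + LookAhead optimizer stack are implemented
directly on NumPy with explicit, finite-difference-verified backward
passes.

## Model

Each drug is described by three token sets (chemical substructures,
protein targets, metabolizing enzymes).  Its feature representation is
the *similarity profile*: the `n_drugs × 3` matrix of Jaccard
similarities

```
J(A, B) = |A ∩ B| / (|A| + |B| − |A ∩ B|)
```

to every drug on the roster, one column per modality.  A pair input is
the ordered stack `2 × n_drugs × 3`.

Two weight-sharing CNN branches (five 1-D convolutions, channels
64/128/128/128/256, kernel 3, a residual connection from conv layer 2
to the input of conv layer 5, batch normalization, global average
pooling) encode the two drugs; the embeddings are summed and an MLP
head (2048 → 256 → 65) produces class probabilities.  Weight sharing
plus additive fusion makes predictions invariant to drug order.
Training uses the focal loss `FL(p_t) = −(1−p_t)^γ log p_t` (γ = 2)
against the severe event-frequency imbalance, mixup with
λ ~ Beta(0.5, 0.5), rectified Adam wrapped in LookAhead slow weights,
and stratified 5-fold cross-validation scored by accuracy and
micro-averaged AUPR/AUC/precision/recall/F1.

See `docs/methods.md` for assumptions, parameter meanings and
numerical details.

## Worked example

Generate a synthetic benchmark with planted cluster structure (60
drugs, 10 event types, two-thirds of samples in the top three events),
then train and evaluate end to end:

```python
import numpy as np
from ddisiam import (ModelConfig, TrainConfig, SyntheticSpec,
                     generate_dataset, pairs_to_tensors, train_kfold)

spec = SyntheticSpec()                      # 60 drugs, 6 clusters, 10 events
roster, clusters, pairs = generate_dataset(spec)
xa, xb, y = pairs_to_tensors(roster, pairs) # (3540, 60, 3) each

model_cfg = ModelConfig(conv_channels=(8, 16, 16, 16, 32),
                        mlp_hidden=(64, 32), n_classes=10)
train_cfg = TrainConfig(epochs=60, batch_size=64, learning_rate=2e-3,
                        k_folds=5, seed=0)
result = train_kfold(xa, xb, y, model_cfg, train_cfg)
print(result.averaged)
```

which prints (about 6 minutes on one CPU):

```
MetricReport(acc=0.9723, aupr_micro=0.9869, auc_micro=0.9982, precision_micro=0.9723, recall_micro=0.9723, f1_micro=0.9723)
```

Averaged over the 5 validation folds the network recovers 97% of the
pair labels — against a 41% majority-class baseline and a 1.00
nearest-centroid oracle that knows the planted clusters — and the
micro-averaged ranking areas show the probability scores are
well-ordered, not just the argmax.

The same pipeline is available from the shell:

```bash
ddisiam simulate --out-dir fx                 # synthetic descriptors + pairs
ddisiam preprocess fx/descriptors.csv --out-dir profiles
ddisiam train run.yaml                        # checkpoints + fold metrics
ddisiam predict run/fold0.npz fx/pairs.csv fx/descriptors.csv --out preds.csv
```

Loaders for the 572-drug benchmark CSV export (descriptor and pair
tables in the same dialects) are included; reproducing its headline
scores requires downloading that dataset and hours of CPU training,
and is deliberately not part of the test suite.

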