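"""Train the mesh CNN on a synthetic two-class thickness cohort.

The generator plants a 0.4 mm regional mean shift (class 1 only) on a
smooth 2-4 mm baseline with correlated 0.1 mm noise; the network must find
the region from labeled examples. Accuracy near 100% on held-out subjects
shows the conv/pool/classifier pipeline learns the regional signal.
"""

import numpy as np
from sklearn.model_selection import train_test_split

from spherecnn import (
    CohortSpec,
    ModelSpec,
    TrainConfig,
    build_model,
    evaluate,
    generate_cohort,
    train,
)

cohort = generate_cohort(
    CohortSpec(n_per_class=60, level=2, effect_regions=((None, 0.6, 0.4),), seed=7)
)
X, y = cohort.network_inputs(), cohort.y
idx = np.arange(cohort.n_subjects)
tv, te = train_test_split(idx, test_size=24, stratify=y, random_state=0)
tr, va = train_test_split(tv, test_size=24, stratify=y[tv], random_state=0)

spec = ModelSpec(input_level=2, n_complexes=2, filters_per_layer=(8, 8), seed=0)
model = build_model(spec)
print(f"model: {model.n_params} parameters, "
      f"feature maps {model.feature_map_shapes()}")

cfg = TrainConfig(batch_size=24, seed=0, stop_patience=6)
result = train(model, (X[tr], y[tr], X[va], y[va]), cfg)
test_acc, _ = evaluate(model, X[te], y[te])

print(f"epochs run: {len(result.train_err)}, best epoch {result.best_epoch}")
print(f"validation accuracy {result.val_accuracy:.1f}%  "
      f"held-out test accuracy {test_acc:.1f}%")
print("(chance level is 50%; the regional 0.4 mm shift is easily separable)")
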