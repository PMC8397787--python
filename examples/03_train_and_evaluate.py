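"""Train the tiny classifier on synthetic data and evaluate it.

Desk-scale protocol: 64 x 64 inputs, tiny backbone (reduction 16), SGD with
Nesterov momentum, the staged learning-rate schedule, and stochastic
augmentation.  Reports held-out macro metrics and per-class AUC with DeLong
95% confidence intervals.  Takes a few minutes on one CPU.
"""

import numpy as np

import oralscope as osc
from oralscope.model import OralClassifier, make_backbone
from oralscope.samples import DatasetManifest
from oralscope.train import predict_probabilities

SIDE = 64

data = osc.generate_dataset([120] * 5, height=192, width=256, rng_seed=2)
data = osc.split_by_patient(data, test_fraction=0.25, rng_seed=2)

processed = []
for s in data.samples:
    roi = osc.crop_center_roi(s.pixels, osc.RoiConfig(roi_fraction=0.5))
    s.pixels = osc.resize_image(roi, SIDE)
    processed.append(s)
manifest = DatasetManifest(samples=processed, split=dict(data.split))

model = OralClassifier(make_backbone("tiny", rng_seed=0))
cfg = osc.TrainConfig(epochs=30, folds=1, seed=0)
model, history = osc.train_model(manifest.subset("train"), model, cfg, osc.AugmentConfig())
print(f"best val macro-F1 during training: {max(h['val_macro_f1'] for h in history):.3f}")

test = manifest.subset("test")
probs = predict_probabilities(model, [s.pixels for s in test.samples])
labels = np.array([s.label_index for s in test.samples])
cm = osc.confusion_matrix(labels, probs.argmax(axis=1))
mm = osc.macro_metrics(cm)
print(f"held-out: SE={mm.se_macro:.3f} SP={mm.sp_macro:.3f} "
      f"Pr={mm.pr_macro:.3f} F1={mm.f1:.3f}")
for i, cls in enumerate(osc.CLASS_NAMES):
    res = osc.delong_ci(probs, labels, i)
    print(f"  {cls:10s} AUC {res.auc:.3f} (95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
# macro metrics near 1.0 mean the five synthetic signatures are cleanly
# separable at this scale; the AUC intervals narrow as the test set grows.
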