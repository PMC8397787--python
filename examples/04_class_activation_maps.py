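"""Class activation maps: where the classifier looks.

Trains briefly, then computes the predicted class's activation map for a
lesion image (pre-pooling head response, 16x bilinear upsample) and writes
a heatmap overlay.  The raw map's spatial mean equals the class logit — an
exact identity of the global-pooling head, checked below.
"""

import numpy as np

import oralscope as osc
from oralscope.manifest_io import write_image
from oralscope.model import OralClassifier, make_backbone
from oralscope.preprocess import to_model_input
from oralscope.samples import DatasetManifest
from oralscope.visualize import compute_cam, overlay_heatmap

SIDE = 64

data = osc.generate_dataset([40] * 5, height=192, width=256, rng_seed=5)
data = osc.split_by_patient(data, test_fraction=0.25, rng_seed=5)
for s in data.samples:
    s.pixels = osc.resize_image(osc.crop_center_roi(s.pixels, osc.RoiConfig()), SIDE)

model = OralClassifier(make_backbone("tiny", rng_seed=0))
model, _ = osc.train_model(
    data.subset("train"), model, osc.TrainConfig(epochs=10, folds=1, seed=0)
)

sample = next(s for s in data.subset("test").samples if s.label == "cancer")
x = to_model_input(sample.pixels)
probs = model.predict_proba(x[None])[0]
pred = int(probs.argmax())
print(f"true={sample.label} predicted={osc.CLASS_NAMES[pred]} p={probs[pred]:.3f}")

amap = compute_cam(model, x, pred)
logit = model.logits(x[None])[0, pred]
print(f"raw CAM mean {amap.raw_map.mean():+.5f} == class logit {logit:+.5f}")
peak = np.unravel_index(np.argmax(amap.map), amap.map.shape)
print(f"activation peak at {tuple(int(v) for v in peak)} in the 64 x 64 view")

write_image(overlay_heatmap(sample.pixels, amap, alpha=0.4), "cam_overlay.png")
print("overlay written to cam_overlay.png")
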