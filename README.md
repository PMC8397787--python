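# oralscope

A tested, reusable implementation of a smartphone-photograph pipeline for
early oral-cancer screening: five-way classification of oral-cavity images
into **normal**, **aphthous ulcer**, **low-risk OPMD**, **high-risk OPMD**
(OPMD = oral potentially malignant disorder) and **cancer**.

It is written for researchers who want to study the *method* — the centered
capture rule, the resampling scheme, the global-pooling classification head,
and the evaluation machinery — without access to clinical photographs: a
synthetic oral-image generator emulates the dataset's statistical and
geometric structure, so every stage is exercised end-to-end on data the
package creates itself.

## The method

**Centered capture & ROI.** Photographs are framed with the lesion inside
the central cell of the camera's 3×3 grid, at a distance making the lesion
slightly smaller than that cell (4:3 frames). Preprocessing is then a fixed
centered crop ("ROI", larger than the central cell so neighborhood context
is kept), a bilinear resize to a square, and per-channel normalization
`(x/255 − μ_c)/σ_c`. No lesion detector or region proposals are needed.

**Resampling.** Each training image is expanded into `3 × Nt` fixed-size
patches: three rotation angles `{−θ, 0, +θ}` (θ = 15°) around each of `Nt`
centers (the nominal center plus `Nt − 1` uniform draws from a disc,
compensating centering error). Class-specific `Nt` — 3, 3, 5, 15 for ulcer,
low-risk, high-risk, cancer; rotation-only for normals — simultaneously
balances class sizes. Patch geometry is validated against the
rotated-square bound `s(|cos θ| + |sin θ|) + 2r ≤ min(H, W)`, so no patch
ever samples outside the source frame (no zero-padding, unlike rotation
done as on-the-fly augmentation).

**Classifier.** A convolutional backbone produces a spatial feature map; the
modified head is `1×1 conv (→ 5 channels) → batch norm → global average
pooling → log-softmax`, and the decision rule is
`c = argmax_j p_j(F(x))` with `p = softmax`. Because pooling is last, the
pre-pooling class maps are class activation maps (CAMs): the spatial mean
of class *k*'s map equals its logit exactly. The default `tiny` backbone
(reduction 16) trains in minutes on a CPU; the full HRNet-W18 the design
targets at clinical scale is an optional plug-in requiring external weights.

**Evaluation.** Macro-averaged sensitivity, specificity and precision from
the 5×5 confusion matrix, `F1 = 2·SE·Pr/(SE+Pr)` of the *macro* values,
plus per-class one-vs-rest AUC (Mann–Whitney, ties at ½) with 95% DeLong
confidence intervals.

The model and training stack (convolutions, batch norm, SGD with Nesterov
momentum, backprop) is implemented in NumPy inside the package — see
`docs/methods.md` for design details and known limitations.

## Worked example

```python
import numpy as np
import oralscope as osc

# 40 images/class, 4:3 frames, lesions framed by the centered rule
data = osc.generate_dataset([40] * 5, height=192, width=256, rng_seed=7)
data = osc.split_by_patient(data, test_fraction=0.3, rng_seed=7)

# expand the train split: 3 rotations x Nt offset centers per class
expanded = osc.build_training_set(data.subset("train"), osc.ResamplingConfig(), rng_seed=7)
print(expanded.class_counts)
```

prints

```
{'normal': 84, 'ulcer': 252, 'low_risk': 252, 'high_risk': 420, 'cancer': 1260}
```

i.e. each class's 28 training images became `base × 3 × Nt` patches:
`28×3 = 84` for normals (rotation-only), `28×3×3 = 252` for ulcer and
low-risk, `28×3×5 = 420` for high-risk and `28×3×15 = 1260` for cancer —
the minority classes expand the most. Running the training example
(`examples/03_train_and_evaluate.py`) then trains the tiny backbone at
64×64 and reports held-out macro metrics and per-class AUCs with DeLong
intervals; a representative run prints `SE=0.853 SP=0.963 Pr=0.863
F1=0.858` with per-class AUCs between 0.93 and 1.0 (the synthetic task is
deliberately learnable; clinical accuracy claims require clinical data).

Each script in `examples/` is a short narrative of one capability:
generation, preprocessing/resampling geometry, training + evaluation, and
CAM overlays.

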