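# Methods

This note documents the models, procedures and numerical choices behind
`oralscope`, in the spirit of a package methods appendix: what is computed,
under which assumptions, with which defaults, and what the tests do and do
not establish.

## Problem setting

Five-way classification of oral-cavity photographs — normal mucosa,
aphthous ulcer, low-risk (homogeneous) OPMD, high-risk (nonhomogeneous)
OPMD, oral cancer — from hand-held smartphone images captured under a
*centered* protocol: the lesion is framed inside the central cell of the
camera's 3×3 grid, at a distance making it slightly smaller than that cell,
in 4:3 frames. The protocol converts lesion localization (easy for a
layperson) into a geometric prior that a fixed centered crop can exploit,
so no detector or bounding-box annotation is needed.

## Synthetic data generator

Clinical photographs cannot ship with the package, so the generator
(`oralscope.synth`) emulates the *structure* the pipeline depends on, not
the appearance of real tissue:

- **Background**: textured pink mucosa — low-frequency mottling (stronger in
  the red channel), a smooth illumination gradient, one specular highlight,
  Gaussian sensor noise (σ = 3 intensity levels).
- **Lesion signatures** (procedural caricatures of the clinical
  descriptions, chosen so a small CNN can separate them): ulcer = round
  yellow core inside a red halo; low-risk OPMD = uniform pale patch with a
  smooth boundary; high-risk OPMD = pale patch with red blotches and an
  irregular boundary; cancer = dark nodular mass with strong bumpy texture
  and the most irregular boundary. Boundaries are discs modulated by random
  low-order polar harmonics scaled by an `irregularity` parameter.
- **Per-lesion appearance variability**: each lesion's palette gets an
  independent per-channel color scale (±15%) and its structural parameters
  (core fraction, blotch fraction, texture amplitudes) jitter by
  ±15–30%, and the background tone varies per subject (±4%). Clinical
  presentations of one class differ markedly between patients; without this
  intra-class variability a handful of minority-class examples would fully
  cover their class, which would make class imbalance (and any remedy for
  it) consequence-free — an unrealistic regime.
- **Geometry**: lesion diameter uniform in [0.5, 0.9] × the central-cell
  side (the "slightly smaller than the grid cell" rule quantified; the
  interval is a package choice). Under the `centered` protocol the lesion
  center is uniform over the central ninth of the frame; under `random` it
  is uniform over all positions keeping the lesion in frame.
- **Patient structure**: normal subjects contribute several images
  (different anatomic sites), lesion patients about one. Per-patient image
  counts are zero-truncated Poisson with the rate solved to match the
  requested mean (defaults 3.28, 1.15, 1.40, 1.32, 1.00 images/patient per
  class); the patient count is pinned at `round(n/mean)` and sampled counts
  are repaired by ±1 increments to sum exactly to `n`, so the patient count
  is reproducible while the count distribution keeps its spread.
- Default canvas 768×1024; all geometry is expressed in fractions, so any
  4:3 size works (tests use 192×256 for speed).

What passing tests on this generator *show*: the pipeline's geometry,
counting, optimization and evaluation machinery behave as specified, and
the training signal propagates end-to-end. What they do *not* show:
clinical accuracy. The synthetic classes are separable mainly by color and
texture statistics; real lesions overlap far more (clinically, low- vs
high-risk OPMD confuse even dentists), contain specular artifacts, occlusion
and pose variation the generator does not model.

## Splits and cross-validation

Train/test splits and CV folds are always at the *patient* level; an
image-level split would leak, because a patient's images are highly
correlated. `split_by_patient` targets per-class test-image counts with a
greedy exact-fit over whole patients (skip patients that would overshoot,
then top up minimally), so integer targets are usually hit exactly.

## Resampling

Each training image expands into `3 × Nt` patches: rotation angles
`{−θ, 0, +θ}` (θ = 15° default) around each of `Nt` centers — the nominal
center plus `Nt − 1` draws uniform in a disc (area-uniform; the
distribution is a package choice, the source leaves it open). Rotations
compensate capture-angle variability; offset centers compensate centering
error; per-class `Nt` (3, 3, 5, 15; normals rotation-only) balances class
sizes. The count law `expanded = base × 3 × Nt` is exact and seed-independent.

No-padding guarantee: a square of side `s` rotated by `a` spans
`s(|cos a| + |sin a|)` per axis, so patches satisfy
`s(|cos θ| + |sin θ|) + 2·offset_radius ≤ min(H, W)`; `max_valid_patch_side`
inverts this bound and `extract_rotated_patch` additionally asserts every
sample coordinate is in-frame, raising rather than padding.

Defaults: when no patch size is given, the largest valid square is used;
the default offset radius is 5% of the patch side. For the desk-scale
imbalance ablation the patch is sized so that the centered protocol's
placement jitter (the lesion center is anywhere in the central ninth, ±1/6
of the frame) plus the offset displacement can never push a lesion outside
the patch — on a 192×256 canvas that means a 128-px patch with a 10-px
offset radius. With a smaller patch, offset patches truncate lesions and
the expansion injects label noise instead of diversity.

Open point resolved: resampling operates on the *pre-crop* image (patches
replace the ROI crop for training; at test time the plain centered view is
used). The package treats the ROI and the patch as the same square
geometry, which keeps train and test views at the same lesion scale.

## Model

`backbone → 1×1 conv (C_f → 5) → BN → global average pool → log-softmax`,
prediction by argmax of the probabilities (ties, which have measure zero,
resolve to the lowest class index). Ordering rationale: conv+BN before
pooling (as drawn for the head), log taken after pooling — the only
placement that makes "global pooling directly outputs log probability"
exact. No nonlinearity after the head BN (none is specified; adding one
would break the CAM/logit identity below).

The `tiny` backbone is four Conv3×3(stride 2)→BN→ReLU stages
(3→8→16→32→64 channels, reduction r = 16), He-initialized. The head's 1×1
conv is initialized at 0.01× He scale so an untrained network predicts
near-uniform probabilities (cross-entropy ≈ ln 5 on balanced data); batch
norm makes training dynamics invariant to that scale. `hrnet_w18` is an
optional plug-in requiring the external PyTorch implementation and
ImageNet weights; requesting it without them raises — it is never silently
replaced by a random network.

The engine (`oralscope._nn`) is a deliberately small NumPy implementation:
im2col convolution on BLAS matmuls, standard batch-norm forward/backward,
SGD with Nesterov momentum (`v ← μv + g`, applied gradient `g + μv`) and
decoupled-from-BN weight decay (biases and BN affines exempt). float32
throughout; eval-mode forwards are bitwise deterministic.

## Training protocol

Cross-entropy on log-probabilities; initial learning rate 1e-3 multiplied
by 0.7 at epochs 15, 30, 45 ("reduced by 30%" read as ×0.7); weight decay
1e-4; Nesterov momentum 0.9; batch 24. Augmentation: horizontal flip
(p = 0.5), random-area crop with area ratio in [0.7, 1.0] resized back,
brightness and contrast scaling in [0.9, 1.1]; deterministic per seed;
inference is a single eval-mode forward pass, no test-time augmentation.
Model selection: best validation macro-F1 (the selection criterion is a
package choice; "best-performing" is otherwise unspecified), either across
patient-wise k folds (`folds=5` default) or a single patient-disjoint
holdout (`folds=1`). `steps_per_epoch` fixes the gradient-step count per
epoch so training-set constructions of different sizes can be compared
under matched budgets.

Desk-scale defaults used by the test suite: 192×256 canvases, 64×64 model
inputs, tiny backbone, ≤30 epochs, ~200 images/class — sized so the whole
suite runs on one CPU in minutes. Clinical scale (512×512, HRNet-class
backbone, 100 epochs, five folds) is reachable through the same configs
but is not part of the test surface.

## Evaluation

Per-class one-vs-rest counts from the 5×5 confusion matrix give
sensitivity, specificity and precision; macro values are unweighted means
over the five classes, and `F1 = 2·SE_macro·Pr_macro/(SE_macro+Pr_macro)` —
deliberately the harmonic mean of the *macro* sensitivity and precision,
not the mean of per-class F1s (the two differ). A 0/0 rate (class absent
from truth and predictions) is reported as 0 and flagged, keeping macro
averages defined on degenerate test sets without hiding the degeneracy.

AUC is the normalized Mann–Whitney statistic on the class probability
(midranks ⇒ ½ credit for ties). The DeLong variance uses the structural
components `V10, V01` computed via midranks (O(n log n)); CI =
`auc ± z·sqrt(var(V10)/m + var(V01)/n)`, clipped to [0, 1]; perfect
separation yields a zero variance and a degenerate interval with a
warning. The implementation is cross-checked in the tests against an R
pROC DeLong interval frozen from a seeded fixture and against a stratified
bootstrap.

## Class activation maps

The CAM for class *k* is the post-BN, pre-pooling response of head channel
*k* (eval-mode BN). Because eval BN is per-channel affine and pooling is a
spatial mean, `mean(CAM_k) = logit_k` exactly; the tests assert this
numerically (1e-5). Maps are bilinearly upsampled by the backbone
reduction (16×) to input size; overlays min-max normalize per image and
alpha-blend through a configurable colormap (default `jet`); a constant
map renders as zero heat with a warning.

## Numerical conventions

- All resizes and rotations: bilinear, half-pixel-center convention,
  border clamp (resize) or hard in-bounds assertion (rotation). Chosen once
  for reproducibility; verified against naive per-pixel oracles.
- Softmax/log-softmax: max-subtracted.
- Every stochastic operation takes an integer seed; pipelines derive
  per-operation seeds as `sha256(global_seed, tag) mod 2^31`, so one global
  seed reproduces a full run.

## Desk-scale ablations

The test suite reproduces the two study ablations qualitatively on
synthetic data (3 seeds, matched step budgets, 64×64, tiny backbone):

1. *Centered vs random positioning*: training and evaluating under the
   centered protocol (centered square view) vs under random lesion
   placement with random-location crops. Centered wins by a wide margin on
   synthetic data — random crops frequently truncate or miss the lesion.
2. *Resampling vs random oversampling*: on an imbalanced training set with
   the study's class proportions, the resampling expansion (rotations +
   offset centers, class-specific Nt) vs duplicating minority images to
   balance. Both arms train under the same step budget and are evaluated
   on a common balanced held-out set; the stochastic augmentation is
   disabled in *both* arms so that the only difference is the expansion
   scheme itself. (With the augmentation on, its random crops and
   photometric jitter supply both arms with much of the diversity the
   expansion schemes differ by, and at desk scale the residual difference
   drowns in seed noise; disabling it isolates the mechanism the
   comparison is about — distinct patches vs repeated pixels.)
   Resampling wins consistently across seeds in this regime.

These are direction checks, not effect-size reproductions: the study's
printed percentages require the clinical dataset and full-scale training.

## Known limitations

- The NumPy engine is single-threaded beyond BLAS and is not intended for
  512×512 training runs.
- The generator's class signatures are color/texture caricatures; models
  trained on them say nothing about clinical performance.
- `simulate_random_positioning` crops with per-axis fractions (matching the
  ROI definition), so its output distorts aspect slightly; the ablation's
  centered arm uses the square view for scale consistency.
- DeLong intervals are asymptotic; for very small classes the bootstrap
  check in the tests is the better reference.
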