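"""Supervised training harness.

Cross-entropy on the head's log-probabilities, SGD with Nesterov momentum
(0.9) and weight decay 1e-4, an initial learning rate of 1e-3 multiplied by
0.7 at epochs 15, 30 and 45, mini-batches of 24, and patient-wise k-fold
cross-validation with best-model selection by validation macro-F1.
Stochastic augmentation (horizontal flip, random resize-crop with area ratio
0.7-1.0, brightness and contrast scaling 0.9-1.1) is applied at train time
only; inference is always a single deterministic forward pass.

The harness operates on manifests whose samples already carry
pipeline-output pixels (square uint8 patches); normalization to model input
happens internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seeds import derive_seed
from .evaluate import confusion_matrix, macro_metrics
from ._nn import SGD
from .model import ClassScores, OralClassifier, log_softmax, softmax
from .preprocess import _resize, normalize
from .samples import DatasetManifest

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "lr_at_epoch",
    "augment",
    "make_folds",
    "train_model",
    "single_forward_inference",
    "predict_probabilities",
    "TrainingDiverged",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule and cross-validation settings.

    The defaults are the clinical-scale protocol (100 epochs, 5 folds);
    desk-scale runs shrink ``epochs`` and set ``folds=1`` (single
    patient-disjoint holdout of ``val_fraction``).  ``steps_per_epoch``
    fixes the number of gradient steps per epoch regardless of dataset
    size — used to compare training-set constructions under a matched step
    budget.
    """

    initial_lr: float = 0.001
    lr_drop_epochs: tuple[int, ...] = (15, 30, 45)
    lr_drop_factor: float = 0.7
    weight_decay: float = 0.0001
    momentum: float = 0.9
    nesterov: bool = True
    epochs: int = 100
    batch_size: int = 24
    folds: int = 5
    val_fraction: float = 0.2
    steps_per_epoch: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0 or self.weight_decay < 0 or self.batch_size < 1:
            raise ValueError("learning rate / weight decay / batch size invalid")
        if not (0.0 < self.lr_drop_factor < 1.0):
            raise ValueError("lr_drop_factor must be in (0, 1)")
        if self.epochs < 0 or self.folds < 1:
            raise ValueError("epochs must be >= 0 and folds >= 1")


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic train-time augmentation ranges."""

    hflip: bool = True
    resize_crop_ratio: tuple[float, float] = (0.7, 1.0)
    brightness_ratio: tuple[float, float] = (0.9, 1.1)
    contrast_ratio: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        for name in ("resize_crop_ratio", "brightness_ratio", "contrast_ratio"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} bounds must satisfy 0 < lo <= hi")

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(
            hflip=False,
            resize_crop_ratio=(1.0, 1.0),
            brightness_ratio=(1.0, 1.0),
            contrast_ratio=(1.0, 1.0),
        )


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Learning rate in force during ``epoch`` (0-based).

    The initial rate is multiplied by ``lr_drop_factor`` once for every drop
    epoch that has been reached (epoch >= drop).
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    n_drops = sum(1 for d in config.lr_drop_epochs if epoch >= d)
    return config.initial_lr * config.lr_drop_factor**n_drops


def augment(image: np.ndarray, config: AugmentConfig, rng_seed: int) -> np.ndarray:
    """Apply one random draw of the augmentation chain to an H x W x 3 image.

    Independent horizontal flip (p = 0.5), a random-area crop (area ratio
    drawn from ``resize_crop_ratio``) resized back to the input size, then
    brightness and contrast scaling.  Output size and dtype equal the
    input's; deterministic per ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    arr = np.asarray(image)
    height, width = arr.shape[:2]
    out = arr.astype(np.float64)
    if config.hflip and rng.uniform() < 0.5:
        out = out[:, ::-1]
    area = rng.uniform(*config.resize_crop_ratio)
    if area < 1.0:
        frac = math.sqrt(area)
        ch = max(1, round(frac * height))
        cw = max(1, round(frac * width))
        top = int(rng.integers(0, height - ch + 1))
        left = int(rng.integers(0, width - cw + 1))
        out = _resize(out[top : top + ch, left : left + cw], height, width)
    brightness = rng.uniform(*config.brightness_ratio)
    out = out * brightness
    contrast = rng.uniform(*config.contrast_ratio)
    mean = out.mean()
    out = (out - mean) * contrast + mean
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(arr.dtype)
    return out.astype(arr.dtype)


def make_folds(
    manifest: DatasetManifest, k: int, rng_seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-wise k-fold partition: (train_indices, val_indices) pairs.

    Patients — never individual images — are split across folds, so no
    patient's images straddle train and validation in any fold.  Every image
    appears in exactly one validation fold.
    """
    patients = manifest.patient_ids
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k} folds, have {len(patients)}")
    rng = np.random.default_rng(rng_seed)
    order = list(patients)
    rng.shuffle(order)
    fold_of = {pid: i % k for i, pid in enumerate(order)}
    folds = []
    sample_folds = np.asarray([fold_of[s.patient_id] for s in manifest.samples])
    for f in range(k):
        val_idx = np.flatnonzero(sample_folds == f)
        train_idx = np.flatnonzero(sample_folds != f)
        folds.append((train_idx, val_idx))
    return folds


class TrainingDiverged(RuntimeError):
    """Loss became non-finite during optimization."""


def _to_batch(images: Sequence[np.ndarray]) -> np.ndarray:
    """Stack uint8 H x W x 3 images into a normalized float32 NCHW batch."""
    arr = np.stack([normalize(im) for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2).astype(np.float32))


def predict_probabilities(
    model: OralClassifier, images: Sequence[np.ndarray], batch_size: int = 64
) -> np.ndarray:
    """Class probabilities for a sequence of uint8 H x W x 3 images, (n, 5)."""
    out = []
    for i in range(0, len(images), batch_size):
        out.append(model.predict_proba(_to_batch(images[i : i + batch_size])))
    return np.concatenate(out, axis=0)


_predict_proba_batched = predict_probabilities


def _fit_single(
    model: OralClassifier,
    train_images: list[np.ndarray],
    train_labels: np.ndarray,
    val_images: list[np.ndarray],
    val_labels: np.ndarray,
    cfg: TrainConfig,
    aug: AugmentConfig | None,
    seed: int,
) -> tuple[dict, list[dict]]:
    """Train one model; return (best_state_dict, history)."""
    n = len(train_images)
    optimizer = SGD(
        model.params,
        lr=cfg.initial_lr,
        momentum=cfg.momentum,
        nesterov=cfg.nesterov,
        weight_decay=cfg.weight_decay,
    )
    history: list[dict] = []
    best = {"f1": -1.0, "state": model.state_dict()}
    rng = np.random.default_rng(seed)
    for epoch in range(cfg.epochs):
        optimizer.lr = lr_at_epoch(cfg, epoch)
        if cfg.steps_per_epoch is None:
            order = rng.permutation(n)
            batches = [
                order[i : i + cfg.batch_size] for i in range(0, n, cfg.batch_size)
            ]
        else:
            batches = [
                rng.integers(0, n, size=min(cfg.batch_size, n))
                for _ in range(cfg.steps_per_epoch)
            ]
        epoch_loss = 0.0
        n_seen = 0
        for batch_idx in batches:
            imgs = []
            for bi in batch_idx:
                im = train_images[int(bi)]
                if aug is not None:
                    im = augment(im, aug, int(rng.integers(0, 2**31 - 1)))
                imgs.append(im)
            x = _to_batch(imgs)
            y = train_labels[batch_idx]
            logits = model.logits(x, train=True)
            logp = log_softmax(logits)
            loss = -logp[np.arange(len(y)), y].mean()
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} (lr={optimizer.lr:g})"
                )
            probs = softmax(logits)
            dlogits = probs.copy()
            dlogits[np.arange(len(y)), y] -= 1.0
            dlogits /= len(y)
            model.zero_grad()
            model.backward_from_logits(dlogits)
            optimizer.step()
            epoch_loss += float(loss) * len(y)
            n_seen += len(y)
        entry = {
            "epoch": epoch,
            "lr": optimizer.lr,
            "train_loss": epoch_loss / max(n_seen, 1),
        }
        if len(val_images):
            probs = _predict_proba_batched(model, val_images)
            preds = probs.argmax(axis=1)
            cm = confusion_matrix(val_labels, preds)
            mm = macro_metrics(cm)
            entry["val_macro_f1"] = mm.f1
            entry["val_accuracy"] = float((preds == val_labels).mean())
            if mm.f1 > best["f1"]:
                best = {"f1": mm.f1, "state": model.state_dict()}
        history.append(entry)
    if best["f1"] < 0:  # no validation set: keep the final weights
        best["state"] = model.state_dict()
    return best["state"], history


def train_model(
    manifest: DatasetManifest,
    model: OralClassifier,
    train_cfg: TrainConfig = TrainConfig(),
    augment_cfg: AugmentConfig | None = AugmentConfig(),
) -> tuple[OralClassifier, list[dict]]:
    """Train on a manifest of square uint8 images; return (model, history).

    With ``folds > 1``, one model is trained per patient-wise fold and the
    one with the best validation macro-F1 is returned; with ``folds == 1`` a
    single patient-disjoint holdout of ``val_fraction`` is used.  History
    entries carry fold, epoch, learning rate, train loss and validation
    metrics.  ``epochs == 0`` returns the initial model untouched with an
    empty history.
    """
    if len(manifest) == 0:
        raise ValueError("training manifest is empty")
    if train_cfg.epochs == 0:
        return model, []
    images = [s.pixels for s in manifest.samples]
    if any(im is None for im in images):
        raise ValueError("all training samples must carry pixels")
    labels = np.asarray([s.label_index for s in manifest.samples], dtype=np.int64)

    if train_cfg.folds > 1:
        folds = make_folds(manifest, train_cfg.folds, derive_seed(train_cfg.seed, "folds"))
    else:
        k = max(2, round(1.0 / max(train_cfg.val_fraction, 1e-9)))
        folds = [make_folds(manifest, k, derive_seed(train_cfg.seed, "holdout"))[0]]

    best_overall = {"f1": -np.inf, "state": None}
    history: list[dict] = []
    init_state = model.state_dict()
    for fi, (tr_idx, va_idx) in enumerate(folds):
        fold_model = model.clone()
        fold_model.load_state_dict(init_state)
        state, fold_hist = _fit_single(
            fold_model,
            [images[i] for i in tr_idx],
            labels[tr_idx],
            [images[i] for i in va_idx],
            labels[va_idx],
            train_cfg,
            augment_cfg,
            derive_seed(train_cfg.seed, f"fold{fi}"),
        )
        fold_f1 = max(
            (h.get("val_macro_f1", -np.inf) for h in fold_hist), default=-np.inf
        )
        for h in fold_hist:
            history.append({"fold": fi, **h})
        if fold_f1 > best_overall["f1"]:
            best_overall = {"f1": fold_f1, "state": state}
    if best_overall["state"] is not None:
        model.load_state_dict(best_overall["state"])
    return model, history


def single_forward_inference(model: OralClassifier, image: np.ndarray) -> ClassScores:
    """Score one image with a single eval-mode forward pass.

    No test-time augmentation or ensembling.  Accepts an H x W x 3 uint8
    image (normalized internally) or an already-normalized (3, H, W) float
    tensor.
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] == 3 and arr.shape[0] != 3:
        x = _to_batch([arr])[0]
    else:
        x = arr.astype(np.float32)
    return model.scores(x)
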