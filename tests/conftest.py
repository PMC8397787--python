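"""Shared fixtures: synthetic datasets and a trained desk-scale model.

The heavier fixtures are session-scoped so the separability training run is
paid for once and reused by the model-quality, CAM-localization and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import oralscope as osc
from oralscope._seeds import derive_seed
from oralscope.model import OralClassifier, make_backbone
from oralscope.preprocess import RoiConfig, crop_center_roi, resize_image
from oralscope.samples import DatasetManifest, split_by_patient
from oralscope.train import AugmentConfig, TrainConfig, train_model

CANVAS = (192, 256)  # 4:3 generation canvas for desk-scale tests
SIDE = 64  # model input side
ROI = RoiConfig(roi_fraction=0.5, output_side=SIDE)


def center_preprocess(manifest: DatasetManifest) -> DatasetManifest:
    """Centered ROI crop + resize for every sample, keeping the split.

    Recorded lesion centers/diameters are mapped into the output frame."""
    out = []
    for s in manifest.samples:
        c = crop_center_roi(s, ROI)
        ch, cw = c.pixels.shape[:2]
        if c.lesion_center is not None:
            c.lesion_center = (
                (c.lesion_center[0] + 0.5) * SIDE / ch - 0.5,
                (c.lesion_center[1] + 0.5) * SIDE / cw - 0.5,
            )
        if c.lesion_diameter is not None:
            c.lesion_diameter = c.lesion_diameter * SIDE / ((ch + cw) / 2.0)
        c.pixels = resize_image(c.pixels, SIDE)
        out.append(c)
    return DatasetManifest(samples=out, split=dict(manifest.split))


@pytest.fixture(scope="session")
def small_rendered_manifest() -> DatasetManifest:
    """A tiny rendered centered-protocol dataset (8 images/class)."""
    return osc.generate_dataset([8] * 5, height=CANVAS[0], width=CANVAS[1], rng_seed=11)


@pytest.fixture(scope="session")
def separability_run():
    """Train the tiny model on 200 images/class at 64 x 64 (30 epochs).

    Returns (model, val_manifest, history, heldout_accuracy).  The held-out
    set is a patient-disjoint 25% of the data.
    """
    manifest = osc.generate_dataset(
        [200] * 5, height=CANVAS[0], width=CANVAS[1], rng_seed=3
    )
    manifest = split_by_patient(manifest, 0.25, rng_seed=3)
    processed = center_preprocess(manifest)
    train_m = processed.subset("train")
    val_m = processed.subset("test")
    model = OralClassifier(make_backbone("tiny", rng_seed=0))
    cfg = TrainConfig(epochs=30, folds=1, seed=0)
    model, history = train_model(train_m, model, cfg, AugmentConfig())
    from oralscope.train import predict_probabilities

    probs = predict_probabilities(model, [s.pixels for s in val_m.samples])
    labels = np.asarray([s.label_index for s in val_m.samples])
    accuracy = float((probs.argmax(axis=1) == labels).mean())
    return model, val_m, history, accuracy
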