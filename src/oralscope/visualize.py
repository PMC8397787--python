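"""Class activation mapping (CAM) and heatmap overlays.

Because the classifier's head is 1x1 conv -> BN -> global average pooling,
the 5-channel pre-pooling response *is* the set of class activation maps:
the spatial mean of class k's raw map equals class k's pooled logit exactly
(BN in eval mode is a per-channel affine map, which commutes with spatial
averaging).  To visualize, the raw map is bilinearly upsampled by the
backbone's reduction factor (16x for the default backbone) back to the input
size and alpha-blended over the image through a colormap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .model import OralClassifier
from .preprocess import _resize
from .samples import CLASS_NAMES

__all__ = ["ActivationMap", "compute_cam", "overlay_heatmap"]


@dataclass(frozen=True)
class ActivationMap:
    """One class's spatial activation map, upsampled to the input size."""

    map: np.ndarray  # (H, W) float
    class_index: int
    normalization: str = "raw"  # "raw" | "minmax"
    raw_map: np.ndarray | None = None  # pre-upsampling response, (h, w)


def compute_cam(
    model: OralClassifier, image: np.ndarray, class_index: int
) -> ActivationMap:
    """Per-position evidence map for one class, at input resolution.

    ``image`` is a normalized (3, H, W) float tensor (model input).  The raw
    map is the post-BN pre-pooling response of channel ``class_index`` (eval
    mode); it is bilinearly upsampled to H x W.  The raw map's spatial mean
    equals the class's pooled pre-softmax logit.
    """
    if not 0 <= class_index < model.n_classes:
        raise ValueError(
            f"class_index must be in [0, {model.n_classes}); got {class_index} "
            f"(classes: {CLASS_NAMES})"
        )
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    prepool = model.forward_prepool(x, train=False)
    raw = prepool[0, class_index].astype(np.float64)
    height, width = x.shape[2], x.shape[3]
    upsampled = _resize(raw, height, width)
    return ActivationMap(
        map=upsampled, class_index=class_index, normalization="raw", raw_map=raw
    )


def overlay_heatmap(
    image: np.ndarray,
    amap: ActivationMap,
    alpha: float = 0.4,
    cmap: str = "jet",
) -> np.ndarray:
    """Alpha-blend a min-max-normalized activation map over an image.

    ``image`` is H x W x 3 uint8; ``alpha`` = 0 returns the image untouched,
    ``alpha`` = 1 the pure heatmap.  A constant map carries no spatial
    information; it is rendered as all-zero with a warning.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    arr = np.asarray(image, dtype=np.float64)
    m = np.asarray(amap.map, dtype=np.float64)
    if m.shape != arr.shape[:2]:
        raise ValueError(f"map shape {m.shape} does not match image {arr.shape[:2]}")
    span = m.max() - m.min()
    if span <= 0:
        warnings.warn("constant activation map; rendering a zero heatmap", stacklevel=2)
        norm = np.zeros_like(m)
    else:
        norm = (m - m.min()) / span
    heat = colormaps[cmap](norm)[..., :3] * 255.0
    blended = (1.0 - alpha) * arr + alpha * heat
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)
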