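"""Preprocessing chain: centered ROI crop, normalization, square resize.

Images captured under the centered protocol hold the lesion inside the
central cell of the camera's 3x3 grid, so a fixed, axis-aligned centered crop
("region of interest", ROI) isolates the lesion plus its immediate
neighborhood without any lesion detector.  The ROI is deliberately larger
than the central grid cell (``roi_fraction > 1/3``) because context near the
lesion carries diagnostic information.  The chain is: centered crop ->
bilinear resize to a square (default 512 px) -> per-channel normalization.

A "random positioning" simulator is also provided: it crops at a uniformly
random location instead of the center, emulating capture without the framing
rule; it serves as the ablation baseline against the centered protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import overload

import numpy as np
from scipy.ndimage import map_coordinates

from .samples import ImageSample

__all__ = [
    "RoiConfig",
    "crop_center_roi",
    "normalize",
    "denormalize",
    "resize_image",
    "simulate_random_positioning",
    "to_model_input",
]

#: conventional ImageNet channel statistics, matching an ImageNet-pretrained
#: backbone's expectations; configurable via RoiConfig
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class RoiConfig:
    """Centered-crop and normalization parameters.

    ``roi_fraction`` is the side of the centered crop as a fraction of each
    image side; it must exceed 1/3 so the ROI strictly contains the central
    grid cell.  ``output_side`` is the square side after resizing.
    """

    roi_fraction: float = 0.5
    output_side: int = 512
    channel_mean: tuple[float, float, float] = IMAGENET_MEAN
    channel_std: tuple[float, float, float] = IMAGENET_STD

    def __post_init__(self) -> None:
        if not (1.0 / 3.0 < self.roi_fraction <= 1.0):
            raise ValueError(
                f"roi_fraction must be in (1/3, 1] so the ROI exceeds the central "
                f"grid cell; got {self.roi_fraction}"
            )
        if self.output_side <= 0:
            raise ValueError("output_side must be positive")
        if any(s <= 0 for s in self.channel_std):
            raise ValueError("channel_std entries must be > 0")


def _center_slices(height: int, width: int, fraction: float) -> tuple[slice, slice]:
    ch = int(np.floor(fraction * height))
    cw = int(np.floor(fraction * width))
    if ch <= 1 or cw <= 1:
        raise ValueError(
            f"crop fraction {fraction} of a {height}x{width} image degenerates to "
            f"{ch}x{cw} pixels"
        )
    top = (height - ch) // 2
    left = (width - cw) // 2
    return slice(top, top + ch), slice(left, left + cw)


@overload
def crop_center_roi(image: np.ndarray, config: RoiConfig) -> np.ndarray: ...
@overload
def crop_center_roi(image: ImageSample, config: RoiConfig) -> ImageSample: ...


def crop_center_roi(image, config: RoiConfig = RoiConfig()):
    """Axis-aligned centered crop of side ``roi_fraction`` x image side.

    Pixel values are untouched.  Accepts a raw H x W x 3 array or an
    :class:`~oralscope.samples.ImageSample` (whose recorded lesion center, if
    any, is shifted into the crop frame).
    """
    if isinstance(image, ImageSample):
        cropped = crop_center_roi(image.pixels, config)
        center = image.lesion_center
        if center is not None:
            rs, cs = _center_slices(*image.pixels.shape[:2], config.roi_fraction)
            center = (center[0] - rs.start, center[1] - cs.start)
        return ImageSample(
            label=image.label,
            patient_id=image.patient_id,
            source_id=image.source_id,
            protocol=image.protocol,
            pixels=cropped,
            path=image.path,
            lesion_center=center,
            lesion_diameter=image.lesion_diameter,
        )
    arr = np.asarray(image)
    rs, cs = _center_slices(arr.shape[0], arr.shape[1], config.roi_fraction)
    return arr[rs, cs].copy()


def normalize(
    image: np.ndarray,
    channel_mean: tuple[float, float, float] = IMAGENET_MEAN,
    channel_std: tuple[float, float, float] = IMAGENET_STD,
) -> np.ndarray:
    """Map [0, 255] pixel values to standardized floats.

    Each pixel is first scaled to [0, 1] (divide by 255), then per channel
    the mean is subtracted and the result divided by the std.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("normalize expects pixel values in [0, 255]")
    std = np.asarray(channel_std, dtype=np.float64)
    if np.any(std <= 0):
        raise ValueError("channel std must be > 0")
    mean = np.asarray(channel_mean, dtype=np.float64)
    return (arr / 255.0 - mean) / std


def denormalize(
    image: np.ndarray,
    channel_mean: tuple[float, float, float] = IMAGENET_MEAN,
    channel_std: tuple[float, float, float] = IMAGENET_STD,
) -> np.ndarray:
    """Exact inverse of :func:`normalize` (returns floats in [0, 255])."""
    arr = np.asarray(image, dtype=np.float64)
    return (arr * np.asarray(channel_std) + np.asarray(channel_mean)) * 255.0


def resize_image(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize to ``side x side`` (half-pixel-center convention).

    The aspect ratio is allowed to change — the pipeline's output is always
    square.  Integer inputs are rounded back to their dtype; float inputs
    stay float.
    """
    return _resize(image, side, side)


def _resize(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    if out_h <= 0 or out_w <= 0:
        raise ValueError("output size must be positive")
    arr = np.asarray(image)
    in_h, in_w = arr.shape[:2]
    rows = (np.arange(out_h) + 0.5) * (in_h / out_h) - 0.5
    cols = (np.arange(out_w) + 0.5) * (in_w / out_w) - 0.5
    grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([grid_r.ravel(), grid_c.ravel()])

    def _one(channel: np.ndarray) -> np.ndarray:
        return map_coordinates(
            channel.astype(np.float64), coords, order=1, mode="nearest"
        ).reshape(out_h, out_w)

    if arr.ndim == 2:
        out = _one(arr)
    else:
        out = np.stack([_one(arr[..., c]) for c in range(arr.shape[2])], axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(arr.dtype)
    return out.astype(arr.dtype)


@overload
def simulate_random_positioning(
    image: np.ndarray, crop_fraction: float, rng_seed: int, output_side: int = 512
) -> np.ndarray: ...
@overload
def simulate_random_positioning(
    image: ImageSample, crop_fraction: float, rng_seed: int, output_side: int = 512
) -> ImageSample: ...


def simulate_random_positioning(image, crop_fraction, rng_seed, output_side=512):
    """Crop at a uniformly random location, then resize to a square.

    Emulates capture *without* the centered framing rule: the lesion ends up
    at a much wider range of positions in the processed image than under
    :func:`crop_center_roi`.  Deterministic per ``rng_seed``.
    """
    if not (0.0 < crop_fraction <= 1.0):
        raise ValueError(f"crop_fraction must be in (0, 1], got {crop_fraction}")
    if isinstance(image, ImageSample):
        arr = image.pixels
    else:
        arr = np.asarray(image)
    height, width = arr.shape[:2]
    ch = int(np.floor(crop_fraction * height))
    cw = int(np.floor(crop_fraction * width))
    if ch <= 1 or cw <= 1:
        raise ValueError("crop degenerates to <= 1 px")
    rng = np.random.default_rng(rng_seed)
    top = int(rng.integers(0, height - ch + 1))
    left = int(rng.integers(0, width - cw + 1))
    out = _resize(arr[top : top + ch, left : left + cw], output_side, output_side)
    if isinstance(image, ImageSample):
        center = image.lesion_center
        if center is not None:
            # map the lesion center through crop then resize
            r = (center[0] - top + 0.5) * (output_side / ch) - 0.5
            c = (center[1] - left + 0.5) * (output_side / cw) - 0.5
            center = (r, c)
        diameter = image.lesion_diameter
        if diameter is not None:
            diameter = diameter * output_side / ((ch + cw) / 2.0)
        return ImageSample(
            label=image.label,
            patient_id=image.patient_id,
            source_id=image.source_id,
            protocol=image.protocol,
            pixels=out,
            path=image.path,
            lesion_center=center,
            lesion_diameter=diameter,
        )
    return out


def to_model_input(image: np.ndarray, config: RoiConfig = RoiConfig()) -> np.ndarray:
    """Normalize an H x W x 3 uint8 image into a float32 (3, H, W) tensor."""
    arr = normalize(image, config.channel_mean, config.channel_std)
    return np.ascontiguousarray(arr.transpose(2, 0, 1).astype(np.float32))
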