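"""Rotation / offset-center resampling of the training set.

Each training photograph is expanded into several fixed-size patches before
training, compensating at once for two sources of hand-held capture
variability and for class imbalance:

* small framing-angle differences — every image is sampled at the three
  rotation angles ``{-theta, 0, +theta}`` about the patch center;
* imprecise lesion centering — the nominal center is displaced to ``Nt``
  points (the original plus ``Nt - 1`` uniform draws from a disc), and the
  three rotated patches are extracted around each;
* imbalance — ``Nt`` is chosen per class (defaults 3, 3, 5, 15 for ulcer,
  low-risk, high-risk and cancer) so minority classes expand more.  Healthy
  (normal) images get rotations only, no offset centers.

Every emitted patch samples exclusively in-bounds pixels of its source
image: patch geometry is validated against the rotated-square circumscription
bound before extraction, so no zero-padding ever occurs (unlike rotation done
as on-the-fly augmentation, which pads corners).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from ._seeds import derive_seed
from .samples import CLASS_NAMES, DatasetManifest, ImageSample

__all__ = [
    "ResamplingConfig",
    "PatchSet",
    "PatchRecord",
    "ExpandedManifest",
    "rotation_angles",
    "max_valid_patch_side",
    "extract_rotated_patch",
    "sample_offset_centers",
    "expand_case",
    "build_training_set",
    "materialize_patches",
    "random_oversample",
]

#: per-class offset-center counts Nt; normal is rotation-only (Nt = 1, no
#: offsets), the others balance class sizes
DEFAULT_NT: dict[str, int] = {
    "normal": 1,
    "ulcer": 3,
    "low_risk": 3,
    "high_risk": 5,
    "cancer": 15,
}


@dataclass(frozen=True)
class ResamplingConfig:
    """Parameters of the resampling expansion.

    ``patch_size`` may be ``None``, in which case the largest square patch
    that stays in-bounds under the worst-case rotation and offset
    (:func:`max_valid_patch_side`) is used per image.  ``offset_radius`` may
    be ``None`` to default to 5% of the patch side.
    """

    theta: float = 15.0
    nt_per_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_NT))
    patch_size: tuple[int, int] | None = None
    offset_radius: float | None = None

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        for cls, nt in self.nt_per_class.items():
            if cls not in CLASS_NAMES:
                raise ValueError(f"unknown class {cls!r} in nt_per_class")
            if nt < 1:
                raise ValueError(f"Nt must be >= 1, got {nt} for {cls}")
        if self.offset_radius is not None and self.offset_radius < 0:
            raise ValueError("offset_radius must be >= 0")

    def nt(self, label: str) -> int:
        """Effective Nt for a class (normal is always 1: rotation only)."""
        if label == "normal":
            return 1
        return int(self.nt_per_class.get(label, 1))

    def rotation_only(self) -> "ResamplingConfig":
        """Variant with offset-center resampling disabled for every class."""
        return replace(self, nt_per_class={c: 1 for c in CLASS_NAMES})


@dataclass
class PatchRecord:
    """Metadata of one patch of an expanded training set."""

    source_id: str
    label: str
    angle: float
    center: tuple[float, float]
    patch_id: str = ""


@dataclass
class PatchSet:
    """The patches extracted from one source image."""

    source_id: str
    label: str
    patches: list[np.ndarray]
    angles: list[float]
    centers: list[tuple[float, float]]

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class ExpandedManifest:
    """Patch-level training manifest produced by :func:`build_training_set`."""

    records: list[PatchRecord]
    config: ResamplingConfig
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_counts:
            counts = Counter(r.label for r in self.records)
            self.class_counts = {c: counts.get(c, 0) for c in CLASS_NAMES}

    def __len__(self) -> int:
        return len(self.records)


def rotation_angles(theta: float) -> list[float]:
    """The three extraction angles ``{-theta, 0, +theta}`` (degrees).

    ``theta == 0`` degenerates to the single angle 0.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if theta == 0:
        return [0.0]
    return [-float(theta), 0.0, float(theta)]


def _rotation_span_factor(theta: float) -> float:
    """max over |a| <= theta of (|cos a| + |sin a|): the rotated-square span."""
    rad = np.deg2rad(min(abs(theta), 45.0))
    return float(np.cos(rad) + np.sin(rad))


def max_valid_patch_side(
    image_size: tuple[int, int], theta: float, offset_radius: float
) -> int:
    """Largest square patch side guaranteed in-bounds for all geometries.

    A square of side ``s`` rotated by angle ``a`` spans ``s (|cos a| +
    |sin a|)`` along each axis; adding the worst-case center displacement
    gives the no-padding condition ``s (|cos a| + |sin a|) + 2 r <=
    min(H, W)``, maximized over ``|a| <= theta``.
    """
    height, width = image_size
    if height <= 0 or width <= 0 or offset_radius < 0:
        raise ValueError("image size must be positive and offset_radius >= 0")
    avail = min(height, width) - 2.0 * offset_radius
    if avail <= 0:
        return 0
    return int(np.floor(avail / _rotation_span_factor(theta)))


class PatchOutOfBoundsError(ValueError):
    """Raised when a requested patch would sample outside the source frame."""


def _patch_coords(
    center: tuple[float, float], angle: float, size: tuple[int, int]
) -> np.ndarray:
    """(2, H*W) source coordinates for an axis grid rotated by ``angle``."""
    ph, pw = size
    rows = np.arange(ph) - (ph - 1) / 2.0
    cols = np.arange(pw) - (pw - 1) / 2.0
    gr, gc = np.meshgrid(rows, cols, indexing="ij")
    a = np.deg2rad(angle)
    cos, sin = np.cos(a), np.sin(a)
    # rotating the source by +angle about `center` and reading an axis-aligned
    # patch is equivalent to sampling the source at the inversely rotated grid
    src_r = center[0] + cos * gr - sin * gc
    src_c = center[1] + sin * gr + cos * gc
    return np.stack([src_r.ravel(), src_c.ravel()])


def extract_rotated_patch(
    image: np.ndarray,
    center: tuple[float, float],
    angle: float,
    size: tuple[int, int],
) -> np.ndarray:
    """Sample an ``H x W`` patch rotated by ``angle`` degrees about ``center``.

    Bilinear interpolation via the inverse rotation map.  Every sample
    coordinate must lie inside the source frame; an out-of-bounds request
    raises :class:`PatchOutOfBoundsError` — the patch is never padded.
    """
    arr = np.asarray(image)
    height, width = arr.shape[:2]
    coords = _patch_coords(center, angle, size)
    rmin, rmax = coords[0].min(), coords[0].max()
    cmin, cmax = coords[1].min(), coords[1].max()
    if rmin < 0 or cmin < 0 or rmax > height - 1 or cmax > width - 1:
        raise PatchOutOfBoundsError(
            f"patch {size} at center {center} rotated {angle} deg samples rows "
            f"[{rmin:.1f}, {rmax:.1f}] cols [{cmin:.1f}, {cmax:.1f}] outside the "
            f"{height}x{width} frame; no padding is performed"
        )

    def _one(channel: np.ndarray) -> np.ndarray:
        return map_coordinates(
            channel.astype(np.float64), coords, order=1, mode="constant", cval=np.nan
        ).reshape(size)

    if arr.ndim == 2:
        out = _one(arr)
    else:
        out = np.stack([_one(arr[..., c]) for c in range(arr.shape[2])], axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(arr.dtype)
    return out.astype(arr.dtype)


def sample_offset_centers(
    center: tuple[float, float],
    nt: int,
    offset_radius: float,
    rng_seed: int,
) -> list[tuple[float, float]]:
    """``nt`` approximate lesion centers: the original plus uniform-disc draws.

    The first returned center is always the input; the remaining ``nt - 1``
    are uniform over the disc of ``offset_radius`` around it (area-uniform:
    radius ~ R * sqrt(U)).  Deterministic per ``rng_seed``.
    """
    if nt < 1:
        raise ValueError("nt must be >= 1")
    rng = np.random.default_rng(rng_seed)
    centers = [(float(center[0]), float(center[1]))]
    for _ in range(nt - 1):
        radius = offset_radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        centers.append(
            (float(center[0] + radius * np.sin(phi)), float(center[1] + radius * np.cos(phi)))
        )
    return centers


def _resolve_geometry(
    image_size: tuple[int, int], config: ResamplingConfig
) -> tuple[tuple[int, int], float]:
    """Concrete (patch_size, offset_radius) for one source image."""
    if config.patch_size is not None:
        size = config.patch_size
        radius = (
            config.offset_radius
            if config.offset_radius is not None
            else 0.05 * min(size)
        )
    else:
        if config.offset_radius is not None:
            radius = config.offset_radius
            side = max_valid_patch_side(image_size, config.theta, radius)
        else:
            # radius tied to the patch side (5%): solve the circumscription
            # bound s*f + 2*(0.05 s) <= min(H, W) directly
            f = _rotation_span_factor(config.theta)
            side = int(np.floor(min(image_size) / (f + 0.1)))
            radius = 0.05 * side
        size = (side, side)
    if min(size) <= 0:
        raise ValueError(f"degenerate patch size {size} for image {image_size}")
    max_side = max_valid_patch_side(image_size, config.theta, radius)
    if max(size) > max_side:
        raise ValueError(
            f"patch {size} with theta={config.theta} and offset_radius={radius:.1f} "
            f"cannot stay inside a {image_size} image (max side {max_side})"
        )
    return (int(size[0]), int(size[1])), float(radius)


def expand_case(
    sample: ImageSample, config: ResamplingConfig, rng_seed: int
) -> PatchSet:
    """Expand one labeled image into its resampled patches.

    Normal images yield 3 patches (three rotation angles about the image
    center); lesion images yield ``3 x Nt(class)``: three rotations around
    each of the Nt offset centers.  All patches are asserted in-bounds.
    """
    if sample.pixels is None:
        raise ValueError(f"sample {sample.source_id!r} has no pixels to expand")
    arr = sample.pixels
    image_size = arr.shape[:2]
    size, radius = _resolve_geometry(image_size, config)
    base_center = ((image_size[0] - 1) / 2.0, (image_size[1] - 1) / 2.0)
    nt = config.nt(sample.label)
    if nt == 1:
        centers = [base_center]
    else:
        centers = sample_offset_centers(
            base_center, nt, radius, derive_seed(rng_seed, f"offsets:{sample.source_id}")
        )
    angles = rotation_angles(config.theta)
    patches, out_angles, out_centers = [], [], []
    for center in centers:
        for angle in angles:
            patches.append(extract_rotated_patch(arr, center, angle, size))
            out_angles.append(angle)
            out_centers.append(center)
    return PatchSet(
        source_id=sample.source_id,
        label=sample.label,
        patches=patches,
        angles=out_angles,
        centers=out_centers,
    )


def build_training_set(
    manifest: DatasetManifest,
    config: ResamplingConfig = ResamplingConfig(),
    rng_seed: int = 0,
    image_size: tuple[int, int] | None = None,
) -> ExpandedManifest:
    """Expand the train split of a manifest into a patch-level manifest.

    Works at the metadata level (angles and centers only); pixels are
    materialized lazily by :func:`expand_case` or
    :meth:`materialize_patches`.  The count law is ``expanded_c = base_c x
    len(angles) x Nt(c)`` with ``Nt(normal) = 1``.

    ``image_size`` is needed to draw offset centers when samples carry no
    pixels; with pixels present each sample's own shape is used.
    """
    train = manifest.subset("train") if manifest.split else manifest
    records: list[PatchRecord] = []
    angles = rotation_angles(config.theta)
    for sample in train.samples:
        if sample.pixels is not None:
            src_size = sample.pixels.shape[:2]
        elif image_size is not None:
            src_size = image_size
        else:
            src_size = (768, 1024)
        size, radius = _resolve_geometry(src_size, config)
        base_center = ((src_size[0] - 1) / 2.0, (src_size[1] - 1) / 2.0)
        nt = config.nt(sample.label)
        if nt == 1:
            centers = [base_center]
        else:
            centers = sample_offset_centers(
                base_center, nt, radius,
                derive_seed(rng_seed, f"offsets:{sample.source_id}"),
            )
        for ci, center in enumerate(centers):
            for angle in angles:
                records.append(
                    PatchRecord(
                        source_id=sample.source_id,
                        label=sample.label,
                        angle=angle,
                        center=center,
                        patch_id=f"{sample.source_id}:c{ci}:a{angle:+.0f}",
                    )
                )
    return ExpandedManifest(records=records, config=config)


def materialize_patches(
    manifest: DatasetManifest,
    expanded: ExpandedManifest,
    output_side: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the pixels of every patch record of an expanded manifest.

    Returns ``(patches, labels)``: a uint8 array ``N x H x W x 3`` (patches
    are resized to ``output_side`` if given) and the integer class labels.
    Source images are looked up by ``source_id`` in ``manifest`` and must
    carry pixels.
    """
    from .preprocess import resize_image

    by_id = {s.source_id: s for s in manifest.samples}
    patches, labels = [], []
    for rec in expanded.records:
        sample = by_id.get(rec.source_id)
        if sample is None or sample.pixels is None:
            raise ValueError(f"no pixels available for source {rec.source_id!r}")
        size, _ = _resolve_geometry(sample.pixels.shape[:2], expanded.config)
        patch = extract_rotated_patch(sample.pixels, rec.center, rec.angle, size)
        if output_side is not None:
            patch = resize_image(patch, output_side)
        patches.append(patch)
        labels.append(CLASS_NAMES.index(rec.label))
    return np.stack(patches), np.asarray(labels, dtype=np.int64)


def random_oversample(manifest: DatasetManifest, rng_seed: int) -> DatasetManifest:
    """Random over-sampling baseline: duplicate minority-class entries.

    Entries of every minority class are duplicated uniformly at random until
    all classes match the majority count.  The original multiset of samples
    is preserved (duplicates reference the same images).
    """
    if len(manifest) == 0:
        raise ValueError("cannot oversample an empty manifest")
    rng = np.random.default_rng(rng_seed)
    counts = manifest.class_counts
    target = max(counts.values())
    samples = list(manifest.samples)
    for cls in CLASS_NAMES:
        pool = [s for s in manifest.samples if s.label == cls]
        if not pool or counts[cls] == target:
            continue
        extra = target - counts[cls]
        picks = rng.integers(0, len(pool), size=extra)
        samples.extend(pool[int(i)] for i in picks)
    return DatasetManifest(samples=samples, split=dict(manifest.split))
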