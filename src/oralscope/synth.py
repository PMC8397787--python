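"""Synthetic oral-cavity image generator.

Real clinical photographs of the oral cavity cannot be redistributed, so this
module generates labeled stand-ins with the statistical and geometric
structure the rest of the pipeline assumes:

* 4:3 aspect-ratio frames of textured pink mucosa;
* at most one lesion per image, drawn with a class-specific procedural
  signature (see :data:`CLASS_STYLES`) so that the five categories are
  separable by a small convolutional classifier;
* a capture protocol: ``centered`` places the lesion uniformly inside the
  central cell of the camera's 3x3 grid with a diameter slightly smaller
  than that cell, ``random`` places it anywhere that keeps it in frame;
* a patient structure in which healthy subjects contribute several images
  (different anatomic sites) while lesion patients contribute about one.

The renderings are deliberate caricatures — texture plus color statistics,
not photorealism — because only class separability and framing geometry
matter to the downstream training and ablation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from ._seeds import derive_seed
from .samples import CLASS_NAMES, DatasetManifest, ImageSample, canonical_label

__all__ = [
    "LesionSpec",
    "CLASS_STYLES",
    "render_oral_image",
    "place_lesion",
    "generate_manifest",
    "render_manifest",
    "generate_dataset",
]


@dataclass
class LesionSpec:
    """Geometry and appearance parameters for a single rendered lesion.

    ``irregularity`` in [0, 1] controls how far the lesion boundary departs
    from a circle (0 = smooth disc).  For the ``normal`` class there is no
    lesion and ``diameter`` is treated as 0.
    """

    class_label: str
    center: tuple[float, float] = (0.0, 0.0)  # (row, col) pixels
    diameter: float = 0.0
    irregularity: float = 0.3
    color_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.class_label = canonical_label(self.class_label)
        if self.class_label == "normal":
            self.diameter = 0.0
        if not 0.0 <= self.irregularity <= 1.0:
            raise ValueError(f"irregularity must be in [0,1], got {self.irregularity}")


#: Per-class visual signature: colors are RGB in [0,255]; the geometry keys
#: shape the intra-lesion texture.  Healthy mucosa: homogeneous pink, shiny.
#: Ulcer: yellow pseudomembrane core with an erythematous (red) halo.
#: Low-risk OPMD: uniform flat thin white patch.  High-risk OPMD: red
#: components mixed into white patches, irregular surface.  Cancer: dark
#: nodular mass with rough surface and unclear boundary.
CLASS_STYLES: dict[str, dict] = {
    "normal": {},
    "ulcer": {
        "core_color": (228.0, 215.0, 148.0),
        "halo_color": (188.0, 58.0, 58.0),
        "core_fraction": 0.62,
        "irregularity": 0.15,
    },
    "low_risk": {
        "patch_color": (230.0, 222.0, 206.0),
        "texture_amp": 4.0,
        "irregularity": 0.25,
    },
    "high_risk": {
        "patch_color": (224.0, 214.0, 198.0),
        "blotch_color": (172.0, 52.0, 62.0),
        "blotch_fraction": 0.42,
        "irregularity": 0.55,
    },
    "cancer": {
        "mass_color": (122.0, 44.0, 50.0),
        "bump_amp": 38.0,
        "irregularity": 0.75,
    },
}

_BACKGROUND_RGB = np.array([196.0, 126.0, 132.0])  # pink mucosa


def _check_aspect(height: int, width: int) -> None:
    if height <= 0 or width <= 0 or width * 3 != height * 4:
        raise ValueError(
            f"image must have 4:3 aspect ratio (width/height = 4/3); got {height}x{width}"
        )


def _mucosa_background(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Textured pink background with smooth illumination and specular sheen."""
    img = np.empty((height, width, 3), dtype=np.float64)
    img[:] = _BACKGROUND_RGB * rng.uniform(0.96, 1.04, 3)  # subject-to-subject tone
    # low-frequency mottling, stronger in the red channel
    low = gaussian_filter(rng.normal(0.0, 1.0, (height, width)), sigma=height / 10.0)
    low *= 18.0 / (np.std(low) + 1e-9)
    img += low[:, :, None] * np.array([1.0, 0.55, 0.55])
    # smooth illumination gradient (hand-held lighting)
    gy, gx = rng.normal(0.0, 10.0, 2)
    rows = np.linspace(-0.5, 0.5, height)[:, None]
    cols = np.linspace(-0.5, 0.5, width)[None, :]
    img += (gy * rows + gx * cols)[:, :, None]
    # a shiny highlight patch
    hr = rng.uniform(0.2, 0.8) * height
    hc = rng.uniform(0.2, 0.8) * width
    yy, xx = np.mgrid[0:height, 0:width]
    d2 = ((yy - hr) / (0.25 * height)) ** 2 + ((xx - hc) / (0.25 * width)) ** 2
    img += (28.0 * np.exp(-d2))[:, :, None]
    return img


def _lesion_fields(
    spec: LesionSpec, height: int, width: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Soft lesion mask and normalized radial coordinate u = r / boundary(phi)."""
    cr, cc = spec.center
    yy, xx = np.mgrid[0:height, 0:width]
    dy = yy - cr
    dx = xx - cc
    r = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    radius = np.full_like(r, spec.diameter / 2.0)
    # irregular boundary: low-order random harmonics of the polar angle
    boundary = np.ones_like(phi)
    for k in range(2, 6):
        amp = spec.irregularity * rng.uniform(0.0, 0.28) / (k - 1)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        boundary += amp * np.cos(k * phi + phase)
    radius = radius * boundary
    u = r / np.maximum(radius, 1e-9)
    edge = max(1.5, 0.04 * spec.diameter)
    mask = 1.0 / (1.0 + np.exp((r - radius) / edge))
    return mask, u


def render_oral_image(
    spec: LesionSpec, height: int, width: int, rng_seed: int
) -> ImageSample:
    """Render one synthetic oral-cavity photograph.

    Deterministic for a fixed ``rng_seed``.  The frame must be 4:3; a
    non-normal lesion must fit inside it (center plus nominal radius within
    bounds), otherwise a ``ValueError`` states the violated bounds.
    """
    _check_aspect(height, width)
    rng = np.random.default_rng(rng_seed)
    img = _mucosa_background(height, width, rng)

    cls = spec.class_label
    if cls != "normal":
        cr, cc = spec.center
        rad = spec.diameter / 2.0
        if not (0 <= cr < height and 0 <= cc < width):
            raise ValueError(
                f"lesion center {spec.center} outside image bounds "
                f"[0,{height}) x [0,{width})"
            )
        if cr - rad < 0 or cr + rad > height or cc - rad < 0 or cc + rad > width:
            raise ValueError(
                f"lesion of diameter {spec.diameter} at {spec.center} exceeds the "
                f"{height}x{width} frame; center must be at least {rad:.1f} px from "
                "every border"
            )
        style = dict(CLASS_STYLES[cls])
        # per-lesion appearance variability: clinical presentations of one
        # class differ markedly in tone and internal structure, so palette
        # colors get a per-channel scale and structural parameters jitter
        color_scale = rng.uniform(0.85, 1.15, 3)
        for key in ("core_color", "halo_color", "patch_color", "blotch_color", "mass_color"):
            if key in style:
                style[key] = tuple(np.asarray(style[key]) * color_scale)
        for key, lo, hi in (
            ("core_fraction", 0.8, 1.15),
            ("blotch_fraction", 0.75, 1.25),
            ("bump_amp", 0.7, 1.3),
            ("texture_amp", 0.6, 1.6),
        ):
            if key in style:
                style[key] = style[key] * rng.uniform(lo, hi)
        style.update(spec.color_overrides)
        mask, u = _lesion_fields(spec, height, width, rng)
        paint = np.empty_like(img)
        if cls == "ulcer":
            core = np.clip((style["core_fraction"] - u) / 0.12 + 0.5, 0.0, 1.0)
            paint[:] = np.asarray(style["halo_color"])
            paint += core[:, :, None] * (
                np.asarray(style["core_color"]) - np.asarray(style["halo_color"])
            )
        elif cls == "low_risk":
            tex = gaussian_filter(
                rng.normal(0.0, 1.0, (height, width)), sigma=max(1.0, spec.diameter / 12)
            )
            tex *= style["texture_amp"] / (np.std(tex) + 1e-9)
            paint[:] = np.asarray(style["patch_color"])
            paint += tex[:, :, None]
        elif cls == "high_risk":
            blotch = gaussian_filter(
                rng.normal(0.0, 1.0, (height, width)), sigma=max(1.0, spec.diameter / 9)
            )
            thr = np.quantile(blotch, 1.0 - style["blotch_fraction"])
            w = np.clip((blotch - thr) / (np.std(blotch) * 0.5 + 1e-9) + 0.5, 0.0, 1.0)
            paint[:] = np.asarray(style["patch_color"])
            paint += w[:, :, None] * (
                np.asarray(style["blotch_color"]) - np.asarray(style["patch_color"])
            )
        elif cls == "cancer":
            bump = gaussian_filter(
                rng.normal(0.0, 1.0, (height, width)), sigma=max(1.0, spec.diameter / 14)
            )
            bump *= style["bump_amp"] / (np.std(bump) + 1e-9)
            paint[:] = np.asarray(style["mass_color"])
            paint += bump[:, :, None]
            # nodular: brighter protruding center, darker rim
            paint += (18.0 * (1.0 - np.clip(u, 0.0, 1.0)) - 8.0)[:, :, None]
        img = img * (1.0 - 0.96 * mask[:, :, None]) + paint * (0.96 * mask[:, :, None])

    img += rng.normal(0.0, 3.0, img.shape)  # sensor noise
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageSample(
        label=cls,
        patient_id="",
        source_id="",
        protocol="centered",
        pixels=pixels,
        lesion_center=None if cls == "normal" else tuple(map(float, spec.center)),
        lesion_diameter=None if cls == "normal" else float(spec.diameter),
    )


def place_lesion(
    protocol: str,
    image_size: tuple[int, int],
    diameter: float,
    rng_seed: int,
) -> tuple[int, int]:
    """Draw a lesion center consistent with a capture protocol.

    ``centered``: the center is uniform over the central ninth of the 3x3
    camera grid (rows ``[H//3, 2H//3)``, cols ``[W//3, 2W//3)``), and the
    diameter must be at most 0.9x the central cell side (``min(H, W) / 3``)
    — the "slightly smaller than the central grid cell" framing rule.

    ``random``: the center is uniform over every position that keeps the
    nominal lesion disc fully inside the frame.
    """
    height, width = image_size
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    rng = np.random.default_rng(rng_seed)
    if protocol == "centered":
        cell = min(height, width) / 3.0
        if diameter > 0.9 * cell:
            raise ValueError(
                f"centered protocol requires diameter <= 0.9 x central cell side "
                f"({0.9 * cell:.0f} px for a {height}x{width} frame); got {diameter}"
            )
        row = int(rng.integers(height // 3, 2 * height // 3))
        col = int(rng.integers(width // 3, 2 * width // 3))
        return row, col
    if protocol == "random":
        margin = int(np.ceil(diameter / 2.0))
        if 2 * margin >= min(height, width):
            raise ValueError(
                f"diameter {diameter} cannot fit inside a {height}x{width} frame"
            )
        row = int(rng.integers(margin, height - margin))
        col = int(rng.integers(margin, width - margin))
        return row, col
    raise ValueError(f"protocol must be 'centered' or 'random', got {protocol!r}")


# ---------------------------------------------------------------------------
# patient / manifest structure


def _truncated_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (> 1)."""
    if mean <= 1.0 + 1e-12:
        return 0.0
    return brentq(
        lambda lam: lam / (1.0 - np.exp(-lam)) - mean, 1e-9, max(10.0 * mean, 10.0)
    )


def _patient_image_counts(n: int, mean: float, rng: np.random.Generator) -> list[int]:
    """Per-patient image counts: zero-truncated Poisson shaped, summing to n.

    The number of patients is pinned at ``round(n / mean)`` and the sampled
    counts are repaired by +-1 increments so they sum exactly to ``n``; this
    keeps the patient count essentially deterministic while preserving the
    spread of images per patient.
    """
    if n <= 0:
        return []
    if mean <= 1.0 + 1e-12:
        return [1] * n
    k = max(1, round(n / mean))
    if k >= n:
        return [1] * n
    lam = _truncated_poisson_lambda(mean)
    counts = rng.poisson(lam, size=k)
    while np.any(counts == 0):
        zeros = counts == 0
        counts[zeros] = rng.poisson(lam, size=int(zeros.sum()))
    total = int(counts.sum())
    while total != n:
        i = int(rng.integers(0, k))
        if total > n:
            if counts[i] > 1:
                counts[i] -= 1
                total -= 1
        else:
            counts[i] += 1
            total += 1
    return [int(c) for c in counts]


#: Table-style defaults for mean images per patient, one per class: healthy
#: subjects are photographed at several anatomic sites; OPMD patients are
#: somewhat likely to have multifocal lesions; cancer patients contribute one.
DEFAULT_IMAGES_PER_PATIENT: tuple[float, ...] = (3.28, 1.15, 1.40, 1.32, 1.00)


def generate_manifest(
    n_per_class: Sequence[int],
    images_per_normal_patient: float = 3.28,
    rng_seed: int = 0,
    protocol: str = "centered",
    images_per_patient: Sequence[float] | None = None,
) -> DatasetManifest:
    """Build a metadata-only manifest with a realistic patient structure.

    ``n_per_class`` gives the image count for each of the five classes in
    :data:`~oralscope.samples.CLASS_NAMES` order.  ``images_per_patient``
    optionally overrides the per-class mean images/patient (defaults to
    :data:`DEFAULT_IMAGES_PER_PATIENT`, with the normal-class entry replaced
    by ``images_per_normal_patient``).
    """
    if len(n_per_class) != len(CLASS_NAMES):
        raise ValueError(f"n_per_class must have {len(CLASS_NAMES)} entries")
    if any(n < 0 for n in n_per_class):
        raise ValueError("n_per_class entries must be >= 0")
    means = list(images_per_patient or DEFAULT_IMAGES_PER_PATIENT)
    if images_per_patient is None:
        means[0] = float(images_per_normal_patient)
    rng = np.random.default_rng(rng_seed)
    samples: list[ImageSample] = []
    for ci, (cls, n) in enumerate(zip(CLASS_NAMES, n_per_class)):
        counts = _patient_image_counts(int(n), float(means[ci]), rng)
        s = 0
        for pi, c in enumerate(counts):
            pid = f"{cls}_p{pi:04d}"
            for _ in range(c):
                samples.append(
                    ImageSample(
                        label=cls,
                        patient_id=pid,
                        source_id=f"{cls}_s{s:05d}",
                        protocol=protocol,
                    )
                )
                s += 1
    return DatasetManifest(samples=samples)


def render_manifest(
    manifest: DatasetManifest,
    height: int = 768,
    width: int = 1024,
    rng_seed: int = 0,
    diameter_fraction: tuple[float, float] = (0.5, 0.9),
) -> DatasetManifest:
    """Fill in pixels for every sample of a metadata-only manifest.

    Lesion diameters are drawn uniformly from ``diameter_fraction`` times the
    central-grid-cell side (``min(height, width) / 3``); positions follow each
    sample's capture protocol.  Deterministic given ``rng_seed`` (each sample
    derives its own seed from its source id).
    """
    _check_aspect(height, width)
    cell = min(height, width) / 3.0
    rendered: list[ImageSample] = []
    for sample in manifest.samples:
        seed = derive_seed(rng_seed, f"render:{sample.source_id}")
        rng = np.random.default_rng(seed)
        if sample.label == "normal":
            spec = LesionSpec(class_label="normal")
        else:
            diameter = float(rng.uniform(*diameter_fraction) * cell)
            center = place_lesion(
                sample.protocol, (height, width), diameter,
                derive_seed(seed, "place"),
            )
            irr = CLASS_STYLES[sample.label].get("irregularity", 0.3)
            spec = LesionSpec(
                class_label=sample.label,
                center=center,
                diameter=diameter,
                irregularity=irr,
            )
        img = render_oral_image(spec, height, width, derive_seed(seed, "pixels"))
        rendered.append(
            ImageSample(
                label=sample.label,
                patient_id=sample.patient_id,
                source_id=sample.source_id,
                protocol=sample.protocol,
                pixels=img.pixels,
                path=sample.path,
                lesion_center=img.lesion_center,
                lesion_diameter=img.lesion_diameter,
            )
        )
    return DatasetManifest(samples=rendered, split=dict(manifest.split))


def generate_dataset(
    n_per_class: Sequence[int],
    height: int = 768,
    width: int = 1024,
    rng_seed: int = 0,
    protocol: str = "centered",
    images_per_normal_patient: float = 3.28,
) -> DatasetManifest:
    """Convenience: :func:`generate_manifest` followed by :func:`render_manifest`."""
    manifest = generate_manifest(
        n_per_class,
        images_per_normal_patient=images_per_normal_patient,
        rng_seed=derive_seed(rng_seed, "manifest"),
        protocol=protocol,
    )
    return render_manifest(
        manifest, height=height, width=width, rng_seed=derive_seed(rng_seed, "render")
    )
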