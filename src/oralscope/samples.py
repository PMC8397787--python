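"""Core dataset containers: labeled image samples and manifests.

The five diagnostic categories are: healthy mucosa (``normal``), aphthous
ulcer (``ulcer``), homogeneous / low-risk OPMD (``low_risk``), nonhomogeneous
/ high-risk OPMD (``high_risk``) and oral cancer (``cancer``).  OPMD = oral
potentially malignant disorder.

A :class:`DatasetManifest` is the unit every pipeline stage consumes: a list
of :class:`ImageSample` plus an optional train/test split that is always
patient-disjoint (no patient contributes images to both sides).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "class_index",
    "ImageSample",
    "DatasetManifest",
    "split_by_patient",
]

CLASS_NAMES: tuple[str, ...] = ("normal", "ulcer", "low_risk", "high_risk", "cancer")

_ALIASES = {
    "normal": "normal",
    "healthy": "normal",
    "ulcer": "ulcer",
    "aphthous ulcer": "ulcer",
    "aphthous_ulcer": "ulcer",
    "low_risk": "low_risk",
    "low-risk": "low_risk",
    "low_risk_opmd": "low_risk",
    "high_risk": "high_risk",
    "high-risk": "high_risk",
    "high_risk_opmd": "high_risk",
    "cancer": "cancer",
    "oral cancer": "cancer",
}


def canonical_label(label: str) -> str:
    """Map a label string (case/space-insensitive) to its canonical token."""
    key = str(label).strip().lower().replace("-", "_")
    key2 = key.replace(" ", "_")
    for k in (key, key2):
        if k in _ALIASES:
            return _ALIASES[k]
    raise ValueError(
        f"unknown class label {label!r}; expected one of {CLASS_NAMES}"
    )


def class_index(label: str) -> int:
    """Integer index of a (canonical or alias) class label."""
    return CLASS_NAMES.index(canonical_label(label))


@dataclass
class ImageSample:
    """One RGB photograph with its diagnostic label and provenance.

    ``pixels`` is an H x W x 3 uint8 array (may be ``None`` for
    metadata-only manifests, in which case ``path`` locates the image on
    disk).  ``protocol`` records how the lesion was framed at capture time:
    ``"centered"`` (lesion inside the central cell of the camera's 3x3 grid)
    or ``"random"`` (no framing constraint).
    """

    label: str
    patient_id: str
    source_id: str
    protocol: str = "centered"
    pixels: np.ndarray | None = None
    path: str | None = None
    lesion_center: tuple[float, float] | None = None
    lesion_diameter: float | None = None

    def __post_init__(self) -> None:
        self.label = canonical_label(self.label)
        if self.protocol not in ("centered", "random"):
            raise ValueError(f"protocol must be 'centered' or 'random', got {self.protocol!r}")
        if self.pixels is not None:
            px = np.asarray(self.pixels)
            if px.ndim != 3 or px.shape[2] != 3:
                raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
            self.pixels = px

    @property
    def label_index(self) -> int:
        return CLASS_NAMES.index(self.label)


@dataclass
class DatasetManifest:
    """A collection of samples with an optional patient-disjoint split."""

    samples: list[ImageSample] = field(default_factory=list)
    #: map source_id -> "train" | "test"; empty until a split is assigned
    split: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = Counter(s.label for s in self.samples)
        return {name: counts.get(name, 0) for name in CLASS_NAMES}

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    def subset(self, which: str) -> "DatasetManifest":
        """Samples assigned to split ``which`` ('train' or 'test')."""
        if which not in ("train", "test"):
            raise ValueError("which must be 'train' or 'test'")
        picked = [s for s in self.samples if self.split.get(s.source_id) == which]
        return DatasetManifest(samples=picked, split={s.source_id: which for s in picked})

    def validate_split(self) -> None:
        """Raise if any patient appears on both sides of the split."""
        sides: dict[str, set[str]] = {}
        for s in self.samples:
            side = self.split.get(s.source_id)
            if side is not None:
                sides.setdefault(s.patient_id, set()).add(side)
        leaked = sorted(p for p, ss in sides.items() if len(ss) > 1)
        if leaked:
            raise ValueError(f"patients present in both train and test: {leaked[:10]}")


def split_by_patient(
    manifest: DatasetManifest,
    test_fraction: float | Mapping[str, float] = 0.3,
    rng_seed: int = 0,
) -> DatasetManifest:
    """Assign a patient-disjoint train/test split.

    ``test_fraction`` is the target fraction of *images* per class placed in
    the test set; it may be a single float or a per-class mapping (the study
    design oversamples the harmful classes into the test set, e.g. 0.37 for
    high-risk OPMD and 0.46 for cancer).  Whole patients are moved greedily
    per class until the target is reached, so the achieved fraction is
    approximate whenever patients contribute several images.
    """
    rng = np.random.default_rng(rng_seed)
    if isinstance(test_fraction, Mapping):
        fractions = {c: float(test_fraction.get(c, 0.0)) for c in CLASS_NAMES}
    else:
        fractions = {c: float(test_fraction) for c in CLASS_NAMES}

    split: dict[str, str] = {s.source_id: "train" for s in manifest.samples}
    for cls in CLASS_NAMES:
        cls_samples = [s for s in manifest.samples if s.label == cls]
        if not cls_samples:
            continue
        target = int(round(fractions[cls] * len(cls_samples)))
        by_patient: dict[str, list[ImageSample]] = {}
        for s in cls_samples:
            by_patient.setdefault(s.patient_id, []).append(s)
        patients = list(by_patient)
        rng.shuffle(patients)
        # greedy with exact fit: skip patients that would overshoot, then
        # top up minimally if no exact combination was found
        placed = 0
        leftover = []
        for pid in patients:
            size = len(by_patient[pid])
            if placed + size <= target:
                for s in by_patient[pid]:
                    split[s.source_id] = "test"
                placed += size
            else:
                leftover.append(pid)
        if placed < target and leftover:
            pid = min(leftover, key=lambda p: len(by_patient[p]))
            for s in by_patient[pid]:
                split[s.source_id] = "test"
    # a patient with images in several classes could end up straddling the
    # split; promote such patients wholly to the test side
    test_patients = {s.patient_id for s in manifest.samples if split[s.source_id] == "test"}
    for s in manifest.samples:
        if s.patient_id in test_patients:
            split[s.source_id] = "test"
    out = DatasetManifest(samples=list(manifest.samples), split=split)
    out.validate_split()
    return out
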