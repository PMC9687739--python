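"""Geometric augmentation: the seven flip/rotate variants of each image.

Each source image yields seven transformed copies (horizontal flip, vertical
flip, both flips, +/-30 degree rotations, and the rotations followed by a
horizontal flip), so a dataset grows exactly eightfold once the originals are
retained.  Flips are exact pixel permutations; rotations keep the original
canvas, interpolate bilinearly and fill the exposed corners with black,
matching the mammogram background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import rotate as _rotate

__all__ = ["TRANSFORM_NAMES", "AugmentSet", "augment_image", "augment_dataset"]

TRANSFORM_NAMES = (
    "hflip",
    "vflip",
    "hvflip",
    "rot+30",
    "rot+30+hflip",
    "rot-30",
    "rot-30+hflip",
)


@dataclass
class AugmentSet:
    """The ordered set of seven augmentations and their rendering options."""

    transforms: tuple[str, ...] = TRANSFORM_NAMES
    rotation_fill: int = 0
    interpolation: str = "bilinear"  # or "nearest"

    def validate(self) -> None:
        if len(self.transforms) != 7 or len(set(self.transforms)) != 7:
            raise ValueError("exactly seven uniquely named transforms required")
        unknown = set(self.transforms) - set(TRANSFORM_NAMES)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")
        if self.interpolation not in ("nearest", "bilinear"):
            raise ValueError("interpolation must be 'nearest' or 'bilinear'")


def _rot(img: np.ndarray, angle: float, aset: AugmentSet) -> np.ndarray:
    order = 0 if aset.interpolation == "nearest" else 1
    out = _rotate(
        img.astype(float),
        angle,
        resize=False,
        order=order,
        cval=aset.rotation_fill,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _apply_one(img: np.ndarray, name: str, aset: AugmentSet) -> np.ndarray:
    if name == "hflip":
        return img[:, ::-1].copy()
    if name == "vflip":
        return img[::-1, :].copy()
    if name == "hvflip":
        return img[::-1, ::-1].copy()
    if name == "rot+30":
        return _rot(img, 30.0, aset)
    if name == "rot+30+hflip":
        return _rot(img, 30.0, aset)[:, ::-1].copy()
    if name == "rot-30":
        return _rot(img, -30.0, aset)
    if name == "rot-30+hflip":
        return _rot(img, -30.0, aset)[:, ::-1].copy()
    raise ValueError(f"unknown transform {name!r}")


def augment_image(
    img: np.ndarray, aset: AugmentSet | None = None
) -> list[np.ndarray]:
    """The seven augmented variants of one image, in the set's order."""
    aset = aset or AugmentSet()
    aset.validate()
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    img = img.astype(np.uint8)
    return [_apply_one(img, name, aset) for name in aset.transforms]


@dataclass
class AugmentedDataset:
    images: list
    labels: list
    provenance: list = field(default_factory=list)  # (source index, transform)


def augment_dataset(
    images: list, labels: list, aset: AugmentSet | None = None
) -> AugmentedDataset:
    """Grow a labelled image set exactly 8x (originals plus 7 variants each).

    Every augmented image inherits its source's label; provenance records the
    source index and transform name ('original' for the untouched copy).
    """
    aset = aset or AugmentSet()
    aset.validate()
    if len(images) != len(labels):
        raise ValueError("images and labels must be aligned")
    out_images, out_labels, prov = [], [], []
    for i, (img, lab) in enumerate(zip(images, labels)):
        out_images.append(np.asarray(img, dtype=np.uint8).copy())
        out_labels.append(lab)
        prov.append((i, "original"))
        for name, aug in zip(aset.transforms, augment_image(img, aset)):
            out_images.append(aug)
            out_labels.append(lab)
            prov.append((i, name))
    return AugmentedDataset(images=out_images, labels=out_labels, provenance=prov)
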