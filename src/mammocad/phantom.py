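"""Synthetic mammogram phantoms with ground-truth masks.

Real craniocaudal (CC) screening mammograms show a bright breast region
against a black background, with the lesion (calcification or mass) as the
brightest spot, dense tissue slightly darker than the lesion, and a set of
acquisition artefacts: a white border frame, bright text/marker blobs outside
the breast, and a near-vertical white line touching the breast edge.  The
generator here reproduces exactly those ingredients as a seeded, fully
deterministic phantom, together with the ground-truth breast, lesion and
artefact masks, so every downstream stage (artefact removal, enhancement,
segmentation, feature extraction, classification) can be exercised and scored
without any image download.

A companion generator emits a labelled 4-class numeric feature table with a
controllable class separation, standing in for the table of descriptors
extracted from real lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "FeatureTableSpec",
    "generate_phantom",
    "generate_feature_table",
]


@dataclass
class PhantomSpec:
    """Geometry, intensity and artefact parameters of one phantom.

    The breast is a vertically oriented half-ellipse flush with the left
    image edge (CC-view convention).  The lesion is a uniform disk at the
    image's maximum artefact-free intensity; dense-tissue texture is
    Gaussian-blurred noise whose level stays well below the lesion.
    """

    width: int = 224
    height: int = 224
    breast_center_row: int | None = None  # defaults to height // 2
    breast_semi_axis_col: int | None = None  # defaults to 0.62 * width
    breast_semi_axis_row: int | None = None  # defaults to 0.45 * height
    breast_base_intensity: int = 120
    tissue_texture_sigma: float = 8.0
    lesion_center: tuple[int, int] | None = None  # defaults near breast core
    lesion_radius: int = 12
    lesion_intensity: int = 250
    dense_patch_center: tuple[int, int] | None = None
    dense_patch_radius: int = 8
    dense_patch_intensity: int | None = None  # defaults to lesion - 8
    border_frame: bool = True
    text_blob: bool = True
    vertical_line: bool = True
    border_thickness: int = 3
    rng_seed: int = 0

    def resolved(self) -> "PhantomSpec":
        """Return a copy with all defaulted geometry filled in."""
        spec = PhantomSpec(**asdict(self))
        if spec.breast_center_row is None:
            spec.breast_center_row = spec.height // 2
        if spec.breast_semi_axis_col is None:
            spec.breast_semi_axis_col = int(0.62 * spec.width)
        if spec.breast_semi_axis_row is None:
            spec.breast_semi_axis_row = int(0.45 * spec.height)
        if spec.lesion_center is None:
            spec.lesion_center = (
                spec.breast_center_row,
                int(0.30 * spec.breast_semi_axis_col),
            )
        if spec.dense_patch_intensity is None:
            spec.dense_patch_intensity = spec.lesion_intensity - 8
        return spec

    def validate(self) -> None:
        spec = self.resolved()
        if spec.width <= 0 or spec.height <= 0:
            raise ValueError("phantom dimensions must be positive")
        if not (0 <= spec.breast_base_intensity <= 255):
            raise ValueError("breast_base_intensity outside [0, 255]")
        if not (0 <= spec.lesion_intensity <= 255):
            raise ValueError("lesion_intensity outside [0, 255]")
        margin = spec.lesion_intensity - spec.breast_base_intensity
        if margin <= 3 * spec.tissue_texture_sigma:
            raise ValueError(
                "lesion_intensity must exceed breast_base_intensity by more "
                "than 3x tissue_texture_sigma so the lesion is the image "
                "maximum"
            )
        r, c = spec.lesion_center
        rad = spec.lesion_radius
        if not _disk_inside_breast(spec, r, c, rad):
            raise ValueError("lesion disk must lie fully inside the breast")
        if spec.dense_patch_center is not None:
            pr, pc = spec.dense_patch_center
            if not _disk_inside_breast(spec, pr, pc, spec.dense_patch_radius):
                raise ValueError("dense patch must lie fully inside the breast")


def _disk_inside_breast(spec: PhantomSpec, row: int, col: int, radius: int) -> bool:
    a = spec.breast_semi_axis_col
    b = spec.breast_semi_axis_row
    cr = spec.breast_center_row
    # conservative: shrink the ellipse by the disk radius
    aa, bb = a - radius, b - radius
    if aa <= 0 or bb <= 0:
        return False
    return (col / aa) ** 2 + ((row - cr) / bb) ** 2 <= 1.0 and col - radius >= 0


@dataclass
class PhantomTruth:
    """A generated phantom image plus its ground-truth masks."""

    image: np.ndarray  # uint8, (height, width)
    breast_mask: np.ndarray  # bool
    lesion_mask: np.ndarray  # bool
    artefact_mask: np.ndarray  # bool
    spec: PhantomSpec = field(repr=False, default=None)


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom mammogram and its ground-truth masks.

    Deterministic: the same spec (including ``rng_seed``) always yields a
    bit-identical image.  The global intensity maximum of the artefact-free
    image area is attained only inside the lesion mask.
    """
    spec.validate()
    spec = spec.resolved()
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w]

    a = spec.breast_semi_axis_col
    b = spec.breast_semi_axis_row
    cr = spec.breast_center_row
    breast = (cols / a) ** 2 + ((rows - cr) / b) ** 2 <= 1.0

    img = np.zeros((h, w), dtype=float)
    texture = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
    texture *= spec.tissue_texture_sigma / max(texture.std(), 1e-12)
    img[breast] = spec.breast_base_intensity + texture[breast]
    # texture must never reach the lesion level
    np.clip(img, 0, spec.lesion_intensity - 3 * 1.0 - 2, out=img)

    lesion = (rows - spec.lesion_center[0]) ** 2 + (
        cols - spec.lesion_center[1]
    ) ** 2 <= spec.lesion_radius**2
    img[lesion] = spec.lesion_intensity

    if spec.dense_patch_center is not None:
        patch = (rows - spec.dense_patch_center[0]) ** 2 + (
            cols - spec.dense_patch_center[1]
        ) ** 2 <= spec.dense_patch_radius**2
        img[patch] = spec.dense_patch_intensity

    artefact = np.zeros((h, w), dtype=bool)
    if spec.border_frame:
        t = spec.border_thickness
        frame = np.zeros((h, w), dtype=bool)
        frame[:t, :] = frame[-t:, :] = True
        frame[:, :t] = frame[:, -t:] = True
        img[frame] = 255
        artefact |= frame
    if spec.text_blob:
        # 2-4 bright rectangles in the corner opposite the breast (top right)
        n_blobs = int(rng.integers(2, 5))
        for _ in range(n_blobs):
            bh = int(rng.integers(max(2, h // 56), max(3, h // 25) + 1))
            bw = int(rng.integers(max(3, w // 28), max(4, w // 11) + 1))
            r0_lo = min(max(2, h // 28), max(1, h - bh - 1))
            r0_hi = max(r0_lo + 1, h // 5)
            r0 = int(rng.integers(r0_lo, r0_hi))
            c0_lo = max(0, w - w // 4)
            c0_hi = max(c0_lo + 1, w - bw)
            c0 = int(rng.integers(c0_lo, c0_hi))
            blob = np.zeros((h, w), dtype=bool)
            blob[r0 : r0 + bh, c0 : c0 + bw] = True
            blob &= ~breast  # text never overlaps the breast
            img[blob] = 255
            artefact |= blob
    if spec.vertical_line:
        # near-vertical white line touching the breast's right extent
        line_col = min(a + 2, w - 4)
        line = np.zeros((h, w), dtype=bool)
        line[h // 6 : h - h // 6, line_col : line_col + 2] = True
        img[line] = 255
        artefact |= line

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return PhantomTruth(
        image=img,
        breast_mask=breast,
        lesion_mask=lesion,
        artefact_mask=artefact,
        spec=spec,
    )


@dataclass
class FeatureTableSpec:
    """Parameters of the synthetic 4-class feature table.

    Informative columns are class-conditional Gaussians whose class means are
    ``class_separation`` pooled standard deviations apart; noise columns are
    class-independent standard normals.
    """

    n_per_class: int = 50
    n_classes: int = 4
    n_features: int = 16
    class_separation: float = 3.0
    noise_features: int = 4
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.noise_features > self.n_features:
            raise ValueError("noise_features cannot exceed n_features")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")


def generate_feature_table(spec: FeatureTableSpec) -> pd.DataFrame:
    """Simulate a labelled numeric feature table with controllable separation.

    Returns a DataFrame with ``spec.n_features`` float columns plus an integer
    ``label`` column coded 0..n_classes-1 (uniform class priors by
    construction).  Informative feature ``j`` carries a mean offset of
    ``class_separation`` (in units of the within-class standard deviation)
    for class ``j % n_classes``, so every class is linearly separable from the
    rest once ``class_separation`` is large.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n_rows = spec.n_per_class * spec.n_classes
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    X = rng.standard_normal((n_rows, spec.n_features))
    n_informative = spec.n_features - spec.noise_features
    for j in range(n_informative):
        cls = j % spec.n_classes
        X[labels == cls, j] += spec.class_separation
    names = [f"f{j:02d}" for j in range(spec.n_features)]
    table = pd.DataFrame(X, columns=names)
    table["label"] = labels
    # shuffle rows so splits see no class ordering
    order = rng.permutation(n_rows)
    return table.iloc[order].reset_index(drop=True)
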