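"""Dynamic-threshold seeded region growing for lesion (ROI) segmentation.

On a cleaned, enhanced mammogram the lesion is the brightest structure, but a
single global cutoff fails across images: dense tissue can sit only a few
grey levels below the lesion, and in some images the brightest level is held
by just a handful of pixels while the lesion body lies slightly lower.  The
segmenter therefore derives a per-image threshold from two statistics — the
brightest intensity and the "near-brightest" band just below it:

* if at least ``min_region`` pixels sit at the image maximum, the maximum
  itself is a usable threshold (``MAX_SUFFICIENT`` branch);
* otherwise the brightest level is too sparse to cover the lesion body and
  the threshold relaxes to ``max - delta`` (``NEAR_MAX_EXPANDED`` branch).

The seed is the rounded centroid of the brightest-pixel set (snapped to the
nearest above-threshold pixel when the centroid of a disjoint set falls on
dark background), and the ROI is the seed's connected component of the
above-threshold pixel set, grown by flood fill.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ThresholdDiagnostics",
    "ROIResult",
    "compute_dynamic_threshold",
    "find_seed",
    "region_grow",
    "extract_roi",
    "RegionGrowingSegmenter",
]

MAX_SUFFICIENT = "MAX_SUFFICIENT"
NEAR_MAX_EXPANDED = "NEAR_MAX_EXPANDED"


@dataclass
class ThresholdDiagnostics:
    """Brightest/near-brightest statistics and the threshold decision."""

    max_intensity: int
    near_max_intensity: int
    count_max: int
    count_near_max: int
    chosen_threshold: int
    rule_fired: str

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ROIResult:
    """Segmentation output: mask, seed, diagnostics and the masked image."""

    mask: np.ndarray  # bool
    seed: tuple[int, int]
    diagnostics: ThresholdDiagnostics
    roi_image: np.ndarray  # uint8; input where mask, else 0


def compute_dynamic_threshold(
    img: np.ndarray, delta: int = 10, min_region: int = 10
) -> ThresholdDiagnostics:
    """Per-image intensity threshold from brightest-pixel statistics.

    ``count_max`` is the number of pixels at the image maximum and
    ``count_near_max`` the number in ``[max - delta, max)``.  The threshold is
    the maximum when the brightest level alone already covers at least
    ``min_region`` pixels, else ``max - delta`` (floored at 0), so lesions
    whose brightest level is sparse keep their near-brightest body.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if delta < 0 or min_region < 1:
        raise ValueError("delta must be >= 0 and min_region >= 1")
    if not (img > 0).any():
        raise ValueError("all-zero image: no breast content to segment")
    max_int = int(img.max())
    near = max(max_int - delta, 0)
    count_max = int(np.count_nonzero(img == max_int))
    count_near = int(np.count_nonzero((img >= near) & (img < max_int)))
    if count_max >= min_region:
        chosen, rule = max_int, MAX_SUFFICIENT
    else:
        chosen, rule = near, NEAR_MAX_EXPANDED
    return ThresholdDiagnostics(
        max_intensity=max_int,
        near_max_intensity=near,
        count_max=count_max,
        count_near_max=count_near,
        chosen_threshold=chosen,
        rule_fired=rule,
    )


def find_seed(img: np.ndarray, diag: ThresholdDiagnostics) -> tuple[int, int]:
    """Seed at the rounded centroid of the brightest-pixel region.

    When the brightest pixels form disjoint blobs their centroid can land on
    a pixel below the chosen threshold; the seed then snaps to the nearest
    above-threshold pixel (Euclidean distance, row-major tie-break).
    """
    img = np.asarray(img)
    bright = np.argwhere(img == diag.max_intensity)
    if len(bright) == 0:
        raise ValueError("diagnostics do not match this image")
    centroid = bright.mean(axis=0)
    seed = (int(np.floor(centroid[0] + 0.5)), int(np.floor(centroid[1] + 0.5)))
    if img[seed] >= diag.chosen_threshold:
        return seed
    candidates = np.argwhere(img >= diag.chosen_threshold)
    d2 = ((candidates - np.array(seed)) ** 2).sum(axis=1)
    best = d2.min()
    # row-major tie-break: argwhere already scans in row-major order
    snap = candidates[int(np.argmax(d2 == best))]
    return (int(snap[0]), int(snap[1]))


def region_grow(
    img: np.ndarray,
    seed: tuple[int, int],
    threshold: int,
    connectivity: int = 8,
) -> np.ndarray:
    """Grow the maximal connected region of pixels >= threshold from a seed.

    Classic seeded flood fill: the result is the seed's connected component
    of the boolean image ``img >= threshold`` under the requested (4 or 8)
    connectivity.  Each pixel is visited once, so termination is guaranteed.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    r, c = seed
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ValueError(f"seed {seed} outside image of shape {img.shape}")
    if img[r, c] < threshold:
        raise ValueError("seed intensity is below the growth threshold")
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)
    elif connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    else:
        raise ValueError("connectivity must be 4 or 8")
    above = img >= threshold
    labels, _ = ndi.label(above, structure=structure)
    return labels == labels[r, c]


def extract_roi(
    img: np.ndarray,
    delta: int = 10,
    min_region: int = 10,
    connectivity: int = 8,
) -> ROIResult:
    """Threshold -> seed -> grow -> mask-apply, for one enhanced mammogram."""
    img = np.asarray(img).astype(np.uint8)
    diag = compute_dynamic_threshold(img, delta=delta, min_region=min_region)
    seed = find_seed(img, diag)
    mask = region_grow(img, seed, diag.chosen_threshold, connectivity)
    roi_image = np.where(mask, img, 0).astype(np.uint8)
    return ROIResult(mask=mask, seed=seed, diagnostics=diag, roi_image=roi_image)


class RegionGrowingSegmenter(TransformerMixin, BaseEstimator):
    """sklearn-style transformer mapping enhanced images to ``ROIResult``s."""

    def __init__(self, delta: int = 10, min_region: int = 10, connectivity: int = 8):
        self.delta = delta
        self.min_region = min_region
        self.connectivity = connectivity

    def fit(self, X, y=None):
        if self.delta < 0 or self.min_region < 1:
            raise ValueError("delta must be >= 0 and min_region >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        self.n_images_seen_ = len(X) if X is not None else 0
        return self

    def transform(self, X) -> list[ROIResult]:
        return [
            extract_roi(
                img,
                delta=self.delta,
                min_region=self.min_region,
                connectivity=self.connectivity,
            )
            for img in X
        ]
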