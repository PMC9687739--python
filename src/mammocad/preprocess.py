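"""Artefact removal and contrast enhancement for CC-view mammograms.

The cleaning stage removes the three artefact families that interfere with
lesion segmentation: the white border frame (rectangular border masking),
text/marker blobs outside the breast (keeping only the largest connected
bright component — the breast is always the biggest object in a mammogram),
and the near-vertical white line that acquisition sometimes leaves touching
the breast edge (Canny edges + straight-line Hough voting, then overdrawing
the detected segments in black).

Enhancement is power-law (gamma) correction on [0, 1]-normalised intensities
followed by contrast-limited adaptive histogram equalisation (CLAHE).  The
CLAHE ``clip_limit`` follows the OpenCV convention (histogram bins are clipped
at ``clip_limit * tile_area / 256``); it is converted internally to
scikit-image's normalised convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import exposure
from skimage.feature import canny as _canny
from skimage.transform import probabilistic_hough_line
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "EnhanceParams",
    "apply_border_mask",
    "binarize",
    "largest_component_mask",
    "remove_vertical_lines",
    "gamma_correct",
    "clahe",
    "preprocess_image",
    "MammogramPreprocessor",
]


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        # luminance conversion for RGB input
        img = np.rint(
            0.2125 * img[..., 0] + 0.7154 * img[..., 1] + 0.0721 * img[..., 2]
        )
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return img.astype(np.uint8)


@dataclass
class EnhanceParams:
    """All tunable parameters of the cleaning + enhancement stage.

    Defaults are the published operating point: border width 5, Canny
    hysteresis 50/150, overdraw width 5, gamma 2.0, CLAHE clip limit 1.0 on
    an 8x8 tile grid.
    """

    gamma: float = 2.0
    gain: float = 1.0
    clip_limit: float = 1.0
    tile_grid: tuple[int, int] = (8, 8)
    border_thickness: int = 5
    binarize_method: str = "otsu"
    fixed_thr: int = 20
    canny_lo: float = 50.0
    canny_hi: float = 150.0
    angle_tol: float = 10.0
    min_line_len: int = 30
    overdraw_width: int = 5
    hough_threshold: int = 50
    hough_theta_res: float = math.pi / 180

    def validate(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if min(self.tile_grid) < 1:
            raise ValueError("tile_grid entries must be positive")


def apply_border_mask(img: np.ndarray, thickness: int = 5) -> np.ndarray:
    """Zero every pixel within ``thickness`` of any image edge.

    Removes white border-frame artefacts.  Idempotent; interior pixels are
    untouched.
    """
    img = _check_gray(img)
    m, n = img.shape
    if thickness < 0 or thickness >= min(m, n) / 2:
        raise ValueError(f"thickness {thickness} invalid for shape {img.shape}")
    out = img.copy()
    if thickness > 0:
        out[:thickness, :] = 0
        out[-thickness:, :] = 0
        out[:, :thickness] = 0
        out[:, -thickness:] = 0
    return out


def binarize(
    img: np.ndarray, method: str = "otsu", fixed_thr: int = 20
) -> np.ndarray:
    """Threshold to a boolean mask (True where intensity >= threshold).

    ``method='otsu'`` picks the threshold maximising between-class variance;
    a constant image has no such threshold and falls back to ``fixed_thr``.
    """
    img = _check_gray(img)
    if method == "fixed":
        thr = fixed_thr
    elif method == "otsu":
        if img.min() == img.max():
            logger.warning(
                "otsu undefined on a constant image; falling back to fixed "
                "threshold %d",
                fixed_thr,
            )
            thr = fixed_thr
        else:
            from skimage.filters import threshold_otsu

            # threshold_otsu returns the last bin edge below the cut; use
            # strictly-greater there, i.e. >= thr+1 on integer data
            thr = threshold_otsu(img) + 1
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return img >= thr


def largest_component_mask(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest connected component, with interior holes filled.

    8-connectivity.  Area ties break toward the component containing the
    row-major-smallest pixel.  Applied to a binarised mammogram this isolates
    the breast (always the largest bright object) and discards text blobs.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("cannot take the largest component of an empty mask")
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    areas = np.bincount(labels.ravel())[1:]  # skip background
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # row-major order of each candidate's first pixel
        flat = labels.ravel()
        firsts = [np.argmax(flat == lab) for lab in candidates]
        keep = candidates[int(np.argmin(firsts))]
    largest = labels == keep
    return ndi.binary_fill_holes(largest)


def remove_vertical_lines(
    img: np.ndarray,
    canny_lo: float = 50.0,
    canny_hi: float = 150.0,
    angle_tol: float = 10.0,
    min_len: int = 30,
    overdraw_width: int = 5,
    hough_threshold: int = 50,
    hough_theta_res: float = math.pi / 180,
) -> np.ndarray:
    """Detect near-vertical bright line segments and overdraw them in black.

    Edges come from a Canny detector with the given hysteresis thresholds;
    segments from a probabilistic straight-line Hough transform restricted to
    normals within ``angle_tol`` degrees of horizontal (i.e. lines within
    ``angle_tol`` of vertical).  Detected segments at least ``min_len`` pixels
    long are painted over with intensity 0 at ``overdraw_width``.  With no
    detection the image is returned unchanged.
    """
    img = _check_gray(img)
    edges = _canny(
        img.astype(float), sigma=1.0, low_threshold=canny_lo, high_threshold=canny_hi
    )
    if not edges.any():
        return img.copy()
    tol = math.radians(angle_tol)
    n_angles = max(3, int(round(2 * tol / hough_theta_res)) | 1)
    thetas = np.linspace(-tol, tol, n_angles)  # normals near horizontal
    segments = probabilistic_hough_line(
        edges,
        threshold=hough_threshold,
        line_length=min_len,
        line_gap=3,
        theta=thetas,
        rng=0,
    )
    out = img.copy()
    if not segments:
        return out
    line_mask = np.zeros(img.shape, dtype=bool)
    for (x0, y0), (x1, y1) in segments:
        dx, dy = abs(x1 - x0), abs(y1 - y0)
        if math.degrees(math.atan2(dx, dy)) > angle_tol:
            continue  # not close enough to vertical
        if math.hypot(dx, dy) < min_len:
            continue
        rr, cc = skdraw.line(y0, x0, y1, x1)
        line_mask[rr, cc] = True
    if line_mask.any():
        radius = max(overdraw_width // 2, 0)
        if radius:
            line_mask = ndi.binary_dilation(
                line_mask, structure=np.ones((1, 2 * radius + 1), dtype=bool)
            )
        out[line_mask] = 0
    return out


def gamma_correct(
    img: np.ndarray, gamma: float = 2.0, gain: float = 1.0
) -> np.ndarray:
    """Power-law intensity mapping V_out = gain * V_in**gamma.

    Applied on [0, 1]-normalised intensities and rescaled to 8 bits, so the
    transform is independent of bit depth.  Monotone non-decreasing; gamma
    above 1 darkens mid-tones, below 1 brightens them.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    img = _check_gray(img)
    v = img.astype(float) / 255.0
    out = gain * np.power(v, gamma)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def clahe(
    img: np.ndarray,
    clip_limit: float = 1.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation.

    ``tile_grid`` is the number of tiles per (row, column); ``clip_limit``
    uses the OpenCV convention (bin clip at ``clip_limit * tile_area / 256``)
    and defaults to the published 1.0.  A constant image comes back constant.
    """
    img = _check_gray(img)
    m, n = img.shape
    tr, tc = tile_grid
    if tr < 1 or tc < 1 or tr > m or tc > n:
        raise ValueError(f"tile_grid {tile_grid} invalid for image shape {img.shape}")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    kernel = (max(m // tr, 1), max(n // tc, 1))
    out = exposure.equalize_adapthist(
        img, kernel_size=kernel, clip_limit=clip_limit / 256.0, nbins=256
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def preprocess_image(
    img: np.ndarray, params: EnhanceParams | None = None
) -> np.ndarray:
    """Full cleaning + enhancement chain for one mammogram.

    Order: border mask -> binarise -> largest component -> apply breast mask
    -> vertical-line removal -> gamma correction -> CLAHE.
    """
    params = params or EnhanceParams()
    params.validate()
    img = _check_gray(img)
    step = apply_border_mask(img, params.border_thickness)
    bin_mask = binarize(step, params.binarize_method, params.fixed_thr)
    if not bin_mask.any():
        raise ValueError("image has no foreground after border masking")
    breast = largest_component_mask(bin_mask)
    step = np.where(breast, step, 0).astype(np.uint8)
    step = remove_vertical_lines(
        step,
        canny_lo=params.canny_lo,
        canny_hi=params.canny_hi,
        angle_tol=params.angle_tol,
        min_len=params.min_line_len,
        overdraw_width=params.overdraw_width,
        hough_threshold=params.hough_threshold,
        hough_theta_res=params.hough_theta_res,
    )
    step = gamma_correct(step, params.gamma, params.gain)
    return clahe(step, params.clip_limit, params.tile_grid)


class MammogramPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer wrapping :func:`preprocess_image`.

    ``transform`` maps a sequence of 2-D uint8 images to the list of cleaned,
    enhanced images.  There is nothing to fit; ``fit`` validates parameters
    and returns ``self`` so the class composes with sklearn pipelines.
    """

    def __init__(
        self,
        gamma: float = 2.0,
        gain: float = 1.0,
        clip_limit: float = 1.0,
        tile_grid: tuple[int, int] = (8, 8),
        border_thickness: int = 5,
        binarize_method: str = "otsu",
        angle_tol: float = 10.0,
        min_line_len: int = 30,
        overdraw_width: int = 5,
    ):
        self.gamma = gamma
        self.gain = gain
        self.clip_limit = clip_limit
        self.tile_grid = tile_grid
        self.border_thickness = border_thickness
        self.binarize_method = binarize_method
        self.angle_tol = angle_tol
        self.min_line_len = min_line_len
        self.overdraw_width = overdraw_width

    def _params(self) -> EnhanceParams:
        return EnhanceParams(
            gamma=self.gamma,
            gain=self.gain,
            clip_limit=self.clip_limit,
            tile_grid=self.tile_grid,
            border_thickness=self.border_thickness,
            binarize_method=self.binarize_method,
            angle_tol=self.angle_tol,
            min_line_len=self.min_line_len,
            overdraw_width=self.overdraw_width,
        )

    def fit(self, X, y=None):
        self._params().validate()
        self.n_images_seen_ = len(X) if X is not None else 0
        return self

    def transform(self, X):
        params = self._params()
        return [preprocess_image(img, params) for img in X]
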