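"""Image-quality metrics: MSE, RMSE, PSNR and SSIM.

Used to verify that enhancement preserves the information content of
artefact-removed mammograms: the two images are compared pixelwise (MSE /
RMSE), as a signal-to-noise ratio against the 8-bit dynamic range (PSNR, with
an acceptable band of roughly 30-50 dB), and structurally (SSIM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["QualityReport", "mse", "rmse", "psnr", "ssim", "quality_report"]


def _pair(ref, test):
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if ref.size == 0:
        raise ValueError("empty images")
    return ref, test


def mse(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean squared pixel difference (0 means the images are identical)."""
    ref, test = _pair(ref, test)
    return float(np.mean((ref - test) ** 2))


def rmse(ref: np.ndarray, test: np.ndarray) -> float:
    """Root mean squared error, in intensity units."""
    return math.sqrt(mse(ref, test))


def psnr(ref: np.ndarray, test: np.ndarray, max_level: float = 255.0) -> float:
    """Peak signal-to-noise ratio 20*log10(MAX/RMSE), in decibels.

    Identical images yield ``math.inf`` (documented sentinel rather than an
    error).
    """
    if max_level <= 0:
        raise ValueError("max_level must be positive")
    err = mse(ref, test)
    if err == 0:
        return math.inf
    return 20.0 * math.log10(max_level / math.sqrt(err))


def ssim(
    ref: np.ndarray,
    test: np.ndarray,
    max_level: float = 255.0,
    sigma: float = 1.5,
) -> float:
    """Mean structural similarity over Gaussian-weighted 11x11 windows.

    Standard form with stabilizers c1=(0.01*MAX)^2, c2=(0.03*MAX)^2; returns
    a value in [-1, 1], 1 for identical images.
    """
    ref, test = _pair(ref, test)
    return float(
        structural_similarity(
            ref,
            test,
            data_range=max_level,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
        )
    )


@dataclass
class QualityReport:
    mse: float
    rmse: float
    psnr: float
    ssim: float
    max_level: float = 255.0

    def as_dict(self) -> dict:
        return asdict(self)


def quality_report(
    ref: np.ndarray, test: np.ndarray, max_level: float = 255.0
) -> QualityReport:
    """All four metrics for a reference/processed image pair."""
    e = mse(ref, test)
    return QualityReport(
        mse=e,
        rmse=math.sqrt(e),
        psnr=psnr(ref, test, max_level),
        ssim=ssim(ref, test, max_level),
        max_level=max_level,
    )
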