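"""Image-pair quality metrics: RMSE, PSNR and SSIM.

The RMSE here follows the formula used throughout this package's
reporting: the *mean of squared differences* (no square root), i.e.
what is conventionally called MSE.  ``rmse_conventional`` exposes the
square root for readers who expect the textbook definition; PSNR is
defined on top of the no-root quantity, which makes it the standard
``10 log10(peak**2 / MSE)``.

SSIM is evaluated per sliding window (uniform weights by default,
odd window, fully inside the image) from window means, standard
deviations and covariance, stabilized by G1 = (0.01 L)**2 and
G2 = (0.03 L)**2 with L the peak value ``2**n_bits - 1``, then averaged
over all window positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Image2D, as_pixels

__all__ = ["QualityReport", "rmse", "rmse_conventional", "psnr", "ssim", "quality_report"]


@dataclass
class QualityReport:
    """Bundle of the three metrics for one image pair."""

    mse: float  # mean of squared differences (no square root)
    rmse_conventional: float
    psnr_db: float
    ssim: float


def _pair(reference, test) -> tuple[np.ndarray, np.ndarray]:
    a, b = as_pixels(reference), as_pixels(test)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def rmse(reference, test) -> float:
    """Mean squared difference over all pixels; symmetric; 0 iff equal."""
    a, b = _pair(reference, test)
    return float(np.mean((a - b) ** 2))


def rmse_conventional(reference, test) -> float:
    """Square root of :func:`rmse` (the textbook root-mean-square error)."""
    return float(np.sqrt(rmse(reference, test)))


def psnr(reference, test, n_bits: int = 8) -> float:
    """Peak signal-to-noise ratio in dB against peak ``2**n_bits - 1``.

    Returns ``+inf`` for identical images.  Higher is less noise.
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    err = rmse(reference, test)
    if err == 0.0:
        return float("inf")
    peak = 2.0**n_bits - 1.0
    return float(10.0 * np.log10(peak**2 / err))


def _window_stats(img: np.ndarray, window: int, weights: np.ndarray | None):
    views = np.lib.stride_tricks.sliding_window_view(img, (window, window))
    flat = views.reshape(*views.shape[:2], -1)
    if weights is None:
        mean = flat.mean(axis=-1)
        sq = (flat**2).mean(axis=-1)
    else:
        mean = flat @ weights
        sq = (flat**2) @ weights
    return flat, mean, sq - mean**2


def ssim(
    reference,
    test,
    window: int = 11,
    n_bits: int = 8,
    g1: float | None = None,
    g2: float | None = None,
    gaussian: bool = False,
    sigma: float = 1.5,
) -> float:
    """Mean structural similarity over all fully-interior windows.

    Equals 1 iff the images are identical (with nonzero stabilizers);
    bounded above by 1; symmetric in its two arguments.
    """
    a, b = _pair(reference, test)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if window > min(a.shape):
        raise ValueError(f"window {window} exceeds image extent {a.shape}")
    peak = 2.0**n_bits - 1.0
    c1 = (0.01 * peak) ** 2 if g1 is None else g1
    c2 = (0.03 * peak) ** 2 if g2 is None else g2
    weights = None
    if gaussian:
        half = window // 2
        gy, gx = np.mgrid[-half : half + 1, -half : half + 1]
        w = np.exp(-(gx**2 + gy**2) / (2.0 * sigma**2))
        weights = (w / w.sum()).ravel()
    fa, mu_a, var_a = _window_stats(a, window, weights)
    fb, mu_b, var_b = _window_stats(b, window, weights)
    if weights is None:
        cov = (fa * fb).mean(axis=-1) - mu_a * mu_b
    else:
        cov = (fa * fb) @ weights - mu_a * mu_b
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


def quality_report(reference, test, n_bits: int | None = None, window: int = 11) -> QualityReport:
    """All three metrics for one pair; ``n_bits`` defaults to the
    reference image's recorded bit depth (8 for plain arrays)."""
    if n_bits is None:
        n_bits = reference.bit_depth if isinstance(reference, Image2D) else 8
    err = rmse(reference, test)
    return QualityReport(
        mse=err,
        rmse_conventional=float(np.sqrt(err)),
        psnr_db=psnr(reference, test, n_bits),
        ssim=ssim(reference, test, window=window, n_bits=n_bits),
    )
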