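"""Image-correspondence utilities: smoothed line profiles, standardized
histograms and 64-bit DCT perceptual hashing with Hamming distance.

The perceptual hash follows the dominant published pHash convention:
grayscale image -> band-limited 32 x 32 resample (realized as DCT-domain
truncation) -> 8 x 8 lowest-frequency DCT-II block; each bit records
whether its coefficient exceeds the median of the 64 block coefficients
(an even count, so the median is interpolated and exact ties cannot occur
for generic images — intensity negation therefore flips every bit).  Two
images are "perceptually similar" when the Hamming distance between their
codes is strictly below the threshold (default 32.00 of the 64 bits).
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import scipy.fft
import scipy.ndimage

__all__ = ["hamming", "line_profile", "moving_mean", "phash64", "similar",
           "standardized_histogram"]

SIMILARITY_THRESHOLD = 32.0


def moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean with shrinking windows at the ends."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.size
    half_l = (window - 1) // 2
    half_r = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def line_profile(image: np.ndarray, p0: Sequence[float], p1: Sequence[float],
                 window: int = 1) -> np.ndarray:
    """Intensity profile along a segment, smoothed by a moving mean.

    The segment from ``p0`` to ``p1`` (row, col coordinates) is sampled at
    unit-pixel steps with bilinear interpolation, then smoothed with a
    centred moving mean of the given window length (shrinking at the ends);
    ``window=1`` returns the raw profile.
    """
    img = np.asarray(image, dtype=float)
    a = np.asarray(p0, dtype=float)
    b = np.asarray(p1, dtype=float)
    for p in (a, b):
        if np.any(p < 0) or np.any(p > np.asarray(img.shape) - 1):
            raise ValueError("profile endpoint outside the image")
    length = float(np.linalg.norm(b - a))
    if length == 0:
        raise ValueError("degenerate segment: p0 == p1")
    n = int(np.floor(length)) + 1
    ts = np.linspace(0.0, length, n) / length
    pts = a[None, :] + ts[:, None] * (b - a)[None, :]
    raw = scipy.ndimage.map_coordinates(img, pts.T, order=1, mode="nearest")
    return moving_mean(raw, window)


def standardized_histogram(image: np.ndarray, out_size: int = 256,
                           n_bins: int = 256
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of the spline-resampled, background-subtracted image.

    The image is resampled to ``out_size`` x ``out_size`` pixels by cubic
    spline interpolation, the modal (most frequent) intensity is subtracted
    as background, negatives are clipped to zero, and the result is binned
    into ``n_bins`` equal-width bins.  Returns (counts, bin_edges); counts
    always sum to ``out_size**2``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("need a 2D image of at least 2 x 2 pixels")
    if img.shape == (out_size, out_size):
        res = img.copy()
    else:
        zoom = (out_size / img.shape[0], out_size / img.shape[1])
        res = scipy.ndimage.zoom(img, zoom, order=3, grid_mode=True,
                                 mode="reflect")
        res = res[:out_size, :out_size]
    ptp = float(res.max() - res.min())
    if ptp > 1e-9 * max(1.0, abs(float(res.max()))):
        coarse, edges = np.histogram(res, bins=n_bins)
        mode = 0.5 * (edges[np.argmax(coarse)] + edges[np.argmax(coarse) + 1])
    else:
        mode = float(res.max())
    res = np.clip(res - mode, 0.0, None)
    hi = float(res.max())
    counts, bin_edges = np.histogram(res, bins=n_bins,
                                     range=(0.0, hi if hi > 0 else 1.0))
    return counts, bin_edges


# ---------------------------------------------------------------------------
# perceptual hashing
# ---------------------------------------------------------------------------

def phash64(image: np.ndarray) -> int:
    """64-bit DCT perceptual hash of a grayscale image.

    Deterministic; invariant to positive affine intensity maps of typical
    (non-negative) images and flips every bit under intensity negation.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValueError("need a 2D image of at least 8 x 8 pixels")
    # The 32 x 32 low-pass resample is realized in the DCT domain: the 8 x 8
    # lowest-frequency coefficients of the full image equal (up to an overall
    # scale, which cancels in the median comparison) those of an ideally
    # band-limited 32 x 32 resize.  This keeps the hash exactly invariant to
    # resolution for band-limited content.
    coeffs = scipy.fft.dctn(img, type=2, norm="ortho")[:8, :8]
    flat = coeffs.ravel()
    median = float(np.median(flat))
    bits = flat > median
    code = 0
    for b in bits:  # row-major packing, bit 63 first
        code = (code << 1) | int(b)
    return code


def hamming(h1: int, h2: int) -> int:
    """Number of differing bits between two 64-bit hash codes."""
    for h in (h1, h2):
        if not (0 <= h < 1 << 64):
            raise ValueError("hash codes must be unsigned 64-bit values")
    return int(bin((h1 ^ h2) & ((1 << 64) - 1)).count("1"))


def similar(h1: int, h2: int, threshold: float = SIMILARITY_THRESHOLD) -> bool:
    """Perceptual similarity verdict: Hamming distance strictly below
    the threshold."""
    return hamming(h1, h2) < threshold
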