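"""Spatial-heterogeneity quantification of tumour images.

First-order histogram statistics (mean, variance, skewness, kurtosis,
energy, entropy), the three Tamura texture features (coarseness, contrast,
directionality), tumour segmentation, centre/rim partition along radial
rays from the tumour centre, and the relative centre-rim difference
|c - r| / (c + r).  Whole-tumour values are obtained by averaging metrics
over maximum intensity projections of consecutive 400 um sections.

Conventions (documented because the literature varies):

* kurtosis is non-excess — a Gaussian intensity distribution gives 3;
* energy and entropy use a 256-bin equal-width histogram over the masked
  min-max range, while the moments use the raw (unbinned) intensities;
* Tamura coarseness breaks ties towards the smallest window, so a
  constant image has coarseness 2 (the smallest 2^k window).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.ndimage
import skimage.filters
import skimage.measure
import skimage.morphology

from .recon import Volume, mip

__all__ = [
    "HeterogeneityReport",
    "RegionMask",
    "histogram_metrics",
    "partition_centre_rim",
    "region_metrics",
    "relative_difference",
    "segment_tumour",
    "tamura_coarseness",
    "tamura_contrast",
    "tamura_directionality",
    "whole_tumour_metrics",
]

HISTOGRAM_METRICS = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")
TAMURA_METRICS = ("coarseness", "contrast", "directionality")
ALL_METRICS = HISTOGRAM_METRICS + TAMURA_METRICS


@dataclass
class RegionMask:
    """Boolean region with the centre point used for partitioning."""

    mask: np.ndarray
    role: str = "whole"
    centre_point: Optional[Tuple[float, ...]] = None  # (row, col[, ...])

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        if self.role not in ("whole", "centre", "rim"):
            raise ValueError(f"unknown region role {self.role!r}")


@dataclass
class HeterogeneityReport:
    """Per-region metric set with centre-vs-rim relative differences."""

    regions: Dict[str, Dict[str, float]]
    relative_differences: Dict[str, float]
    n_sections: int = 1
    meta: Dict[str, object] = field(default_factory=dict)

    def to_records(self):
        rows = []
        for role, metrics in self.regions.items():
            rows.append({"region": role, **metrics})
        return rows


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def histogram_metrics(image: np.ndarray, mask: Optional[np.ndarray] = None,
                      n_bins: int = 256) -> Dict[str, float]:
    """First-order intensity statistics over the masked pixels.

    Moments are computed from the raw intensities (population moments,
    kurtosis non-excess so a Gaussian scores 3); energy = sum p_i^2 and
    entropy = -sum p_i log2 p_i come from the normalized ``n_bins``-bin
    histogram over the masked min-max range.  A zero-variance region leaves
    skewness and kurtosis undefined (NaN, with a warning).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    img = np.asarray(image, dtype=float)
    x = img[np.asarray(mask, bool)] if mask is not None else img.ravel()
    if x.size == 0:
        raise ValueError("empty mask")
    mean = float(x.mean())
    var = float(np.mean((x - mean) ** 2))
    if var > 0:
        sd = math.sqrt(var)
        skew = float(np.mean((x - mean) ** 3) / sd ** 3)
        kurt = float(np.mean((x - mean) ** 4) / var ** 2)
    else:
        warnings.warn("zero variance: skewness and kurtosis undefined")
        skew = float("nan")
        kurt = float("nan")
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    else:
        counts = np.array([x.size])
    p = counts / counts.sum()
    p_nz = p[p > 0]
    energy = float(np.sum(p ** 2))
    entropy = float(-np.sum(p_nz * np.log2(p_nz)))
    return {"mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt,
            "energy": energy, "entropy": entropy}


# ---------------------------------------------------------------------------
# Tamura features
# ---------------------------------------------------------------------------

def _block_means(image: np.ndarray, s: int) -> np.ndarray:
    """(H-s+1, W-s+1) means of all s x s blocks, via an integral image."""
    S = np.zeros((image.shape[0] + 1, image.shape[1] + 1))
    S[1:, 1:] = np.cumsum(np.cumsum(image, axis=0), axis=1)
    tot = S[s:, s:] - S[s:, :-s] - S[:-s, s:] + S[:-s, :-s]
    return tot / (s * s)


def tamura_coarseness(image: np.ndarray, mask: Optional[np.ndarray] = None,
                      k_max: int = 5) -> float:
    """Classic Tamura coarseness (average best neighbourhood size).

    For every pixel and window size ``s = 2^k`` (k = 1..k_max, capped so
    the opposite blocks fit inside the image), the absolute difference of
    mean intensity between the two adjacent non-overlapping s x s blocks on
    either side of the pixel is evaluated horizontally and vertically; the
    pixel's best size is the ``s`` maximizing that difference (ties towards
    the smallest ``s``) and coarseness is the mean best size over (masked)
    pixels.  Larger for coarser textures; a constant image scores 2.
    """
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    k_cap = min(k_max, int(math.floor(math.log2(min(H, W) / 2.0))) if min(H, W) >= 4 else 0)
    if k_cap < 1:
        raise ValueError("image too small for the smallest 2x2 window pair")
    best_e = np.full((H, W), -1.0)
    best_s = np.zeros((H, W))
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    for k in range(1, k_cap + 1):
        s = 2 ** k
        bm = _block_means(img, s)  # top-left indexed

        e = np.full((H, W), -np.inf)
        # horizontal: blocks rows [i - s//2, ...], cols [j-s, j-1] and [j, j+s-1]
        r0 = rows - s // 2
        ok_r = (r0 >= 0) & (r0 + s <= H)
        okh = ok_r & (cols - s >= 0) & (cols + s <= W)
        ri = np.clip(r0, 0, H - s)
        cl = np.clip(cols - s, 0, W - s)
        cr = np.clip(cols, 0, W - s)
        eh = np.abs(bm[ri, cr] - bm[ri, cl])
        e = np.where(okh, eh, e)
        # vertical
        c0 = cols - s // 2
        ok_c = (c0 >= 0) & (c0 + s <= W)
        okv = ok_c & (rows - s >= 0) & (rows + s <= H)
        ci = np.clip(c0, 0, W - s)
        rt = np.clip(rows - s, 0, H - s)
        rb = np.clip(rows, 0, H - s)
        ev = np.abs(bm[rb, ci] - bm[rt, ci])
        e = np.maximum(e, np.where(okv, ev, -np.inf))

        take = e > best_e  # strict: ties keep the smaller window
        best_e = np.where(take, e, best_e)
        best_s = np.where(take, float(s), best_s)

    valid = best_s > 0
    if mask is not None:
        valid &= np.asarray(mask, bool)
    if not np.any(valid):
        raise ValueError("no pixel has a complete window pair")
    return float(best_s[valid].mean())


def tamura_contrast(image: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Tamura contrast sigma / alpha4^(1/4), with alpha4 = mu4 / sigma^4.

    Zero for constant images (the defined limit); scales linearly with the
    image intensity scale.
    """
    img = np.asarray(image, dtype=float)
    x = img[np.asarray(mask, bool)] if mask is not None else img.ravel()
    if x.size == 0:
        raise ValueError("empty mask")
    mean = x.mean()
    var = np.mean((x - mean) ** 2)
    if var == 0:
        return 0.0
    alpha4 = np.mean((x - mean) ** 4) / var ** 2
    return float(math.sqrt(var) / alpha4 ** 0.25)


_PREWITT_H = np.array([[-1.0, 0.0, 1.0]] * 3)


def tamura_directionality(image: np.ndarray, mask: Optional[np.ndarray] = None,
                          n_orientation_bins: int = 16,
                          threshold: Optional[float] = None) -> float:
    """Tamura directionality from the gradient-orientation histogram.

    3x3 derivative operators give per-pixel gradient magnitude
    ``(|dH| + |dV|) / 2`` and orientation ``atan2(dV, dH) mod pi``; interior
    pixels with magnitude >= ``threshold`` (default: the mean magnitude)
    populate an ``n_orientation_bins``-bin histogram over [0, pi).  Every
    bin is assigned to its nearest histogram peak (boundaries at the
    minimum between consecutive peaks) and directionality is
    ``1 - clip(n_peaks * F / (pi^2 / 12), 0, 1)`` where F sums the
    second moments of the histogram around its peaks — 1 for a perfectly
    oriented texture, towards 0 for an isotropic one.
    """
    img = np.asarray(image, dtype=float)
    if min(img.shape) < 3:
        raise ValueError("image too small for 3x3 gradient operators")
    dh = scipy.ndimage.convolve(img, _PREWITT_H, mode="nearest")[1:-1, 1:-1]
    dv = scipy.ndimage.convolve(img, _PREWITT_H.T, mode="nearest")[1:-1, 1:-1]
    magnitude = (np.abs(dh) + np.abs(dv)) / 2.0
    theta = np.mod(np.arctan2(dv, dh), np.pi)
    sel = np.ones(magnitude.shape, dtype=bool)
    if mask is not None:
        sel &= np.asarray(mask, bool)[1:-1, 1:-1]
    if threshold is None:
        threshold = float(magnitude[sel].mean()) if np.any(sel) else 0.0
    sel &= magnitude >= threshold
    if not np.any(sel):
        return float("nan")
    nb = n_orientation_bins
    hist, _ = np.histogram(theta[sel], bins=nb, range=(0.0, np.pi))
    p = hist / hist.sum()
    centres = (np.arange(nb) + 0.5) * np.pi / nb

    peaks = [b for b in range(nb)
             if p[b] > p[(b - 1) % nb] and p[b] > p[(b + 1) % nb]]
    if not peaks:
        return 0.0  # flat histogram: fully undirected
    # assign every bin to its nearest peak via circular bin distance
    F = 0.0
    for b in range(nb):
        dists = [min((b - q) % nb, (q - b) % nb) for q in peaks]
        q = peaks[int(np.argmin(dists))]
        dphi = centres[b] - centres[q]
        dphi = (dphi + np.pi / 2.0) % np.pi - np.pi / 2.0  # wrap to [-pi/2, pi/2)
        F += dphi * dphi * p[b]
    norm = np.pi ** 2 / 12.0  # variance of a flat orientation distribution
    return float(1.0 - min(1.0, len(peaks) * F / norm))


# ---------------------------------------------------------------------------
# segmentation and centre/rim partition
# ---------------------------------------------------------------------------

def segment_tumour(image: np.ndarray, smooth_sigma: float = 2.0,
                   closing_radius: int = 3) -> RegionMask:
    """Whole-tumour mask: Otsu on the smoothed image, largest component.

    Returns the mask after morphological closing and hole filling together
    with the intensity-weighted centroid as the centre point.
    """
    img = np.asarray(image, dtype=float)
    if not np.any(img > 0):
        raise ValueError("segmentation failed: image has no foreground")
    smoothed = scipy.ndimage.gaussian_filter(img, smooth_sigma)
    thr = skimage.filters.threshold_otsu(smoothed)
    fg = smoothed > thr
    if not np.any(fg):
        raise ValueError("segmentation failed: empty foreground")
    labels = skimage.measure.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    footprint = (skimage.morphology.disk(closing_radius) if img.ndim == 2
                 else skimage.morphology.ball(closing_radius))
    mask = scipy.ndimage.binary_closing(mask, structure=footprint)
    mask = scipy.ndimage.binary_fill_holes(mask)
    w = np.clip(img, 0, None) * mask
    if w.sum() == 0:
        w = mask.astype(float)
    centre = tuple(float(v) for v in scipy.ndimage.center_of_mass(w))
    return RegionMask(mask=mask, role="whole", centre_point=centre)


def partition_centre_rim(region: RegionMask, cutoff_fraction: float = 0.6,
                         step: float = 0.5) -> Tuple[RegionMask, RegionMask]:
    """Split a 2D mask into centre and rim along radial rays.

    For every mask pixel the fractional radial position ``t`` along the ray
    from the centre point through the pixel to the mask boundary (the last
    mask pixel on the discretized ray) is computed; pixels with
    ``t <= cutoff_fraction`` form the centre, the rest the rim.  The
    partition is exact: centre and rim are disjoint and their union is the
    input mask.
    """
    if not (0.0 < cutoff_fraction < 1.0):
        raise ValueError("cutoff_fraction must be in (0, 1)")
    mask = region.mask
    if mask.ndim != 2:
        raise ValueError("centre/rim partition expects a 2D mask")
    if region.centre_point is None:
        raise ValueError("region has no centre point")
    c = np.asarray(region.centre_point, dtype=float)
    ci = tuple(int(round(v)) for v in c)
    if not (0 <= ci[0] < mask.shape[0] and 0 <= ci[1] < mask.shape[1]
            and mask[ci]):
        raise ValueError("centre point lies outside the mask")

    pix = np.argwhere(mask).astype(float)                  # (N, 2) rows/cols
    rel = pix - c[None, :]
    r = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(r[:, None] > 0, rel / np.maximum(r, 1e-12)[:, None], 0.0)

    max_r = float(np.hypot(*mask.shape))
    n_steps = int(max_r / step) + 2
    R = np.zeros(len(pix))
    for k in range(n_steps):
        d = k * step
        pos = c[None, :] + d * u
        ii = np.round(pos[:, 0]).astype(int)
        jj = np.round(pos[:, 1]).astype(int)
        inside = ((ii >= 0) & (ii < mask.shape[0])
                  & (jj >= 0) & (jj < mask.shape[1]))
        hit = np.zeros(len(pix), dtype=bool)
        hit[inside] = mask[ii[inside], jj[inside]]
        R[hit] = d
    t = np.where(r > 0, r / np.maximum(R, 1e-12), 0.0)
    t = np.minimum(t, 1.0)

    centre_mask = np.zeros_like(mask)
    rim_mask = np.zeros_like(mask)
    idx = pix.astype(int)
    is_centre = t <= cutoff_fraction
    centre_mask[idx[is_centre, 0], idx[is_centre, 1]] = True
    rim_mask[idx[~is_centre, 0], idx[~is_centre, 1]] = True
    cp = region.centre_point
    return (RegionMask(centre_mask, "centre", cp), RegionMask(rim_mask, "rim", cp))


def relative_difference(metric_centre: float, metric_rim: float) -> float:
    """|centre - rim| / (centre + rim); NaN when the sum vanishes."""
    s = metric_centre + metric_rim
    if s == 0:
        warnings.warn("relative difference undefined: centre + rim == 0")
        return float("nan")
    return abs(metric_centre - metric_rim) / s


# ---------------------------------------------------------------------------
# whole-tumour reporting
# ---------------------------------------------------------------------------

def region_metrics(image: np.ndarray, mask: Optional[np.ndarray] = None,
                   n_bins: int = 256) -> Dict[str, float]:
    """All heterogeneity metrics of one image region."""
    out = histogram_metrics(image, mask, n_bins=n_bins)
    out["contrast"] = tamura_contrast(image, mask)
    try:
        out["coarseness"] = tamura_coarseness(image, mask)
    except ValueError:
        out["coarseness"] = float("nan")
    out["directionality"] = tamura_directionality(image, mask)
    return out


def whole_tumour_metrics(volume: Volume, axis: str = "z",
                         thickness_um: float = 400.0,
                         cutoff_fraction: float = 0.6,
                         n_bins: int = 256) -> HeterogeneityReport:
    """Average metrics over MIPs of consecutive sections through the tumour.

    Every ``thickness_um`` section along ``axis`` is projected, segmented,
    partitioned into centre and rim, and scored; metric values are averaged
    across the sections that contain tumour, and the relative
    centre-vs-rim difference of each averaged metric is attached.
    """
    ax = {"x": 2, "y": 1, "z": 0}[axis]
    n_slices = volume.values.shape[ax]
    per_section = max(1, int(round(thickness_um / volume.voxel_size_um)))
    coords = volume.axis_coords_um(axis)
    rows: Dict[str, list] = {"whole": [], "centre": [], "rim": []}
    n_used = 0
    for start in range(0, n_slices, per_section):
        img = mip(volume, axis=axis, start_um=float(coords[start]),
                  thickness_um=thickness_um)
        try:
            whole = segment_tumour(img)
            centre, rim = partition_centre_rim(whole, cutoff_fraction)
        except ValueError:
            continue
        if rim.mask.sum() == 0 or centre.mask.sum() == 0:
            continue
        n_used += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows["whole"].append(region_metrics(img, whole.mask, n_bins))
            rows["centre"].append(region_metrics(img, centre.mask, n_bins))
            rows["rim"].append(region_metrics(img, rim.mask, n_bins))
    if n_used == 0:
        raise ValueError("no section contained a segmentable tumour")

    def _avg(lst):
        keys = lst[0].keys()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return {k: float(np.nanmean([d[k] for d in lst])) for k in keys}

    regions = {role: _avg(lst) for role, lst in rows.items()}
    rel = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in regions["centre"]:
            c, r = regions["centre"][k], regions["rim"][k]
            rel[k] = (relative_difference(c, r)
                      if np.isfinite(c) and np.isfinite(r) else float("nan"))
    return HeterogeneityReport(regions=regions, relative_differences=rel,
                               n_sections=n_used,
                               meta={"axis": axis, "thickness_um": thickness_um,
                                     "cutoff_fraction": cutoff_fraction})
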