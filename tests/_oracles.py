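"""Independent naive (double-loop) Tamura implementations and test images.

Used as brute-force oracles against the vectorized texture module.
"""

import math

import numpy as np


def naive_coarseness(img: np.ndarray, k_max: int = 5) -> float:
    H, W = img.shape
    k_cap = min(k_max, int(math.floor(math.log2(min(H, W) / 2.0))))
    best = []
    for i in range(H):
        for j in range(W):
            e_best, s_best = -1.0, 0
            for k in range(1, k_cap + 1):
                s = 2 ** k
                r0 = i - s // 2
                vals = []
                if 0 <= r0 and r0 + s <= H and j - s >= 0 and j + s <= W:
                    right = img[r0:r0 + s, j:j + s].mean()
                    left = img[r0:r0 + s, j - s:j].mean()
                    vals.append(abs(right - left))
                c0 = j - s // 2
                if 0 <= c0 and c0 + s <= W and i - s >= 0 and i + s <= H:
                    bottom = img[i:i + s, c0:c0 + s].mean()
                    top = img[i - s:i, c0:c0 + s].mean()
                    vals.append(abs(bottom - top))
                if vals and max(vals) > e_best:
                    e_best, s_best = max(vals), s
            if s_best > 0:
                best.append(s_best)
    return float(np.mean(best))


def naive_contrast(img: np.ndarray) -> float:
    x = img.ravel()
    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    if var == 0:
        return 0.0
    alpha4 = ((x - mu) ** 4).mean() / var ** 2
    return math.sqrt(var) / alpha4 ** 0.25


def naive_directionality(img: np.ndarray, nb: int = 16) -> float:
    H, W = img.shape
    dh = np.zeros((H - 2, W - 2))
    dv = np.zeros((H - 2, W - 2))
    for i in range(1, H - 1):
        for j in range(1, W - 1):
            dh[i - 1, j - 1] = (img[i - 1:i + 2, j + 1].sum()
                                - img[i - 1:i + 2, j - 1].sum())
            dv[i - 1, j - 1] = (img[i + 1, j - 1:j + 2].sum()
                                - img[i - 1, j - 1:j + 2].sum())
    mag = (np.abs(dh) + np.abs(dv)) / 2.0
    theta = np.mod(np.arctan2(dv, dh), np.pi)
    thr = mag.mean()
    sel = mag >= thr
    if not sel.any():
        return float("nan")
    hist, _ = np.histogram(theta[sel], bins=nb, range=(0.0, np.pi))
    p = hist / hist.sum()
    centres = (np.arange(nb) + 0.5) * np.pi / nb
    peaks = [b for b in range(nb)
             if p[b] > p[(b - 1) % nb] and p[b] > p[(b + 1) % nb]]
    if not peaks:
        return 0.0
    F = 0.0
    for b in range(nb):
        d = [min((b - q) % nb, (q - b) % nb) for q in peaks]
        q = peaks[int(np.argmin(d))]
        dphi = centres[b] - centres[q]
        dphi = (dphi + np.pi / 2.0) % np.pi - np.pi / 2.0
        F += dphi * dphi * p[b]
    return 1.0 - min(1.0, len(peaks) * F / (np.pi ** 2 / 12.0))


def checkerboard(tile: int, n: int = 64) -> np.ndarray:
    idx = np.add.outer(np.arange(n) // tile, np.arange(n) // tile) % 2
    return idx.astype(float)


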