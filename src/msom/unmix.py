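"""Per-voxel linear spectral unmixing of multi-wavelength volumes.

Each voxel's measured spectrum is decomposed by least squares against the
columns [Hb, HbO2, AuNP, constant background].  Total haemoglobin is
HbT = Hb + HbO2 and oxygen saturation sO2 = HbO2 / HbT, defined only where
HbT exceeds a noise threshold.  A non-negative mode constrains chromophore
amplitudes to be >= 0 (background stays unconstrained), guaranteeing
sO2 in [0, 1].  Spectral error maps report the relative residual norm of a
restricted fit, the standard per-pixel goodness-of-fit display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize

from .phantom import CHROMOPHORES, ChromophoreSpectra

__all__ = ["UnmixResult", "linear_unmix", "so2_hbt", "spectral_error_map"]


@dataclass
class UnmixResult:
    """Component maps plus the derived sO2 / HbT / residual maps.

    ``components`` maps chromophore name (and ``"background"``) to an array
    with the spatial shape of the input; ``so2`` is masked (NaN) where
    HbT <= threshold; ``residual_map`` is ||residual||_2 / ||signal||_2 per
    voxel, masked where the signal norm vanishes.
    """

    components: Dict[str, np.ndarray]
    so2: np.ndarray
    hbt: np.ndarray
    residual_map: np.ndarray
    so2_valid: np.ndarray
    hbt_threshold: float
    meta: Dict[str, object] = field(default_factory=dict)


def _design(spectra: ChromophoreSpectra, components: Sequence[str],
            background: bool) -> np.ndarray:
    A = spectra.design_matrix(components, include_background=background)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return A


def _nnls_background(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """NNLS with a free background: the constant column is split into +/-."""
    k = A.shape[1] - 1
    Ax = np.column_stack([A[:, :k], A[:, k], -A[:, k]])
    x, _ = scipy.optimize.nnls(Ax, y)
    return np.concatenate([x[:k], [x[k] - x[k + 1]]])


def linear_unmix(stack: np.ndarray, spectra: ChromophoreSpectra,
                 nonneg: bool = False,
                 components: Sequence[str] = CHROMOPHORES,
                 background: bool = True,
                 hbt_threshold: Optional[float] = None) -> UnmixResult:
    """Unmix a wavelength-leading stack into chromophore amplitude maps.

    Parameters
    ----------
    stack:
        Array of shape (n_wavelengths, ...); the trailing axes are spatial.
    spectra:
        Absorption table whose wavelengths match the stack's leading axis.
    nonneg:
        Solve non-negative least squares for the chromophores (background
        remains unconstrained).  Guarantees components >= 0 and sO2 in
        [0, 1].
    hbt_threshold:
        sO2 validity cut; default 1% of the 99th percentile of HbT.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] != len(spectra.wavelengths_nm):
        raise ValueError("stack and spectra wavelength counts differ")
    A = _design(spectra, components, background)
    if stack.shape[0] < A.shape[1]:
        raise ValueError("need at least as many wavelengths as unknowns")
    spatial = stack.shape[1:]
    Y = stack.reshape(stack.shape[0], -1)

    X, *_ = np.linalg.lstsq(A, Y, rcond=None)
    if nonneg:
        neg = np.any(X[: len(components)] < 0, axis=0)
        for j in np.nonzero(neg)[0]:
            X[:, j] = _nnls_background(A, Y[:, j])

    resid = Y - A @ X
    signal_norm = np.linalg.norm(Y, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.linalg.norm(resid, axis=0) / signal_norm
    rel[signal_norm == 0] = np.nan

    comp = {name: X[i].reshape(spatial) for i, name in enumerate(components)}
    if background:
        comp["background"] = X[len(components)].reshape(spatial)

    hb = comp.get("Hb", np.zeros(spatial))
    hbo2 = comp.get("HbO2", np.zeros(spatial))
    if hbt_threshold is None:
        hbt_all = hb + hbo2
        ref = float(np.percentile(hbt_all, 99.0)) if hbt_all.size else 0.0
        hbt_threshold = 0.01 * max(ref, 0.0)
    so2, hbt = so2_hbt(hb, hbo2, hbt_threshold)

    return UnmixResult(components=comp, so2=so2, hbt=hbt,
                       residual_map=rel.reshape(spatial),
                       so2_valid=~np.isnan(so2), hbt_threshold=hbt_threshold,
                       meta={"nonneg": nonneg, "components": tuple(components),
                             "wavelengths_nm": spectra.wavelengths_nm})


def so2_hbt(hb: np.ndarray, hbo2: np.ndarray,
            hbt_threshold: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Oxygen saturation and total haemoglobin from component maps.

    ``hbt = hb + hbo2`` exactly; ``so2 = hbo2 / hbt`` where
    ``hbt > hbt_threshold`` and NaN (masked) elsewhere.
    """
    hb = np.asarray(hb, dtype=float)
    hbo2 = np.asarray(hbo2, dtype=float)
    if hb.shape != hbo2.shape:
        raise ValueError("Hb and HbO2 maps are not aligned")
    hbt = hb + hbo2
    so2 = np.full_like(hbt, np.nan)
    valid = hbt > hbt_threshold
    so2[valid] = hbo2[valid] / hbt[valid]
    return so2, hbt


def spectral_error_map(stack: np.ndarray, spectra: ChromophoreSpectra,
                       components: Sequence[str] = ("Hb", "HbO2"),
                       background: bool = False) -> np.ndarray:
    """Relative residual norm of a restricted spectral fit, per pixel.

    Each pixel spectrum of the (wavelength-leading) MIP stack is fitted by
    least squares to the designated component spectra; the output is
    ``||residual||_2 / ||signal||_2`` — zero for perfectly fitting pixels,
    one for a signal orthogonal to the fitted span, NaN where the signal
    norm is zero.
    """
    stack = np.asarray(stack, dtype=float)
    A = _design(spectra, components, background)
    Y = stack.reshape(stack.shape[0], -1)
    X, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ X
    signal_norm = np.linalg.norm(Y, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.linalg.norm(resid, axis=0) / signal_norm
    rel[signal_norm == 0] = np.nan
    return rel.reshape(stack.shape[1:])
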