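"""Delay-and-sum backprojection onto a regular voxel grid, plus the image
utilities used to characterize it.

For every voxel the filtered trace of every pulse/element pair is sampled
(linear interpolation) at the voxel's time of flight and summed with
inverse-distance and elevation-acceptance weights.  The optional
universal-backprojection term replaces the trace ``p(t)`` by
``p(t) - t dp/dt``, which sharpens the bipolar N-shaped transients of
small absorbers.  Dual-band volumes are normalized per band and merged
("frequency equalization"); fluence correction divides by the modelled
light fluence; resolution is measured as the full width at half maximum
of interpolated profiles through a point target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import scipy.interpolate

from . import _kernels
from .forward import FluenceModel, Sinogram

__all__ = ["Volume", "ReconConfig", "backproject", "equalize_merge",
           "estimate_sos", "fluence_correct", "measure_fwhm", "mip"]

MM = 1000.0
_AXES = {"x": 2, "y": 1, "z": 0}


@dataclass
class Volume:
    """Scalar 3D image on an isotropic grid.

    ``values`` is indexed [z, y, x]; ``origin_um`` is the centre of voxel
    (0, 0, 0) in (x, y, z) order; coordinates are voxel-centre based.
    """

    values: np.ndarray
    voxel_size_um: float = 24.0
    origin_um: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel: str = ""
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def axis_coords_um(self, axis: str) -> np.ndarray:
        ax = _AXES[axis]
        n = self.values.shape[ax]
        return self.origin_um["xyz".index(axis)] + np.arange(n) * self.voxel_size_um

    def voxel_position_um(self, iz: int, iy: int, ix: int) -> np.ndarray:
        o = np.asarray(self.origin_um)
        return o + np.array([ix, iy, iz]) * self.voxel_size_um

    def grid_positions_um(self) -> np.ndarray:
        """(nz, ny, nx, 3) voxel centre positions in (x, y, z) order."""
        nz, ny, nx = self.values.shape
        zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                                 indexing="ij")
        o = self.origin_um
        v = self.voxel_size_um
        return np.stack([o[0] + xx * v, o[1] + yy * v, o[2] + zz * v], axis=-1)

    def like(self, values: np.ndarray, channel: Optional[str] = None, **meta) -> "Volume":
        m = dict(self.meta)
        m.update(meta)
        return Volume(values=values, voxel_size_um=self.voxel_size_um,
                      origin_um=self.origin_um,
                      channel=self.channel if channel is None else channel, meta=m)


@dataclass(frozen=True)
class ReconConfig:
    """Backprojection grid and options.

    ``centre_um``/``extent_um`` define the reconstructed box; the grid is
    built from the isotropic ``voxel_size_um`` (24 um default; resolution
    studies use a finer local grid).
    """

    centre_um: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    extent_um: Tuple[float, float, float] = (2400.0, 2400.0, 2400.0)
    voxel_size_um: float = 24.0
    speed_of_sound_m_s: Optional[float] = None      # default: the plan's value
    use_derivative_term: bool = False
    elevation_weighting: bool = True
    clip_warn_fraction: float = 0.01

    def grid(self) -> Tuple[Tuple[int, int, int], Tuple[float, float, float]]:
        ns = tuple(max(1, int(round(e / self.voxel_size_um)) + 1)
                   for e in self.extent_um)  # (nx, ny, nz)
        origin = tuple(c - (n - 1) * self.voxel_size_um / 2.0
                       for c, n in zip(self.centre_um, ns))
        return ns, origin


def _backprojection_signal(sinogram: Sinogram, use_derivative: bool) -> np.ndarray:
    data = sinogram.data
    if not use_derivative:
        return data
    dt = sinogram.dt_us
    t = sinogram.time_axis_us.astype(np.float32)
    dp = np.gradient(data, dt, axis=-1)
    return (data - t[None, None, :] * dp).astype(np.float32)


def backproject(sinogram: Sinogram, cfg: ReconConfig) -> Volume:
    """Delay-and-sum reconstruction of one sinogram onto a voxel grid."""
    (nx, ny, nz), origin = cfg.grid()
    c = cfg.speed_of_sound_m_s or sinogram.plan.speed_of_sound_m_s
    b = _backprojection_signal(sinogram, cfg.use_derivative_term)
    vol = np.zeros((nz, ny, nx), dtype=np.float64)
    sigma = sinogram.array.elevation_sigma if cfg.elevation_weighting else -1.0
    clipped = _kernels.backproject_sum(
        b, sinogram.poses.positions, sinogram.poses.elevations,
        np.asarray(origin, dtype=np.float64), cfg.voxel_size_um,
        nx, ny, nz, c, sinogram.dt_us, sinogram.plan.t_start_us, sigma, vol)
    total = b.shape[0] * b.shape[1] * nx * ny * nz
    if clipped > cfg.clip_warn_fraction * total:
        warnings.warn(f"{clipped / total:.1%} of backprojection contributions "
                      "fell outside the recorded window")
    return Volume(values=vol.astype(np.float32), voxel_size_um=cfg.voxel_size_um,
                  origin_um=origin, channel=str(sinogram.meta.get("band", "full")),
                  meta={"wavelength_nm": sinogram.wavelength_nm,
                        "speed_of_sound_m_s": c,
                        "use_derivative_term": cfg.use_derivative_term,
                        "clipped_fraction": clipped / total})


def estimate_sos(sinogram: Sinogram, candidates_m_s: Sequence[float],
                 cfg: Optional[ReconConfig] = None) -> Tuple[float, np.ndarray]:
    """Average speed of sound by autofocus grid search.

    Reconstructs a coarse volume for every candidate speed and returns the
    candidate maximizing the peak voxel intensity (a sharpness criterion:
    the microsphere image collapses to a bright point only at the true
    speed).  Also returns the criterion per candidate.  A flat criterion
    (no absorber in the field of view) raises.
    """
    candidates = np.asarray(list(candidates_m_s), dtype=float)
    if candidates.size < 1:
        raise ValueError("no candidate speeds")
    cfg = cfg or ReconConfig(extent_um=(720.0, 720.0, 720.0), voxel_size_um=24.0)
    crit = np.empty(candidates.size)
    for i, c in enumerate(candidates):
        cfg_i = ReconConfig(**{**cfg.__dict__, "speed_of_sound_m_s": float(c)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vol = backproject(sinogram, cfg_i)
        crit[i] = float(np.abs(vol.values).max())
    if crit.max() <= 0 or np.allclose(crit, crit[0]):
        raise RuntimeError("speed-of-sound estimation failed: flat criterion")
    best = int(np.argmax(crit))
    if best in (0, candidates.size - 1) and candidates.size > 2:
        warnings.warn("speed-of-sound optimum at the search boundary")
    return float(candidates[best]), crit


def equalize_merge(low: Volume, high: Volume,
                   percentile: float = 99.9) -> Tuple[Volume, Volume, Volume]:
    """Frequency equalization of a dual-band reconstruction.

    Each band is normalized independently to its own robust maximum (the
    given percentile of voxel intensity) and returned along with a
    two-channel composite stacked on a leading axis; there is no cross-band
    mixing.
    """
    if low.shape != high.shape or low.voxel_size_um != high.voxel_size_um:
        raise ValueError("band volumes are on different grids")

    def _norm(v: Volume) -> Volume:
        scale = float(np.percentile(np.abs(v.values), percentile))
        scale = scale if scale > 0 else 1.0
        return v.like(v.values / scale, normalization=scale)

    low_n, high_n = _norm(low), _norm(high)
    composite = low_n.like(np.stack([low_n.values, high_n.values]),
                           channel="low+high")
    return low_n, high_n, composite


def fluence_correct(volume: Volume, model: FluenceModel,
                    floor: float = 1e-3) -> Volume:
    """Divide each voxel by the modelled fluence at its position.

    The divisor is floored (default 1e-3) to bound noise amplification at
    depth.
    """
    w = np.exp(-model.mu_eff_per_mm * model.depths_mm(volume.grid_positions_um()))
    w = np.maximum(w, floor)
    return volume.like(volume.values / w, fluence_mu_eff_per_mm=model.mu_eff_per_mm)


def mip(volume: Volume, axis: str = "z", start_um: Optional[float] = None,
        thickness_um: float = 400.0) -> np.ndarray:
    """Maximum intensity projection over a slab of the given thickness."""
    ax = _AXES[axis]
    coords = volume.axis_coords_um(axis)
    if start_um is None:
        lo = 0
    else:
        lo = int(np.searchsorted(coords, start_um - 1e-9))
    n = max(1, int(round(thickness_um / volume.voxel_size_um)))
    hi = min(volume.values.shape[ax], lo + n)
    if lo >= volume.values.shape[ax]:
        raise ValueError("slab outside the volume")
    sl = [slice(None)] * 3
    sl[ax] = slice(lo, hi)
    return volume.values[tuple(sl)].max(axis=ax)


def measure_fwhm(volume: Volume, centre_um: Optional[Sequence[float]] = None,
                 window_um: float = 200.0, upsample: int = 8,
                 axes: Sequence[str] = ("x", "y", "z"),
                 ) -> Dict[str, float]:
    """Per-axis full width at half maximum of a point-like target.

    Profiles along x, y and z through the intensity peak are upsampled by
    cubic interpolation; the local background is the median of the outer
    quarters of each profile and the width is measured at half the peak
    height above it.  Raises if the half level is not crossed inside the
    window (peak too close to the volume border or window too small).
    """
    vals = volume.values
    if centre_um is None:
        peak_idx = np.unravel_index(np.argmax(vals), vals.shape)
    else:
        c = np.asarray(centre_um, dtype=float)
        o = np.asarray(volume.origin_um, dtype=float)
        ixyz = np.round((c - o) / volume.voxel_size_um).astype(int)
        peak_idx = (ixyz[2], ixyz[1], ixyz[0])
    half_w = max(3, int(round(window_um / volume.voxel_size_um)))
    out: Dict[str, float] = {}
    for axis in axes:
        ax = _AXES[axis]
        n = vals.shape[ax]
        i = peak_idx[ax]
        lo, hi = i - half_w, i + half_w + 1
        if lo < 0 or hi > n:
            raise ValueError(f"measurement window truncated at the volume "
                             f"border along {axis}")
        sl = list(peak_idx)
        sl[ax] = slice(lo, hi)
        profile = np.asarray(vals[tuple(sl)], dtype=float)
        x = np.arange(profile.size, dtype=float)
        fine_x = np.linspace(0, profile.size - 1, (profile.size - 1) * upsample + 1)
        fine = scipy.interpolate.CubicSpline(x, profile)(fine_x)
        quarter = max(1, profile.size // 4) * upsample
        background = float(np.median(np.concatenate([fine[:quarter],
                                                     fine[-quarter:]])))
        peak_pos = int(np.argmax(fine))
        peak = fine[peak_pos]
        level = background + 0.5 * (peak - background)
        below_l = np.nonzero(fine[:peak_pos] < level)[0]
        below_r = np.nonzero(fine[peak_pos:] < level)[0]
        if below_l.size == 0 or below_r.size == 0:
            raise ValueError(f"half maximum not crossed inside the window "
                             f"along {axis}")
        il = below_l[-1]
        xl = fine_x[il] + (level - fine[il]) / (fine[il + 1] - fine[il]) \
            * (fine_x[il + 1] - fine_x[il])
        ir = peak_pos + below_r[0]
        xr = fine_x[ir - 1] + (level - fine[ir - 1]) / (fine[ir] - fine[ir - 1]) \
            * (fine_x[ir] - fine_x[ir - 1])
        out[axis] = (xr - xl) * volume.voxel_size_um
    if "x" in out and "y" in out:
        out["in_plane"] = 0.5 * (out["x"] + out["y"])
    return out
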