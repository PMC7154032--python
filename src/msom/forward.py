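"""Analytic optoacoustic forward model for spherical absorbers.

A uniformly heated sphere radiates the classic far-field "N-shaped"
bipolar pressure transient: zero outside ``|t - d/c| <= r/c``, linear
(positive then negative) inside, with amplitude proportional to the
absorbed energy and 1/distance.  Sinograms are synthesized per laser pulse
by summing, for every array element, the band-limited response of every
absorber: the exact N-wave spectrum is multiplied by the detector's
one-way receive spectrum and the time-of-flight phase ramp, then inverse
transformed onto the 125 MS/s sample grid.  This frequency-domain route is
an exact sampling of the convolved continuous-time signal and avoids
aliasing the very short (tens of ns) sphere transients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import scipy.signal

from . import _kernels
from .phantom import AbsorberScene, ChromophoreSpectra, load_spectra
from .scanner import ArraySpec, PoseSet, ScanPlan, scan_poses

__all__ = [
    "FluenceModel",
    "Sinogram",
    "auto_record_window",
    "fluence_weight",
    "impulse_response",
    "ir_spectrum",
    "simulate_sinogram",
    "sphere_pressure",
    "sphere_spectrum",
]

MM = 1000.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Sinogram:
    """Time-resolved pressure traces indexed [pulse, element, sample]."""

    data: np.ndarray                 # (P, E, S) float32, a.u.
    plan: ScanPlan
    array: ArraySpec
    wavelength_nm: float
    poses: PoseSet
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        P, E, S = self.data.shape
        if P != self.plan.n_pulses or E != self.array.n_elements:
            raise ValueError("data dimensions inconsistent with plan/array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def dt_us(self) -> float:
        return self.plan.dt_us

    @property
    def time_axis_us(self) -> np.ndarray:
        return self.plan.t_start_us + np.arange(self.n_samples) * self.dt_us

    def copy_with(self, data: np.ndarray, **meta) -> "Sinogram":
        m = dict(self.meta)
        m.update(meta)
        return Sinogram(data=data, plan=self.plan, array=self.array,
                       wavelength_nm=self.wavelength_nm, poses=self.poses, meta=m)


@dataclass(frozen=True)
class FluenceModel:
    """Depth-dependent light fluence, phi(depth) = exp(-mu_eff * depth).

    ``surface`` selects how depth is measured: ``"cylinder"`` measures
    radial depth inward from a cylinder of radius ``surface_radius_mm``
    around the z axis (side illumination of a protruding sample);
    ``"plane"`` measures depth below the plane z = ``surface_z_mm``.
    """

    mu_eff_per_mm: float = 0.0
    surface: str = "cylinder"
    surface_radius_mm: float = 6.0
    surface_z_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_eff_per_mm < 0:
            raise ValueError("mu_eff must be >= 0")
        if self.surface not in ("cylinder", "plane"):
            raise ValueError("surface must be 'cylinder' or 'plane'")

    def depth_mm(self, position_um: Sequence[float]) -> float:
        p = np.asarray(position_um, dtype=float)
        if self.surface == "cylinder":
            r = math.hypot(p[0], p[1]) / MM
            return max(0.0, self.surface_radius_mm - r)
        return max(0.0, self.surface_z_mm - p[2] / MM)

    def depths_mm(self, positions_um: np.ndarray) -> np.ndarray:
        p = np.asarray(positions_um, dtype=float)
        if self.surface == "cylinder":
            r = np.hypot(p[..., 0], p[..., 1]) / MM
            return np.maximum(0.0, self.surface_radius_mm - r)
        return np.maximum(0.0, self.surface_z_mm - p[..., 2] / MM)


def fluence_weight(position_um: Sequence[float], model: FluenceModel) -> float:
    """exp(-mu_eff * depth); equals 1 on or outside the surface."""
    return float(np.exp(-model.mu_eff_per_mm * model.depth_mm(position_um)))


# ---------------------------------------------------------------------------
# elementary responses
# ---------------------------------------------------------------------------

def sphere_pressure(radius_um: float, distance_um: float, amplitude: float,
                    speed_of_sound_m_s: float, time_axis_us: np.ndarray) -> np.ndarray:
    """Far-field N-wave of a uniformly heated sphere, sampled on a time axis.

    The trace is ``-amplitude/d * (t - d/c)/(r/c)`` inside
    ``|t - d/c| <= r/c`` and zero outside: a bipolar pulse, positive first,
    of total duration ``2 r / c`` whose integral vanishes.
    """
    if distance_um <= radius_um:
        raise ValueError("detector lies inside the sphere")
    if speed_of_sound_m_s <= 0:
        raise ValueError("speed of sound must be positive")
    t = np.asarray(time_axis_us, dtype=float)
    tau = distance_um / speed_of_sound_m_s
    half = radius_um / speed_of_sound_m_s
    rel = t - tau
    p = np.where(np.abs(rel) <= half, -amplitude / distance_um * rel / half, 0.0)
    return p


def sphere_spectrum(radius_um: float, speed_of_sound_m_s: float,
                    freqs_MHz: np.ndarray) -> np.ndarray:
    """Imaginary part of the N-wave's Fourier transform (the real part is 0).

    For the unit-amplitude N-wave ``p(t) = -t/tau`` on ``|t| <= tau`` with
    ``tau = r/c``, the transform is
    ``2 i (sin(w tau) - w tau cos(w tau)) / (tau w^2)``.
    """
    tau = radius_um / speed_of_sound_m_s
    w = 2.0 * np.pi * np.asarray(freqs_MHz, dtype=float)
    out = np.zeros_like(w)
    nz = w != 0.0
    wt = w[nz] * tau
    out[nz] = 2.0 * (np.sin(wt) - wt * np.cos(wt)) / (tau * w[nz] ** 2)
    return out


def ir_spectrum(array: ArraySpec, freqs_MHz: np.ndarray) -> np.ndarray:
    """One-way receive amplitude spectrum of the detector (zero phase).

    ``"gaussian"``: Gaussian peaking at the centre frequency with -6 dB
    (half-amplitude) full width ``fractional_bandwidth * centre_frequency``,
    unit peak amplitude.  ``"broadband"``: third-order Butterworth bandpass
    magnitude over ``response_band_MHz``.
    """
    f = np.asarray(freqs_MHz, dtype=float)
    if array.response_model == "gaussian":
        fc = array.centre_frequency_MHz
        half_width = 0.5 * array.fractional_bandwidth * fc
        sigma = half_width / math.sqrt(2.0 * math.log(2.0))
        return np.exp(-((f - fc) ** 2) / (2.0 * sigma ** 2))
    lo, hi = array.response_band_MHz
    b, a = scipy.signal.butter(3, [lo, hi], btype="bandpass", analog=True)
    _, h = scipy.signal.freqs(b, a, worN=np.maximum(f, 1e-9))
    return np.abs(h)


def impulse_response(array: ArraySpec, n_samples: int, dt_us: float) -> np.ndarray:
    """Zero-phase time-domain receive kernel, centred in the window.

    The kernel's amplitude spectrum is ``ir_spectrum``; for the default
    Gaussian model it peaks (amplitude 1) at the centre frequency and is
    0.5 at +-(fractional_bandwidth * fc / 2).
    """
    nyq = 0.5 / dt_us
    fc = array.centre_frequency_MHz
    upper = fc * (1 + array.fractional_bandwidth)
    if array.response_model == "broadband":
        upper = array.response_band_MHz[1]
    if nyq < upper:
        raise ValueError("sampling rate violates Nyquist for the detection band")
    freqs = np.fft.rfftfreq(n_samples, dt_us)
    h = np.fft.irfft(ir_spectrum(array, freqs), n=n_samples)
    return np.fft.fftshift(h)


# ---------------------------------------------------------------------------
# sinogram synthesis
# ---------------------------------------------------------------------------

def auto_record_window(scene: AbsorberScene, array: ArraySpec, plan: ScanPlan,
                       margin_us: float = 0.35, sample_multiple: int = 256,
                       ) -> Tuple[float, int]:
    """Record start time and length covering all element-absorber delays."""
    poses = scan_poses(array, plan)
    centres = scene.centres()
    rmax = float(scene.radii().max())
    pos = poses.positions.reshape(-1, 1, 3)
    d = np.linalg.norm(pos - centres[None, :, :], axis=-1)
    c = plan.speed_of_sound_m_s
    t_lo = (d.min() - rmax) / c - margin_us
    t_hi = (d.max() + rmax) / c + margin_us
    t_start = max(0.0, t_lo)
    n = int(math.ceil((t_hi - t_start) / plan.dt_us))
    n = int(math.ceil(n / sample_multiple) * sample_multiple)
    return t_start, n


def simulate_sinogram(
    scene: AbsorberScene,
    spectra: Optional[ChromophoreSpectra] = None,
    wavelength_nm: float = 800.0,
    array: Optional[ArraySpec] = None,
    plan: Optional[ScanPlan] = None,
    fluence: Optional[FluenceModel] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    apply_ir: bool = True,
    elevation_weighting: bool = True,
    pulse_chunk: int = 128,
) -> Sinogram:
    """Synthesize one multi-element conical-scan sinogram.

    Per pulse and element the N-waves of all absorbers are summed with
    per-absorber amplitude ``sum_c concentration_c * absorption_c(lambda) *
    fluence_weight(centre)``, weighted by 1/distance and by the Gaussian
    elevation acceptance of the cylindrically focused element, convolved
    with the detector receive response (``apply_ir=True``; the exact
    time-domain N-wave is sampled otherwise), and white Gaussian noise of
    standard deviation ``noise_sd`` is added.  Reproducible under a fixed
    seed.
    """
    array = array or ArraySpec()
    plan = plan or ScanPlan()
    spectra = spectra or load_spectra()

    t_start, n_samples = plan.t_start_us, plan.n_samples
    if n_samples is None:
        if scene.absorbers:
            t_start, n_samples = auto_record_window(scene, array, plan)
        else:
            t_start, n_samples = 0.0, 1024
        plan = ScanPlan(**{**plan.__dict__, "t_start_us": t_start,
                           "n_samples": n_samples})

    poses = scan_poses(array, plan)
    P, E = plan.n_pulses, array.n_elements
    data = np.zeros((P, E, n_samples), dtype=np.float32)
    rng = np.random.default_rng(seed)

    if not scene.absorbers:
        warnings.warn("empty scene: sinogram contains only noise")
    else:
        centres = scene.centres()
        radii = scene.radii()
        amps = scene.amplitudes(spectra, wavelength_nm)
        if fluence is not None:
            amps = amps * np.exp(-fluence.mu_eff_per_mm * fluence.depths_mm(centres))
        c = plan.speed_of_sound_m_s
        sigma = array.elevation_sigma if elevation_weighting else -1.0
        if apply_ir:
            freqs = np.fft.rfftfreq(n_samples, plan.dt_us)
            H = ir_spectrum(array, freqs)
            base = np.empty((len(radii), len(freqs)), dtype=np.float64)
            for k, r in enumerate(radii):
                base[k] = sphere_spectrum(r, c, freqs) * H
            # spectra are per-trace Fourier series over the record window
            base /= (n_samples * plan.dt_us) / n_samples  # = 1/dt: FT -> DFT scale
            df = freqs[1] - freqs[0]
            for p_lo in range(0, P, pulse_chunk):
                p_hi = min(P, p_lo + pulse_chunk)
                spec = np.zeros((p_hi - p_lo, E, len(freqs)), dtype=np.complex64)
                _kernels.synth_spectra(
                    poses.positions, poses.elevations, centres, base, amps,
                    c, df, t_start, sigma, p_lo, p_hi, spec)
                data[p_lo:p_hi] = np.fft.irfft(spec, n=n_samples, axis=-1
                                               ).astype(np.float32)
        else:
            _kernels.synth_time_exact(
                poses.positions, poses.elevations, centres, radii, amps,
                c, plan.dt_us, t_start, n_samples, sigma, data)

    if noise_sd > 0.0:
        data += rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)

    return Sinogram(data=data, plan=plan, array=array,
                    wavelength_nm=wavelength_nm, poses=poses,
                    meta={"seed": seed, "noise_sd": noise_sd,
                          "apply_ir": apply_ir,
                          "elevation_weighting": elevation_weighting})
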