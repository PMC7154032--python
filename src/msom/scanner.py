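"""Conical translation-rotation scan geometry.

The cylindrically focused 96-element linear array is tilted 45 degrees to
the rotation plane and simultaneously rotates and translates around the
sample, so the central element traces a helix on a cylinder of radius
5.8 mm; the array's focal line sweeps a cone close to the rotation axis.
One pose (per-element positions, a look normal and an elevation direction)
is generated per laser pulse.

Coordinate convention: right-handed, z along the rotation/translation axis.
Angles are degrees in all interfaces and radians internally.  Positions are
in um, times in us; sound speed in m/s equals um/us numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Optional, Tuple

import numpy as np

__all__ = ["ArraySpec", "ScanPlan", "Pose", "PoseSet", "scan_poses", "element_delay"]

MM = 1000.0  # um per mm


@dataclass(frozen=True)
class ArraySpec:
    """Geometry and detection band of the linear detector array.

    Defaults are the imaging system's parameters: 96 elements at 100 um
    pitch, 1.5 mm elevation aperture cylindrically focused at 7.8 mm,
    15 MHz centre frequency with 45% -6 dB bandwidth, mounted at 45 degrees
    with the central (48th) element tracing a 5.8 mm radius circle.

    ``response_model`` selects the simulated one-way receive response:
    ``"gaussian"`` is a resonant Gaussian amplitude spectrum (peak at the
    centre frequency, -6 dB full width equal to the fractional bandwidth
    times the centre frequency); ``"broadband"`` is a flat response over
    ``response_band`` (third-order Butterworth magnitude), modelling a
    receive chain whose usable band spans ~1-30 MHz.
    """

    n_elements: int = 96
    pitch_um: float = 100.0
    element_elevation_mm: float = 1.5
    focal_length_mm: float = 7.8
    centre_frequency_MHz: float = 15.0
    fractional_bandwidth: float = 0.45
    tilt_deg: float = 45.0
    central_radius_mm: float = 5.8
    response_model: str = "gaussian"
    response_band_MHz: Tuple[float, float] = (1.0, 30.0)
    elevation_sigma_rad: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        if not (0.0 < self.fractional_bandwidth < 1.0):
            raise ValueError("fractional bandwidth must be in (0, 1)")
        if not (0.0 <= self.tilt_deg <= 90.0):
            raise ValueError("tilt must be in [0, 90] degrees")
        if self.response_model not in ("gaussian", "broadband"):
            raise ValueError("response_model must be 'gaussian' or 'broadband'")

    @property
    def central_index(self) -> int:
        """0-based index of the element tracing the central circle."""
        return self.n_elements // 2 - 1 if self.n_elements % 2 == 0 else self.n_elements // 2

    @property
    def elevation_sigma(self) -> float:
        """Std. dev. (rad) of the Gaussian elevation acceptance.

        Defaults to the half-aperture angle of the cylindrical lens,
        atan((elevation/2) / focal length).
        """
        if self.elevation_sigma_rad is not None:
            return self.elevation_sigma_rad
        return math.atan(0.5 * self.element_elevation_mm / self.focal_length_mm)


@dataclass(frozen=True)
class ScanPlan:
    """One continuous conical scan, discretized at laser pulse instants.

    ``z_start_mm=None`` centres the sweep of the array's focal locus on
    z = 0, which is where scenes are conventionally placed.
    """

    n_pulses: int = 1200
    rotation_range_deg: float = 255.0
    translation_range_mm: float = 10.0
    pulse_rate_Hz: float = 10.0
    speed_of_sound_m_s: float = 1500.0
    sampling_rate_MSs: float = 125.0
    n_samples: Optional[int] = None
    t_start_us: float = 0.0
    start_angle_deg: float = 0.0
    z_start_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if not (0.0 < self.rotation_range_deg <= 360.0):
            raise ValueError("rotation range must be in (0, 360] degrees")
        if self.speed_of_sound_m_s <= 0:
            raise ValueError("speed of sound must be positive")
        if self.sampling_rate_MSs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def dt_us(self) -> float:
        return 1.0 / self.sampling_rate_MSs


class Pose(NamedTuple):
    """Element positions (E, 3) and unit directions for one pulse."""

    positions: np.ndarray      # (E, 3) um
    normal: np.ndarray         # (3,) unit look direction of the array
    elevation: np.ndarray      # (3,) unit elevation (lens) direction
    angle_deg: float
    z_um: float


class PoseSet:
    """Deterministic sequence of poses for a whole scan."""

    def __init__(self, positions: np.ndarray, normals: np.ndarray,
                 elevations: np.ndarray, angles_deg: np.ndarray,
                 z_um: np.ndarray) -> None:
        self.positions = positions      # (P, E, 3)
        self.normals = normals          # (P, 3)
        self.elevations = elevations    # (P, 3)
        self.angles_deg = angles_deg    # (P,)
        self.z_um = z_um                # (P,)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, k: int) -> Pose:
        return Pose(self.positions[k], self.normals[k], self.elevations[k],
                    float(self.angles_deg[k]), float(self.z_um[k]))

    def __iter__(self) -> Iterator[Pose]:
        for k in range(len(self)):
            yield self[k]


def scan_poses(array: ArraySpec, plan: ScanPlan) -> PoseSet:
    """Element positions and directions for every pulse of a conical scan.

    The rotation angle increases linearly over ``rotation_range_deg`` and the
    height linearly over ``translation_range_mm`` (a helical path).  For
    every pose the central element lies exactly ``central_radius_mm`` from
    the rotation axis and the array line is tilted ``tilt_deg`` out of the
    rotation plane.
    """
    P, E = plan.n_pulses, array.n_elements
    if P == 1:
        angles = np.array([plan.start_angle_deg])
        z_rel = np.array([0.0])
    else:
        angles = plan.start_angle_deg + np.linspace(0.0, plan.rotation_range_deg, P)
        z_rel = np.linspace(0.0, plan.translation_range_mm * MM, P)

    tilt = math.radians(array.tilt_deg)
    focal = array.focal_length_mm * MM
    if plan.z_start_mm is None:
        # centre the focal-point sweep on z = 0
        z0 = -focal * math.cos(tilt) - plan.translation_range_mm * MM / 2.0
    else:
        z0 = plan.z_start_mm * MM
    z = z0 + z_rel

    phi = np.radians(angles)
    r_hat = np.stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)], axis=-1)   # (P, 3)
    z_hat = np.array([0.0, 0.0, 1.0])
    # array axis: tilted out of the rotation plane, in the radial-z plane
    u_hat = math.cos(tilt) * r_hat + math.sin(tilt) * z_hat                     # (P, 3)
    # look normal: perpendicular to the array axis in the radial-z plane,
    # pointing inward so the focal point lands near the rotation axis
    n_hat = -math.sin(tilt) * r_hat + math.cos(tilt) * np.broadcast_to(z_hat, r_hat.shape)
    e_hat = np.cross(u_hat, n_hat)                                              # elevation

    centre = array.central_radius_mm * MM * r_hat + z[:, None] * z_hat          # (P, 3)
    offsets = (np.arange(E) - array.central_index) * array.pitch_um             # (E,)
    positions = centre[:, None, :] + offsets[None, :, None] * u_hat[:, None, :]
    return PoseSet(positions=positions, normals=n_hat, elevations=e_hat,
                   angles_deg=angles, z_um=z)


def element_delay(pose_element: np.ndarray, voxel: np.ndarray,
                  speed_of_sound_m_s: float) -> float:
    """Time of flight (us) between an element and a voxel, both in um."""
    if speed_of_sound_m_s <= 0:
        raise ValueError("speed of sound must be positive")
    d = np.linalg.norm(np.asarray(pose_element, float) - np.asarray(voxel, float))
    return float(d / speed_of_sound_m_s)
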