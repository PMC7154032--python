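"""Synthetic absorber scenes and chromophore spectra.

This module builds the ground-truth optical absorber distributions used by
the forward simulator: microsphere calibration phantoms (broadband "black"
polyethylene spheres dispersed in an agar cylinder) and tumour-like phantoms
with an oxygenated vascular rim and a hypoxic core.  It also ships a small
table of relative near-infrared absorption spectra for deoxygenated
haemoglobin (Hb), oxygenated haemoglobin (HbO2) and gold nanoparticles
(AuNP), from which per-wavelength absorber amplitudes are computed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CHROMOPHORES",
    "DEFAULT_WAVELENGTHS_NM",
    "Absorber",
    "AbsorberScene",
    "ChromophoreSpectra",
    "Domain",
    "InfeasibleGeometryError",
    "box_domain",
    "chromophore_spectrum",
    "cylinder_domain",
    "load_spectra",
    "make_microsphere_phantom",
    "make_tumour_phantom",
]

#: Chromophores with spectra in the shipped table.
CHROMOPHORES = ("Hb", "HbO2", "AuNP")

#: Excitation wavelengths used for multispectral imaging (nm).
DEFAULT_WAVELENGTHS_NM = (710.0, 750.0, 780.0, 810.0, 850.0)

#: Wavelength-flat broadband absorber (black polyethylene microspheres).
FLAT_CHROMOPHORE = "black"

_PLACEMENT_RETRY_CAP = 10_000


class InfeasibleGeometryError(RuntimeError):
    """Raised when absorbers cannot be placed at the requested density."""


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _load_table() -> pd.DataFrame:
    with resources.files("msom.data").joinpath("chromophores.csv").open() as fh:
        return pd.read_csv(fh)


def chromophore_spectrum(name: str, wavelengths_nm: Sequence[float]) -> np.ndarray:
    """Relative absorption of one chromophore at the given wavelengths.

    Hb and HbO2 values are tabulated from the standard omlc.org compilation
    of haemoglobin extinction coefficients (normalized to a common peak so
    that their ratio — and hence sO2 — is preserved); the AuNP spectrum is a
    smooth plasmon band peaking at 780 nm.  Values between the 10 nm grid
    points are linearly interpolated.

    Parameters
    ----------
    name:
        One of ``"Hb"``, ``"HbO2"``, ``"AuNP"`` or ``"black"``
        (wavelength-flat, absorption 1 everywhere).
    wavelengths_nm:
        Wavelengths within the tabulated range (690-900 nm).
    """
    wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    if name == FLAT_CHROMOPHORE:
        return np.ones_like(wl)
    if name not in CHROMOPHORES:
        raise ValueError(f"unknown chromophore {name!r}; expected one of {CHROMOPHORES}")
    tab = _load_table()
    lo, hi = tab["wavelength_nm"].iloc[0], tab["wavelength_nm"].iloc[-1]
    if wl.min() < lo or wl.max() > hi:
        raise ValueError(
            f"wavelength out of tabulated range [{lo:g}, {hi:g}] nm: {wl}"
        )
    return np.interp(wl, tab["wavelength_nm"].to_numpy(), tab[name].to_numpy())


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Absorption design table at a fixed set of wavelengths.

    ``absorption`` maps chromophore name to the vector of relative absorption
    coefficients at ``wavelengths_nm``; ``background`` is the constant offset
    spectrum used as the last column of the unmixing design matrix.
    """

    wavelengths_nm: Tuple[float, ...]
    absorption: Mapping[str, np.ndarray]
    background: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.wavelengths_nm)
        for name, vec in self.absorption.items():
            if len(vec) != n:
                raise ValueError(f"spectrum length mismatch for {name}")
            if np.any(np.asarray(vec) <= 0):
                raise ValueError(f"non-positive absorption for {name}")

    def value(self, name: str, wavelength_nm: float) -> float:
        """Absorption of ``name`` at one of the tabulated wavelengths."""
        if name == FLAT_CHROMOPHORE:
            return 1.0
        idx = self.wavelengths_nm.index(wavelength_nm)
        return float(self.absorption[name][idx])

    def design_matrix(self, components: Sequence[str] = CHROMOPHORES,
                      include_background: bool = True) -> np.ndarray:
        """Columns [component spectra..., constant background]."""
        cols = [np.asarray(self.absorption[c], dtype=float) for c in components]
        if include_background:
            cols.append(np.full(len(self.wavelengths_nm), self.background))
        return np.column_stack(cols)


def load_spectra(wavelengths_nm: Sequence[float] = DEFAULT_WAVELENGTHS_NM) -> ChromophoreSpectra:
    """Interpolate the shipped table at the requested wavelengths."""
    wl = tuple(float(w) for w in wavelengths_nm)
    absorption = {c: chromophore_spectrum(c, wl) for c in CHROMOPHORES}
    return ChromophoreSpectra(wavelengths_nm=wl, absorption=absorption)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Domain:
    """Axis-aligned box, optionally restricted to an inscribed z-cylinder.

    ``lo``/``hi`` are the box corners in um.  For ``kind="cylinder"`` the
    usable region is the cylinder of diameter ``hi[0]-lo[0]`` centred in the
    box with its axis along z (an agar cylinder in the sample holder).
    """

    lo: Tuple[float, float, float]
    hi: Tuple[float, float, float]
    kind: str = "box"

    def __post_init__(self) -> None:
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError("degenerate domain bounds")
        if self.kind not in ("box", "cylinder"):
            raise ValueError(f"unknown domain kind {self.kind!r}")

    @property
    def centre(self) -> np.ndarray:
        return (np.asarray(self.lo) + np.asarray(self.hi)) / 2.0

    def contains(self, point: Sequence[float], margin: float = 0.0) -> bool:
        p = np.asarray(point, dtype=float)
        lo = np.asarray(self.lo) + margin
        hi = np.asarray(self.hi) - margin
        if np.any(p < lo) or np.any(p > hi):
            return False
        if self.kind == "cylinder":
            c = self.centre
            r = min(self.hi[0] - self.lo[0], self.hi[1] - self.lo[1]) / 2.0 - margin
            return math.hypot(p[0] - c[0], p[1] - c[1]) <= r
        return True

    def sample(self, rng: np.random.Generator, margin: float = 0.0) -> np.ndarray:
        """Uniform point inside the domain (rejection for cylinders)."""
        lo = np.asarray(self.lo) + margin
        hi = np.asarray(self.hi) - margin
        for _ in range(_PLACEMENT_RETRY_CAP):
            p = rng.uniform(lo, hi)
            if self.contains(p, margin=margin):
                return p
        raise InfeasibleGeometryError("could not sample a point inside the domain")


def box_domain(extent_um: Sequence[float], centre_um: Sequence[float] = (0.0, 0.0, 0.0)) -> Domain:
    c = np.asarray(centre_um, dtype=float)
    e = np.asarray(extent_um, dtype=float) / 2.0
    return Domain(lo=tuple(c - e), hi=tuple(c + e), kind="box")


def cylinder_domain(diameter_um: float, height_um: float,
                    centre_um: Sequence[float] = (0.0, 0.0, 0.0)) -> Domain:
    c = np.asarray(centre_um, dtype=float)
    e = np.array([diameter_um / 2.0, diameter_um / 2.0, height_um / 2.0])
    return Domain(lo=tuple(c - e), hi=tuple(c + e), kind="cylinder")


# ---------------------------------------------------------------------------
# absorbers and scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Absorber:
    """A spherical optical absorber.

    ``concentrations`` maps chromophore name to a non-negative amplitude in
    arbitrary units; ``group`` tags absorbers belonging to the same vessel
    segment, which are exempt from the pairwise non-overlap rule.
    """

    centre: Tuple[float, float, float]
    radius: float
    concentrations: Mapping[str, float]
    group: Optional[int] = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not self.concentrations or all(v <= 0 for v in self.concentrations.values()):
            raise ValueError("at least one concentration must be positive")
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")

    def amplitude(self, spectra: ChromophoreSpectra, wavelength_nm: float) -> float:
        """Total absorption amplitude at one wavelength."""
        return sum(c * spectra.value(name, wavelength_nm)
                   for name, c in self.concentrations.items())

    @property
    def so2(self) -> Optional[float]:
        """Ground-truth oxygen saturation, if haemoglobin is present."""
        hb = self.concentrations.get("Hb", 0.0)
        hbo2 = self.concentrations.get("HbO2", 0.0)
        tot = hb + hbo2
        return None if tot == 0 else hbo2 / tot


@dataclass
class AbsorberScene:
    """Ground-truth container: a list of absorbers inside a domain."""

    absorbers: List[Absorber]
    domain: Domain
    label: str = ""
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in self.absorbers:
            if not self.domain.contains(a.centre, margin=a.radius):
                raise ValueError(f"absorber at {a.centre} outside domain")
        self._check_overlap()

    def _check_overlap(self) -> None:
        n = len(self.absorbers)
        if n < 2:
            return
        centres = np.array([a.centre for a in self.absorbers])
        radii = np.array([a.radius for a in self.absorbers])
        groups = np.array([-1 if a.group is None else a.group for a in self.absorbers])
        d = np.linalg.norm(centres[:, None, :] - centres[None, :, :], axis=-1)
        limit = radii[:, None] + radii[None, :]
        same_group = (groups[:, None] == groups[None, :]) & (groups[:, None] >= 0)
        bad = (d <= limit) & ~same_group & ~np.eye(n, dtype=bool)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"absorbers {i} and {j} overlap")

    def centres(self) -> np.ndarray:
        return np.array([a.centre for a in self.absorbers], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.absorbers], dtype=float)

    def amplitudes(self, spectra: ChromophoreSpectra, wavelength_nm: float) -> np.ndarray:
        return np.array(
            [a.amplitude(spectra, wavelength_nm) for a in self.absorbers], dtype=float
        )

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "label": self.label,
            "domain": {"lo": list(self.domain.lo), "hi": list(self.domain.hi),
                       "kind": self.domain.kind},
            "metadata": self.metadata,
            "absorbers": [
                {"centre": list(a.centre), "radius": a.radius,
                 "concentrations": dict(a.concentrations), "group": a.group}
                for a in self.absorbers
            ],
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AbsorberScene":
        obj = json.loads(text)
        dom = Domain(lo=tuple(obj["domain"]["lo"]), hi=tuple(obj["domain"]["hi"]),
                     kind=obj["domain"].get("kind", "box"))
        absorbers = [
            Absorber(centre=tuple(a["centre"]), radius=a["radius"],
                     concentrations=a["concentrations"], group=a.get("group"))
            for a in obj["absorbers"]
        ]
        return cls(absorbers=absorbers, domain=dom, label=obj.get("label", ""),
                   metadata=obj.get("metadata", {}))


# ---------------------------------------------------------------------------
# phantom generators
# ---------------------------------------------------------------------------

def make_microsphere_phantom(
    n_spheres: int,
    diameter_um: float = 20.0,
    domain: Optional[Domain] = None,
    min_separation_um: Optional[float] = None,
    seed: Optional[int] = None,
    amplitude: float = 1.0,
) -> AbsorberScene:
    """Broadband microspheres uniformly dispersed in an agar cylinder.

    Emulates the calibration target: 20 um black polyethylene microspheres in
    a 12 mm diameter agar gel cylinder.  Placement is uniform rejection
    sampling with pairwise centre separation at least ``min_separation_um``
    (default: one diameter).
    """
    if n_spheres < 1:
        raise ValueError("n_spheres must be >= 1")
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    radius = diameter_um / 2.0
    if min_separation_um is None:
        min_separation_um = diameter_um
    if min_separation_um < diameter_um:
        raise ValueError("min_separation must be at least one diameter")
    if domain is None:
        domain = cylinder_domain(12_000.0, 10_000.0)

    rng = np.random.default_rng(seed)
    placed: List[np.ndarray] = []
    for _ in range(n_spheres):
        for attempt in range(_PLACEMENT_RETRY_CAP):
            p = domain.sample(rng, margin=radius)
            if all(np.linalg.norm(p - q) >= min_separation_um for q in placed):
                placed.append(p)
                break
        else:
            raise InfeasibleGeometryError(
                f"could not place sphere {len(placed) + 1}/{n_spheres} at "
                f"separation {min_separation_um} um"
            )
    absorbers = [
        Absorber(centre=tuple(p), radius=radius,
                 concentrations={FLAT_CHROMOPHORE: amplitude})
        for p in placed
    ]
    return AbsorberScene(absorbers=absorbers, domain=domain,
                         label="microsphere-phantom",
                         metadata={"seed": seed, "diameter_um": diameter_um,
                                   "min_separation_um": min_separation_um})


def make_tumour_phantom(
    diameter_um: float = 8_000.0,
    rim_thickness_um: float = 1_500.0,
    n_vessels: int = 40,
    rim_so2: float = 0.9,
    core_so2: float = 0.3,
    seed: Optional[int] = None,
    vessel_radius_um: float = 30.0,
    vessel_length_um: Optional[Tuple[float, float]] = None,
    rim_density_bias: float = 2.0,
    hbt_amplitude: float = 1.0,
) -> AbsorberScene:
    """Tumour-like scene: vessel segments in a sphere with rim/core sO2.

    Vessels are chains of overlapping spheres (intra-vessel overlap allowed,
    inter-vessel non-overlap enforced).  Every absorber carries Hb/HbO2
    concentrations realizing exactly ``rim_so2`` in the outer shell of
    thickness ``rim_thickness_um`` and ``core_so2`` inside; vessel density is
    biased towards the rim by ``rim_density_bias``.
    """
    if not (0.0 <= core_so2 <= rim_so2 <= 1.0):
        raise ValueError("need 0 <= core_so2 <= rim_so2 <= 1")
    if not (0 < rim_thickness_um < diameter_um / 2.0):
        raise ValueError("rim thickness must be in (0, diameter/2)")
    if n_vessels < 1:
        raise ValueError("n_vessels must be >= 1")

    R = diameter_um / 2.0
    r_core = R - rim_thickness_um
    rng = np.random.default_rng(seed)
    if vessel_length_um is None:
        vessel_length_um = (0.25 * R, 0.6 * R)

    core_vol = r_core ** 3
    rim_vol = R ** 3 - core_vol
    p_rim = rim_density_bias * rim_vol / (rim_density_bias * rim_vol + core_vol)

    domain = box_domain((diameter_um + 4 * vessel_radius_um,) * 3)
    spacing = vessel_radius_um  # centre-to-centre step along a chain

    def region_of(p: np.ndarray) -> str:
        return "core" if np.linalg.norm(p) <= r_core else "rim"

    def sample_in_region(region: str) -> np.ndarray:
        for _ in range(_PLACEMENT_RETRY_CAP):
            p = rng.uniform(-R, R, size=3)
            r = np.linalg.norm(p)
            if r > R - vessel_radius_um:
                continue
            if region_of(p) == region:
                return p
        raise InfeasibleGeometryError(f"cannot sample a start point in the {region}")

    absorbers: List[Absorber] = []
    placed_other: List[Tuple[np.ndarray, float, int]] = []  # centre, radius, group

    def conc_for(p: np.ndarray) -> Dict[str, float]:
        s = rim_so2 if region_of(p) == "rim" else core_so2
        return {"Hb": (1.0 - s) * hbt_amplitude, "HbO2": s * hbt_amplitude}

    for v in range(n_vessels):
        region = "rim" if rng.random() < p_rim else "core"
        for attempt in range(_PLACEMENT_RETRY_CAP):
            start = sample_in_region(region)
            if all(np.linalg.norm(start - c) > vessel_radius_um + rr
                   for c, rr, g in placed_other):
                break
        else:
            raise InfeasibleGeometryError(f"cannot place vessel {v}")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(*vessel_length_um)
        n_links = max(2, int(length / spacing))
        chain: List[np.ndarray] = []
        for k in range(n_links):
            p = start + k * spacing * direction
            if np.linalg.norm(p) > R - vessel_radius_um:
                break  # stay inside the tumour sphere
            if any(np.linalg.norm(p - c) <= vessel_radius_um + rr
                   for c, rr, g in placed_other):
                break  # stop before hitting another vessel
            chain.append(p)
        if not chain:
            continue
        for p in chain:
            absorbers.append(Absorber(centre=tuple(p), radius=vessel_radius_um,
                                      concentrations=conc_for(p), group=v))
            placed_other.append((p, vessel_radius_um, v))

    if not absorbers:
        raise InfeasibleGeometryError("no vessels could be placed")
    scene = AbsorberScene(absorbers=absorbers, domain=domain,
                          label="tumour-phantom",
                          metadata={"seed": seed, "diameter_um": diameter_um,
                                    "rim_thickness_um": rim_thickness_um,
                                    "rim_so2": rim_so2, "core_so2": core_so2,
                                    "core_radius_um": r_core})
    return scene
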