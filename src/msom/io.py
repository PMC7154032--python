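"""File I/O for every pipeline stage.

Sinograms are stored as HDF5 (float32 ``/data`` [pulse, element, sample]
with pose datasets and plan/array metadata in attributes), volumes as
multi-page float32 TIFF (one page per z slice, voxel geometry in the image
description and resolution tags) or NIfTI-1 (um -> mm scaling), scenes as
JSON, spectra and heterogeneity reports as CSV, and run manifests as JSON
with SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Union

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .forward import Sinogram
from .phantom import AbsorberScene, ChromophoreSpectra
from .recon import Volume
from .scanner import ArraySpec, PoseSet, ScanPlan
from .texture import HeterogeneityReport

__all__ = [
    "load_scene", "load_sinogram", "load_spectra_csv", "load_volume_nifti",
    "load_volume_tiff", "save_scene", "save_sinogram", "save_spectra_csv",
    "save_report", "save_volume_nifti", "save_volume_tiff", "sha256_file",
    "write_manifest",
]

PathLike = Union[str, Path]


class FileFormatError(RuntimeError):
    """A file could not be parsed as the expected format."""


# -- sinograms --------------------------------------------------------------

def save_sinogram(path: PathLike, sinogram: Sinogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=sinogram.data.astype(np.float32))
        g = f.create_group("poses")
        g.create_dataset("positions", data=sinogram.poses.positions)
        g.create_dataset("normals", data=sinogram.poses.normals)
        g.create_dataset("elevations", data=sinogram.poses.elevations)
        g.create_dataset("angles_deg", data=sinogram.poses.angles_deg)
        g.create_dataset("z_um", data=sinogram.poses.z_um)
        f.attrs["plan"] = json.dumps(dataclasses.asdict(sinogram.plan))
        f.attrs["array"] = json.dumps(dataclasses.asdict(sinogram.array))
        f.attrs["wavelength_nm"] = sinogram.wavelength_nm
        f.attrs["meta"] = json.dumps(sinogram.meta, default=str)
        f.attrs["units"] = "positions:um time:us frequency:MHz"


def load_sinogram(path: PathLike) -> Sinogram:
    try:
        with h5py.File(path, "r") as f:
            data = f["data"][...]
            plan_d = json.loads(f.attrs["plan"])
            array_d = json.loads(f.attrs["array"])
            if "response_band_MHz" in array_d:
                array_d["response_band_MHz"] = tuple(array_d["response_band_MHz"])
            poses = PoseSet(
                positions=f["poses/positions"][...],
                normals=f["poses/normals"][...],
                elevations=f["poses/elevations"][...],
                angles_deg=f["poses/angles_deg"][...],
                z_um=f["poses/z_um"][...],
            )
            return Sinogram(data=data, plan=ScanPlan(**plan_d),
                            array=ArraySpec(**array_d),
                            wavelength_nm=float(f.attrs["wavelength_nm"]),
                            poses=poses, meta=json.loads(f.attrs["meta"]))
    except (OSError, KeyError) as exc:
        raise FileFormatError(f"{path}: not a valid sinogram file "
                              f"(first problem: {exc})") from exc


# -- volumes ----------------------------------------------------------------

def save_volume_tiff(path: PathLike, volume: Volume) -> None:
    vx_cm = volume.voxel_size_um * 1e-4
    desc = json.dumps({"voxel_size_um": volume.voxel_size_um,
                       "origin_um": list(volume.origin_um),
                       "channel": volume.channel,
                       "meta": volume.meta}, default=str)
    tifffile.imwrite(path, volume.values.astype(np.float32),
                     photometric="minisblack",
                     resolution=(1.0 / vx_cm, 1.0 / vx_cm),
                     resolutionunit="CENTIMETER", description=desc)


def load_volume_tiff(path: PathLike) -> Volume:
    try:
        with tifffile.TiffFile(path) as tf:
            values = tf.asarray()
            desc = tf.pages[0].description
        info = json.loads(desc)
        return Volume(values=values, voxel_size_um=info["voxel_size_um"],
                      origin_um=tuple(info["origin_um"]),
                      channel=info.get("channel", ""),
                      meta=info.get("meta", {}))
    except (tifffile.TiffFileError, json.JSONDecodeError, KeyError) as exc:
        raise FileFormatError(f"{path}: not a valid volume TIFF "
                              f"(first problem: {exc})") from exc


def save_volume_nifti(path: PathLike, volume: Volume) -> None:
    vx_mm = volume.voxel_size_um / 1000.0
    affine = np.diag([vx_mm, vx_mm, vx_mm, 1.0])
    affine[:3, 3] = np.asarray(volume.origin_um) / 1000.0
    # NIfTI is x-fastest; our array is [z, y, x]
    img = nib.Nifti1Image(np.ascontiguousarray(volume.values.T).astype(np.float32),
                          affine)
    nib.save(img, str(path))


def load_volume_nifti(path: PathLike) -> Volume:
    img = nib.load(str(path))
    vx_mm = float(img.affine[0, 0])
    origin = tuple(float(v) * 1000.0 for v in img.affine[:3, 3])
    values = np.asarray(img.dataobj).T.astype(np.float32)
    return Volume(values=values, voxel_size_um=vx_mm * 1000.0, origin_um=origin)


# -- scenes, spectra, reports -----------------------------------------------

def save_scene(path: PathLike, scene: AbsorberScene) -> None:
    Path(path).write_text(scene.to_json())


def load_scene(path: PathLike) -> AbsorberScene:
    try:
        return AbsorberScene.from_json(Path(path).read_text())
    except (json.JSONDecodeError, KeyError) as exc:
        raise FileFormatError(f"{path}: not a valid scene file "
                              f"(first problem: {exc})") from exc


def save_spectra_csv(path: PathLike, spectra: ChromophoreSpectra) -> None:
    df = pd.DataFrame({"wavelength_nm": spectra.wavelengths_nm})
    for name, vec in spectra.absorption.items():
        df[name] = vec
    df.to_csv(path, index=False)


def load_spectra_csv(path: PathLike) -> ChromophoreSpectra:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise FileFormatError(f"{path}: missing 'wavelength_nm' column")
    names = [c for c in df.columns if c != "wavelength_nm"]
    return ChromophoreSpectra(
        wavelengths_nm=tuple(float(w) for w in df["wavelength_nm"]),
        absorption={n: df[n].to_numpy(dtype=float) for n in names})


def save_report(path_csv: PathLike, report: HeterogeneityReport,
                path_json: Optional[PathLike] = None) -> None:
    pd.DataFrame(report.to_records()).to_csv(path_csv, index=False)
    if path_json is not None:
        Path(path_json).write_text(json.dumps({
            "regions": report.regions,
            "relative_differences": report.relative_differences,
            "n_sections": report.n_sections,
            "meta": report.meta,
        }, indent=1, sort_keys=True, default=str))


# -- manifests ----------------------------------------------------------------

def sha256_file(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: PathLike, artifacts: Dict[str, PathLike],
                   config: Optional[dict] = None,
                   seed: Optional[int] = None) -> dict:
    root = Path(path).parent
    manifest = {
        "seed": seed,
        "config": config,
        "artifacts": {
            name: {"path": str(Path(p).relative_to(root)
                               if Path(p).is_relative_to(root) else Path(p)),
                   "sha256": sha256_file(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                     default=str))
    return manifest
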