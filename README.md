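# msom — conical multispectral optoacoustic mesoscopy toolkit

`msom` re-implements the computational pipeline of conical-scan
multispectral optoacoustic mesoscopy (MSOM), an imaging technique that
resolves optical absorption — haemoglobin, oxygenation, injected
nanoparticles — throughout entire solid tumours in vivo at tens-of-µm
resolution. A cylindrically focused 96-element linear array, tilted 45° to
the rotation plane, rotates (255°) and translates (10 mm) around the
sample while a pulsed laser excites broadband ultrasound; volumetric
images are formed by delay-and-sum backprojection and multi-wavelength
stacks are spectrally unmixed into functional maps.

The package is aimed at researchers developing or validating optoacoustic
reconstruction and tumour-heterogeneity analysis: it provides synthetic
phantoms with known ground truth, an analytic acoustic forward model, and
the full analysis chain, so every stage can be tested quantitatively
without instrument data.

## What it computes

* **Forward model** — the far-field N-wave of a uniformly heated sphere,
  `p(t) ∝ −(t − d/c)/(r/c)` on `|t − d/c| ≤ r/c`, band-limited by the
  detector's receive spectrum and weighted by light fluence
  `exp(−µ_eff · depth)`, elevation acceptance and 1/d.
* **Reconstruction** — delay-and-sum backprojection (optionally the
  universal-backprojection term `p − t·dp/dt`) of zero-phase
  Butterworth-filtered sinograms; dual-band imaging in 1–7.5 MHz and
  4–28 MHz with per-band normalization ("frequency equalization");
  speed-of-sound autofocus calibration; FWHM resolution measurement.
* **Spectral unmixing** — per voxel least squares of the wavelength stack
  against Hb, HbO₂, AuNP and a constant background, with a non-negative
  mode; `HbT = Hb + HbO₂`, `sO₂ = HbO₂/HbT`, and relative-residual
  spectral error maps.
* **Heterogeneity analysis** — histogram statistics (mean, variance,
  skewness, kurtosis, energy, entropy), Tamura coarseness/contrast/
  directionality, tumour segmentation with centre/rim partition along
  radial rays, relative differences |c−r|/(c+r), and 400 µm-section MIP
  averaging.
* **Image correspondence** — moving-mean line profiles, standardized
  256-bin histograms, and a 64-bit DCT perceptual hash with Hamming
  distance (similarity threshold 32.00).

See `docs/methods.md` for the model assumptions and numerical choices.

## Worked example

Simulate a small tumour phantom with an oxygenated rim and hypoxic core,
reconstruct it at five wavelengths, unmix, and compare the recovered
oxygen saturation at the vessel positions with the ground truth:

```python
import numpy as np
from msom import (make_tumour_phantom, load_spectra, simulate_sinogram,
                  butter_bandpass, DEFAULT_BANDS, ReconConfig, backproject,
                  linear_unmix, ScanPlan)

scene = make_tumour_phantom(diameter_um=1200.0, rim_thickness_um=300.0,
                            n_vessels=8, rim_so2=0.9, core_so2=0.3,
                            vessel_radius_um=40.0, seed=0)
spectra = load_spectra()                      # Hb / HbO2 / AuNP at 710-850 nm
plan = ScanPlan(n_pulses=200)                 # reduced conical scan
cfg = ReconConfig(extent_um=(1500.0,) * 3, voxel_size_um=50.0,
                  use_derivative_term=True)

volumes = []
for wl in spectra.wavelengths_nm:             # one sinogram per wavelength
    sino = simulate_sinogram(scene, spectra, wavelength_nm=wl, plan=plan)
    volumes.append(backproject(butter_bandpass(sino, DEFAULT_BANDS["full"]), cfg))

result = linear_unmix(np.stack([v.values for v in volumes]), spectra, nonneg=True)

centres = scene.centres()
idx = np.round((centres - np.asarray(volumes[0].origin_um)) / 50.0).astype(int)
so2 = result.so2[idx[:, 2], idx[:, 1], idx[:, 0]]
r = np.linalg.norm(centres, axis=1)
core = r <= scene.metadata["core_radius_um"]
print(f"vessels: {len(centres)} spheres in {core.sum()} core / {(~core).sum()} rim positions")
print(f"recovered core sO2: {np.nanmean(so2[core]):.3f}  (ground truth 0.30)")
print(f"recovered rim  sO2: {np.nanmean(so2[~core]):.3f}  (ground truth 0.90)")
```

Output (a couple of minutes on one CPU):

```
vessels: 34 spheres in 6 core / 28 rim positions
recovered core sO2: 0.333  (ground truth 0.30)
recovered rim  sO2: 0.874  (ground truth 0.90)
```

The recovered saturations sit within a few percent of the ground truth
and preserve the rim > core ordering — the blur and limited-view
sidelobes of the 255° conical scan shift vessel-site estimates only
slightly.

A full pipeline run (phantom → simulate → preprocess → dual-band
reconstruction → equalization → unmixing → heterogeneity report →
checksummed manifest) is available as `msom run` on the command line or
`msom.run_pipeline(msom.demo_config("out", seed=0))` from Python; the same
seed always yields bitwise-identical artifacts.

## Command-line interface

`msom` exposes thin subcommands over the library: `phantom`, `simulate`,
`preprocess`, `reconstruct`, `calibrate-sos`, `unmix`, `analyze`,
`compare` and `run`; see `msom --help`. Sinograms are HDF5, volumes are
multi-page float32 TIFF (or NIfTI-1), scenes/manifests are JSON, spectra
and reports are CSV.
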