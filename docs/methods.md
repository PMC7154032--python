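# Methods

`msom` simulates and analyses conical-scan multispectral optoacoustic
mesoscopy (MSOM) experiments end to end: synthetic absorber scenes,
acoustic forward simulation, dual-band delay-and-sum reconstruction,
linear spectral unmixing, and spatial-heterogeneity quantification. This
note records the model, its assumptions, the defaults that matter, and
the design decisions taken where the problem was genuinely open.

## Coordinate and unit conventions

Right-handed coordinates with z along the rotation/translation axis.
Positions are in µm, time in µs, frequencies in MHz; the speed of sound is
stored in m/s, which is numerically identical to µm/µs. Angles are degrees
at interfaces and radians internally. Voxel coordinates are voxel-centre
based with 0-based indexing.

## Scan geometry (`scanner`)

The detector is a 96-element linear array (100 µm pitch, 1.5 mm elevation
aperture cylindrically focused at 7.8 mm, 15 MHz centre frequency, 45%
fractional −6 dB bandwidth) mounted at 45° to the rotation plane. During a
scan it rotates over 255° and translates over 10 mm, both linear in the
pulse index (a helix); the central (48th) element stays exactly 5.8 mm
from the axis, so the focal line of the lens sweeps a cone close to the
axis. The default record is sampled at 125 MS/s. One pose is generated per
laser pulse; intra-record motion (sub-µm) is ignored. The start angle is
0° and rotation is counter-clockwise; `ScanPlan.z_start_mm=None` centres
the focal sweep on z = 0, which is where scenes are conventionally placed.

Cylindrical elevation focusing is represented by a point detector at the
element position with a Gaussian acceptance in the out-of-plane angle ψ
(sin ψ = projection of the voxel direction onto the elevation axis). Its
width defaults to the lens half-aperture angle,
`atan(0.75 mm / 7.8 mm) ≈ 5.5°`, and the same weight is used in the
forward model and (by default) in reconstruction; a flag disables it.

## Forward model (`forward`)

Each absorber is a uniformly heated fluid sphere whose far-field pressure
is the classic N-wave: linear and bipolar (positive then negative) inside
`|t − d/c| ≤ r/c`, zero outside, amplitude ∝ (per-wavelength absorption) ×
(light fluence at the absorber) / distance, and zero time integral. The
medium is homogeneous (default c = 1500 m/s) and non-attenuating; an
optional STFT power-law filter (`α(f) = α₀·f`, depth = c·t) provides
acoustic attenuation for round-trip tests of the compensation filter.

Sinograms are synthesized in the frequency domain: the analytic N-wave
spectrum `2(sin ωτ − ωτ cos ωτ)/(τω²)` (τ = r/c) is multiplied by the
detector receive spectrum and the time-of-flight phase ramp and inverse
transformed onto the 125 MS/s grid. This is an exact sampling of the
band-limited continuous signal; the sphere transit of a 20 µm sphere
(≈13 ns) is shorter than one sample and would alias under naive
time-domain sampling. With the receive response disabled the exact
time-domain N-wave is sampled instead. Noise is additive white Gaussian
per sample, reproducible under a fixed seed. The record window is
auto-sized to cover all element–absorber delays plus a 0.35 µs margin.

### Detector receive response

Two one-way amplitude models are provided (`ArraySpec.response_model`):

* `"gaussian"` (default): Gaussian peaking at 15 MHz with −6 dB full
  width 0.45 × 15 = 6.75 MHz, i.e. the resonance implied by the array's
  nominal fractional bandwidth.
* `"broadband"`: third-order Butterworth band magnitude over 1–30 MHz,
  modelling a receive chain whose usable detection band spans ~1–30 MHz.

Neither idealization reproduces every published calibration figure of the
real instrument simultaneously. Under the default resonant model the
simulated microsphere study gives in-plane FWHM ≈ 64 µm (full band,
1–28 MHz) and ≈ 88 µm (low band, 1–7.5 MHz), close to the reported 62 and
92 µm; but the received spectrum has negligible energy above ~22 MHz, so
the high band (4–28 MHz) measures ≈ 64 µm instead of the reported ~38 µm —
a genuinely narrowband detector cannot deliver 38 µm. Under the broadband
model the high band is sharp but the full band (≈ 49 µm) and low band
(≈ 136 µm) drift away from the reported values. We keep the resonant
model as the default study condition and report the high-band discrepancy
rather than fitting a hybrid response to the published numbers. The strict
resolution ordering FWHM(high) < FWHM(full) < FWHM(low) holds under the
default model.

## Preprocessing (`preprocess`)

Denoising uses a third-order Butterworth bandpass (default 1–28 MHz)
applied forward–backward (`sosfiltfilt`), i.e. zero phase with squared
magnitude; band corners are the −3 dB points. Zero phase is chosen because
backprojection relies on arrival-time fidelity. Dual-band splitting uses
the same filter at 1–7.5 MHz (low) and 4–28 MHz (high).

The time-variant attenuation compensation is realized as an STFT-domain
gain: hann windows of 128 samples with 75% overlap (an exact
reconstruction pair), per-window gain `α₀ · f · c·t` dB capped at 20 dB by
default. `α₀ = 0` returns the input unchanged.

## Reconstruction (`recon`)

Delay-and-sum backprojection: every voxel sums, over all pulse/element
pairs, the filtered trace value at the voxel time of flight (linear
interpolation between samples — at 125 MS/s one sample is 12 µm of range,
which would dominate the error budget of ~40 µm targets under
nearest-neighbour lookup), weighted by 1/distance and the elevation
acceptance. The universal-backprojection term `p − t·dp/dt` is available
behind a flag (default off for plain summation; all resolution studies in
this package run with it on, since it sharpens the bipolar N-shape).
Contributions whose delay falls outside the record contribute zero and a
warning is issued if they exceed 1% of all contributions.

The default whole-volume grid is 24 µm isotropic; resolution measurements
use a local 6 µm grid around the sphere, since a ~40–90 µm FWHM cannot be
measured reliably on a 24 µm grid.

Speed-of-sound calibration is an autofocus grid search: the candidate
maximizing the peak voxel intensity of a coarse backprojection of the
microsphere phantom is returned (the sphere image collapses to a bright
point only at the true speed). Boundary optima are reported with a
warning.

Frequency equalization normalizes each band volume independently to its
own 99.9th-percentile robust maximum and stacks them as a two-channel
composite; there is no cross-band mixing. Fluence correction divides each
voxel by `exp(−µ_eff · depth)` with the divisor floored at 1e-3; depth is
measured inward from a cylindrical illumination surface by default (side
illumination of a protruding sample), or from a plane.

Resolution is quantified by `measure_fwhm`: axis-aligned profiles through
the intensity peak, cubic-spline upsampled ×8; the local background is the
median of the outer quarters of the profile and the width is taken at half
the peak above it, with linear interpolation of the crossings.

## Spectral unmixing (`unmix`)

Per voxel, ordinary least squares of the measured multi-wavelength
spectrum against the columns [Hb, HbO₂, AuNP, 1]; the constant column
absorbs the background, matching a linear-unmixing formulation with a
constant background spectrum. The non-negative mode constrains the
chromophores to ≥ 0 (the background stays free, implemented by splitting
the constant column into ±1 columns inside NNLS) and guarantees
sO₂ ∈ [0, 1]. It is applied only to voxels whose unconstrained solution
violates non-negativity, so exact-solvable voxels are untouched.
HbT = Hb + HbO₂ exactly; sO₂ = HbO₂/HbT where HbT exceeds a validity
threshold (default 1% of the 99th-percentile HbT — division noise at
near-zero HbT must be controlled; the choice only affects masking, not
values). Spectral error maps fit a restricted design (Hb+HbO₂, or AuNP)
and report ‖residual‖₂/‖signal‖₂ per pixel, masked where the signal norm
vanishes. No absolute calibration is attempted: all amplitudes are
relative, as is sO₂.

### Chromophore spectra

The shipped table (`data/chromophores.csv`, 690–900 nm on a 10 nm grid,
linear interpolation) holds Hb/HbO₂ extinction values from the standard
omlc.org (Prahl) compilation, normalized by a *common* factor so that the
Hb:HbO₂ ratio — hence sO₂ — is preserved and the isosbestic crossing stays
near 800 nm; the AuNP spectrum is a smooth Gaussian band peaking at
780 nm (σ = 50 nm), matching the plasmon resonance of the 780 nm gold
nanorods used for contrast. The default excitation set is 710, 750, 780,
810, 850 nm; the 5×4 design matrix at these wavelengths has full column
rank.

## Heterogeneity metrics (`texture`)

First-order statistics over a masked region: mean, variance, skewness and
kurtosis are population moments of the raw (unbinned) intensities;
**kurtosis is non-excess** (Gaussian → 3). Energy (Σp²) and entropy
(−Σp log₂p) use a 256-bin equal-width histogram over the masked min–max
range. Computing moments from raw values avoids binning bias while the
256-bin histogram matches the standard convention for energy/entropy.

Tamura features follow the classic definitions with the ambiguities fixed
as follows. *Coarseness*: for each pixel and window size 2^k (k = 1…5,
capped by the image size), the absolute difference of mean intensity
between the two adjacent non-overlapping 2^k×2^k blocks on either side of
the pixel, horizontally and vertically; the pixel's best size maximizes
this difference with ties broken towards the smallest window (so a
constant image scores 2); coarseness is the mean best size. *Contrast*:
σ/α₄^(1/4) with α₄ the fourth standardized moment; 0 for constant images.
*Directionality*: 3×3 derivative operators, orientation histogram
(16 bins over [0, π)) of pixels with gradient magnitude ≥ the mean
magnitude; every bin is assigned to its nearest histogram peak and
directionality is `1 − clip(n_peaks · F / (π²/12))`, F being the summed
second moments of the histogram around its peaks (π²/12 is the variance of
a flat orientation distribution). All three match independent brute-force
reimplementations exactly on small images.

Tumour segmentation (the source paper gives no algorithm): Gaussian
smoothing (σ = 2 px), Otsu threshold, largest connected component,
morphological closing, hole filling; the centre point is the
intensity-weighted centroid. The centre/rim partition computes, for every
mask pixel, its fractional radial position t along the ray from the centre
point through the pixel to the boundary (the last mask pixel on the
discretized ray, 0.5 px steps); centre = {t ≤ cutoff}, rim = {t > cutoff}.
The cutoff is a parameter (default 0.6; the published analysis does not
state its value). The partition is exact by construction. Relative
centre–rim differences are |c − r|/(c + r). Whole-tumour values average
the per-section metrics over MIPs of consecutive 400 µm sections.

## Image correspondence (`compare`)

Line profiles sample a segment at unit-pixel steps with bilinear
interpolation and apply a centred moving mean with shrinking end windows
(windows 60/240 reproduce the published smoothing). Standardized
histograms spline-resample to 256×256, subtract the modal background,
clip negatives and bin into 256 equal-width bins.

The 64-bit perceptual hash takes the 8×8 lowest-frequency block of the
orthonormal 2-D DCT-II — an ideal band-limited 32×32 resample realized in
the DCT domain, which makes the hash exactly resolution-invariant for
band-limited content — and thresholds each coefficient at the median of
the 64 block coefficients (even count, interpolated median, so intensity
negation flips all 64 bits and positive affine maps flip none). Two codes
are "similar" when their Hamming distance is strictly below 32.00.

## Synthetic data (`phantom`)

The microsphere phantom emulates 20 µm black polyethylene microspheres
uniformly dispersed in a 12 mm agar cylinder; spheres are wavelength-flat
("black") absorbers placed by rejection sampling (cap 10 000 tries per
absorber) with a minimum separation of one diameter. The tumour phantom is
a sphere of vessel segments — chains of overlapping spheres (intra-vessel
overlap allowed, inter-vessel non-overlap enforced) — whose Hb/HbO₂
concentrations realize the requested sO₂ exactly per region: an oxygenated
rim shell and a hypoxic core, with vessel density biased 2:1 towards the
rim. Defaults follow the imaged tumours (8 mm diameter; study conditions
reduce this for runtime, see below).

What the generator does **not** emulate: realistic vascular trees,
heterogeneous acoustic/optical property maps, laser pulse shape
(≤ 10 ns, absorbed into the impulse response), element directivity beyond
the elevation focus, or electronic noise correlations. Passing tests
therefore demonstrate correctness of the algorithms under the stated
physics, not instrument-level realism.

## Study problem sizes

The package's standard desk-scale studies use: 1200 pulses for the
microsphere resolution study (the full acquisition is ~7286 pulses; the
helical coverage at 1200 is already dense enough that the FWHM is stable),
reconstructed on a 6 µm grid of 64×64×13 voxels; and a 1.6 mm tumour
phantom (16 vessels, 40 µm vessel radius), 320 pulses, five wavelengths,
reconstructed at 50 µm for the recovery study, with region-mean sO₂
evaluated at the known vessel positions. The demo pipeline uses a 1.4 mm
phantom, 120 pulses and 75 µm voxels.

## Known limitations

* The backprojection is unregularized delay-and-sum; limited-view
  (255°) and band-limitation artefacts (negative sidelobes, anisotropic
  in-plane PSF) are present and propagate into unmixed maps.
* Region-mean sO₂ over *all* voxels of a region is biased towards 0.5 by
  sidelobe mixing under non-negative unmixing; recovery is quantified at
  vessel locations instead.
* The attenuation-compensation filter is exercised only through
  round-trip tests against the package's own forward attenuation model.
* No absolute quantification anywhere; all image values are relative.
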