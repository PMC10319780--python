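# Methods

This note documents the models behind `lfoct`, the choices that were
genuinely open, and what the synthetic data can and cannot show about
real measurements.

## Forward model

**Spectral axis.** The spectrograph maps pixel `p` to wavelength
`λ(p) = λ_min + p·d` with `d = (λ_max − λ_min)/N` (half-open
convention; for the nominal 796–879 nm over 1920 pixels,
`d = 0.0432 nm`, which prints as 0.04 nm at two decimals).  The
practical spectral resolution is the two-pixel Airy-sampled value
2 × 0.04 = 0.08 nm, quoted — as instrument specifications are — from
the rounded interval.  With 2×2 binning, adjacent pixel pairs are
averaged: half the pixels at twice the spacing, with no loss of depth
range.

**Interferogram.** Each camera row `y` is

    I(x, y) = I_ref(x) [ 1 + Σⱼ aⱼ² + 2 Σⱼ aⱼ cos(2 k(x) zⱼ(y) + φⱼ) ],

summed over the interfaces and sub-resolution scatterers of that
column.  Sample–sample (autocorrelation) interference is neglected:
with the reference much stronger than any sample return it is orders
of magnitude below the cross terms.  `I_ref` carries the Gaussian
source envelope (833 nm centre, 40 nm FWHM) and is anchored so the
envelope peak fills 50% of the camera full well at the nominal
exposure (0.5 ms) — a common operating point for shot-noise-limited
spectral-domain detection; the instrument's actual reference power is
not public, so this is a configurable convention (`reference_fill`).

**Resolution and pixel integration.** The spectrum is synthesized at 4
subpixels per camera pixel, convolved along the spectral axis with a
Gaussian of FWHM 0.08 nm, and box-averaged per pixel.  Both causes of
sensitivity roll-off — finite spectral resolution (Gaussian factor) and
pixel integration (sinc² factor) — therefore *emerge* from the
simulation; the closed-form model lives separately in `lfoct.metrics`
and is used only as a cross-check.  Four subpixels keep the discrete
box average within ~0.15 dB of true pixel integration at 80% of the
Nyquist depth.  A spectrally constant kernel is used; the real
instrument's resolution degrades towards the band edges (0.18/0.22 nm),
for which no functional form is published — per-pixel widths are
configurable but default to constant.

**Camera.** Poisson shot noise in electrons, additive Gaussian read
noise (7 e⁻ rms), full-well clipping, and rounding to 12-bit counts
(gain = full well / 2¹²).  Rows whose predicted electrons exceed the
full well are flagged saturated.  Noise-free frames (`noise_on=False`)
are returned as idealized float counts without clipping or
quantization — the metrology procedures (PSF fit, roll-off) need the
undistorted fringe, and clipping a unit-reflector fringe would add
harmonics that a Gaussian PSF fit does not model; saturation is still
flagged.

**Precision.** Fringe phases are accumulated in float32 after reducing
each reflector's band-edge phase modulo 2π in float64 ("fast" path,
worst-case phase error ~2×10⁻⁴ rad ≈ 10⁻⁴ of the fringe amplitude,
~3× faster than float64 for speckled volumes).  An "exact" float64
path exists and is what the closed-form oracle tests use, together
with `oversample=1` and the blur disabled.

## Reconstruction

Background subtraction (the background frame passes through the same
blur/integration chain, so the reference term cancels exactly), then
per-row resampling from the wavelength grid to `N` uniform wavenumber
samples over `[2π/λ_max, 2π/λ_min]`, then optional window, zero
padding, FFT, one-sided magnitude with the DC bin dropped.

The resampling is FFT zero-pad upsampling (×8) followed by cubic
convolution at the target positions.  A cubic interpolant applied
directly to the raw grid attenuates fringes near Nyquist by several dB
(measured −3.6 dB at 0.8× Nyquist), which would corrupt deep-depth
roll-off; after band-limited upsampling the interpolation transfer is
flat to <0.01 dB over the usable range, and round-trip error is
~3×10⁻⁴.

Depth scale: `z_max = λ₀²/(4 δλ_s)` with λ₀ the band centre
(837.5 nm) and `δλ_s` the mean sampling interval, giving
z_max ≈ 4.06 mm and 4.23 µm per unpadded bin.  The axis is
air-equivalent; group-index correction happens in the thickness map.
Defaults: Hann window for imaging (rectangular for closed-form
metrology), zero-pad 4 for PSF fitting, zero-pad 2 for segmentation
volumes — at integer-bin surface maps the latter quantizes thickness
at 1.54 µm geometric per bin, comfortably below the layer thicknesses
recovered, while FFT cost stays negligible next to frame synthesis.
No numerical dispersion compensation is applied (the modelled
instrument uses none).

## Segmentation

Three steps per B-scan:

1. **Artifact removal.**  A-scan columns whose mean intensity exceeds
   the column-mean average by 3 SD are flagged as saturation stripes
   (σ = 0 guarded).  Horizontal banding is removed by subtracting each
   depth-row's mean, computed excluding flagged columns, with negatives
   clipped; flagged columns are re-filled by lateral linear
   interpolation; a 5×5 adaptive Wiener filter denoises, with noise
   power estimated as the lower quartile of the local variance map so
   that structure is preserved and a noise-free image is a fixed point.
2. **Air/subject surface.**  Coarse estimate: per-column intensity
   argmax (ties towards smaller depth; empty columns filled from
   neighbours).  Refinement: with the axial gradient
   `g[y,z] = I[y,z] − I[y,z−1]`, accept at the centre column the
   argmax of `g` within ±W of the coarse estimate, then proceed
   outward, each column taking the argmax of
   `w(|z−z_prev|)·g(y,z)` over `z_prev ± W` with linearly decreasing
   ("decrement") weights `w(δ) = 1 − δ/(W+1)`, W = 5 bins.  A window
   with no positive gradient keeps the neighbour's depth and flags the
   column — chasing least-negative evidence would walk the boundary
   away from the surface.
3. **Inner layers.**  A global offset `μ* = argmax_{μ∈α} Σ_y g(y,
   f(y)+μ)` below the refined surface (exhaustive search over the
   configured window α, scaled by the zero-pad factor), then the same
   centre-outward refinement from `f + μ*`.  Offset windows: 20–60
   unpadded bins for the epithelium/stroma interface, 150–450 for the
   endothelium, 5–120 for the PCB coating bottom.

Consequences worth knowing:

- The tracker follows interface *ramps* up to W bins per column
  exactly, catches *steps* up to ~W bins within a couple of columns,
  and **cannot** follow a cliff larger than W — it holds the old level
  and flags the columns.  Tall vertical component edges are outside
  the method's validity regime.
- The global offset μ* is a single number per B-scan.  It is robust
  when the layer-thickness field is radial (centre-extremal): the
  centre column then sits at the extremum of the per-B-scan offset
  profile, where the column density per offset bin peaks, so the score
  mode coincides with the centre-column offset.  For thickness fields
  that vary randomly by more than ~W bins within a B-scan, the centre
  start can miss the interface and the whole B-scan mistracks — a
  genuine fragility of the single-offset design.
- The gradient argmax carries a small constant depth bias that depends
  on the PSF width (≈1–3 bins towards the surface with the Hann
  window); it is shared by all interfaces segmented the same way and
  cancels in thickness differences.

Thickness: `(lower − upper) · depth_scale / n_group`, crossing
surfaces masked with a warning, equal surfaces flagged degenerate;
mean ± SD summaries overall and per ground-truth region label.
Group indices: cornea 1.376, conformal coating 1.50 (PDMS 1.40 where
relevant) — the phantoms store geometric thickness and index, the
simulator produces optical paths, and the recovery divides by the
configured index, so ground truth is unambiguous.

## Metrology

- Theoretical axial resolution `(2 ln 2/π) λ₀²/Δλ` = 7.65 µm in air
  for 833/40 nm.
- The measured PSF (Gaussian fit to the contiguous region above 5% of
  the linear-magnitude peak, peak search excluding the first 100 µm
  where the residual sample-DC hump lives) comes out at 8.27 µm: the
  796–879 nm detection band truncates the source's Gaussian spectrum,
  and the fitted width of the truncated-spectrum PSF is wider than the
  untruncated closed form.  Fitting only samples above threshold
  matters: including the sub-5% tails biases the width ~15% low.  At
  two depth samples per FWHM (no zero padding) a residual scalloping
  bias of ~7% remains; zero-pad ≥ 2 removes it.
- Sensitivity: `20 log₁₀(peak/σ_floor) + attenuation`, floor from the
  deepest 20% of bins excluding the peak ±10 bins.  Noise-free
  reconstructions return ∞ flagged "noise-free" (their floor is FFT
  leakage, not noise).  dB conventions: 20 log₁₀ for amplitudes,
  10 log₁₀ for the power-like roll-off of squared magnitudes.
- Roll-off: simulated mirror peaks (noise off, rectangular window,
  zero-pad 8 so scalloping is <0.06 dB, peak searched near the known
  OPD) against the analytic model
  `10 log₁₀[sinc²(ζπ/2) · exp(−w²π²ζ²/(8 ln 2))]`,
  ζ = z/z_max, w = δλ_res/δλ_s.  Emergent and analytic agree within
  ~0.2 dB over 0.2–0.8 z_max.  The hardware-measured roll-off of such
  systems is larger than the ideal model (alignment, field-dependent
  blur); those effects are deliberately unmodelled, so measured-system
  figures (85 dB sensitivity, 3.6/8.5 dB roll-off at 1/2 mm, 11 µm
  lateral resolution) are *not* reproduction targets of this package.

## Phantoms: what they emulate, what they do not

All phantoms live on the lateral scan grid (B-scan index × A-scan
position), store per-layer geometric thickness maps, group indices,
interface amplitude reflectances and optional sub-resolution
scatterers (uniform positions, Rayleigh amplitudes, uniform phases),
and expose exact ground truth.  A fixed seed reproduces a phantom and
its simulated volume bit for bit.

**Cornea** (default 100 × 256 over 4 × 4 mm): spherical-cap anterior
surface with the ~8.8 mm radius of a porcine cornea; epithelium
(69.2 µm), stroma (total 743.2 µm), and an aqueous half-space whose
top is the endothelial surface.  Total thickness varies like a real
pachymetry map — apex-thin, thickening quadratically by 25 µm towards
the field corner — plus a smooth random residual (SD 3 µm, correlation
1.5 mm); the epithelium carries only a random component (SD 1.2 µm).
Sample means are normalized to the nominal values exactly, so the
ground-truth volume means are 743.2/69.2 µm by construction and the
recovered SDs (≈7 and ≈1.5 µm) mix true variation with segmentation
noise.  Reflectances: air/epithelium 0.158 (Fresnel), epithelium/
stroma 0.02, endothelium/aqueous 0.04; stroma speckle from 30
scatterers per column of mean amplitude 0.004.

**PCB** (default 60 × 256 over 5 × 4 mm): conformal coating
(n = 1.50, air-side reflectance 0.2) over a substrate whose top is
solder mask (reflectance 0.032) or resistor (0.045).  Two 2 × 1 mm
resistor blocks sit side by side along the scan axis in one lateral
band, as adjacent components do; coating is 27.2 µm on the block tops
and 82.9 µm on the mask.  Block edges carry a 0.25 mm smoothstep
fillet — the sloped meniscus sprayed coating and solder form along
component edges — keeping the interface slope within the tracker's
window (~3.4 padded bins per column); the default block height equals
the coating-thickness difference (the self-leveling limit, coating
outer surface flush).  The board is tilted ~1 mrad with 4 µm waviness:
realistic mounting, and necessary — a perfectly level flat interface
occupies a single depth row, which the row-mean-subtraction artifact
filter would suppress along with the artifacts.  Ground truth labels
each position `resistor` (exactly 27.2 µm), `mask` (exactly 82.9 µm)
or `edge` (fillet band, intermediate), matching what "thickness on the
resistor tops" and "on the solder mask" mean physically.

**Tape**: a periodic stack of identical 60 µm layers (n = 1.5),
11 interfaces for 10 layers; deep interfaces are attenuated by the
emergent roll-off, not rejected.  **Mirror**: one flat unit reflector
at a chosen OPD, the metrology target.

Not emulated: absorption, dispersion, birefringence, lateral beam
profile (Gaussian line-intensity falloff), multiple scattering and
cross-talk between line positions, sample motion, source RIN and
temperature drift (background subtraction, the standard mitigation, is
supported).  Laterally the speckle is uncorrelated column to column,
where a real system correlates it over the lateral spot size.
Passing tests therefore demonstrate correctness of the processing
chain under this idealized but physically grounded noise model — not
performance on tissue with motion, strong multiple scattering, or
components outside the segmentation's documented validity regime.

## Study sizes

The bundled end-to-end analyses run at 100 B-scans × 256 A-scans
(cornea) and 60 × 256 (PCB) with the full 1920-pixel spectral axis —
field of view and optical parameters identical to the full-scale
instrument, lateral sampling reduced (the full instrument records 850
A-scans × 600 B-scans).  At these sizes the cornea pipeline completes
in ~1 minute on one CPU; accuracy is set by per-column segmentation,
so denser lateral sampling changes the means only through smaller
standard errors.

## Known limitations

- Single-offset inner-layer initialization per B-scan (see above).
- Integer-bin surfaces: sub-bin localization is deliberately not done
  (the reference procedure does not do it); thickness means rely on
  lateral averaging to dither the quantization.
- The constant 0.08 nm resolution kernel understates band-edge blur.
- The theoretical shot-noise sensitivity of the real instrument cannot
  be recomputed without its unpublished reference-arm power and
  spectrograph losses; the simulator's sensitivity is consistent with
  its own configured electron counts instead.
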