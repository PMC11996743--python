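# Methods

## Measurement model

The package models a sandwich immunoassay read out by imaging: analyte
(CEA) captured on ~50 µm antibody-coated polystyrene microspheres is
labelled by green-emitting CdSe/ZnS quantum dots; a microfluidic pillar gap
(30 µm default) retains labelled microspheres in a circular filtration zone
while free ~11 nm QDs pass to waste; the zone is photographed by an 8-bit
RGB camera under UV excitation. Signal is the mean CIE luminance Y of the
detected circle.

### Dose–response

Expected emission intensity follows a four-parameter logistic (4PL) in
linear concentration,
`I(c) = baseline + (top − baseline) · c^h / (EC50^h + c^h)`,
the standard saturation-binding form for immunoassays: it reproduces both
the slow growth at low dose and the label-saturation plateau at high dose.
Defaults: baseline 0.04, top 0.55 (luminance units), EC50 20 ng/mL, h = 1.
With h = 1 and EC50 = 20 the curve is near-linear over 0.01–1 ng/mL, the
range used for the linear calibration. The top of 0.55 is a gamut
constraint, not a free choice: the QD green chromaticity lies outside the
sRGB gamut, so unit luminance already requires a linear-light green channel
of ≈ 1.4, and a top much above 0.6 would clip G at 255 and destroy the
dose–response monotonicity in the rendered images.

### Emission spectrum and color rendering

The QD emission line is a Gaussian, peak 530 nm, FWHM 35 nm, supported on
450–640 nm (a typical narrow QD linewidth; only the peak and the measured
window are constrained by the physics being emulated). Rendering integrates
the spectrum against the CIE 1931 2° color-matching functions — implemented
as the published multi-lobe piecewise-Gaussian analytic fit (Wyman, Sloan &
Shirley, JCGT 2013, ~1% of peak accuracy) — converts XYZ to linear sRGB by
the inverse IEC 61966-2-1 matrix, clips the (out-of-gamut) negative
channels at zero, and rescales so the clipped triplet's luminance equals
the requested intensity exactly. Without the post-clip rescale, clipping
would silently inflate luminance by ~18% for this spectrum.

Note one consequence of the finite support: a *flat* spectrum over
450–640 nm has chromaticity (0.356, 0.414), not the equal-energy point
(1/3, 1/3) — truncating below 450 nm removes most of the z̄ (blue) weight.
The test suite pins the integration-oracle value.

### Scene and noise

A frame is additive in linear light: an achromatic background at the
decoded 8-bit `background_level` (default 8) plus the emission inside the
circle (default 128×128 px, radius 30). Camera noise is Poisson shot noise
on linear intensity (`shot_scale` = 2000 electrons per unit intensity),
then sRGB encoding, additive Gaussian read noise (σ = 1 gray level), and
8-bit quantisation. The optional RGGB Bayer stage mosaics the encoded
raster (green at sites (0,1) and (1,0) of each 2×2 unit — 50% green, as in
real CFAs) and restores RGB by bilinear interpolation per channel; a
constant color survives the round trip exactly. LFA strips are achromatic
rasters with a fixed-amplitude control band and a 4PL-driven test band
(dark bands on a light membrane for colorimetric/colloidal-gold strips,
bright on dark for fluorescent ones); they carry Gaussian read noise only —
reflective strips under ambient light are read-noise dominated, and the
shot term models the photon-starved emission path.

Every generator output is a pure function of (config, seed); sub-seeds are
derived with `numpy.random.SeedSequence`.

### Particles and filtration

Particle diameters are lognormal (positive support) parameterised so the
arithmetic mean equals the nominal diameter exactly: σ² = ln(1 + CV²),
µ = ln(mean) − σ²/2. Defaults: QDs 11 nm CV 0.1, microspheres 50 µm
CV 0.02. Retention by the pillar gap is the strict inequality
diameter > gap, so the boundary case "diameter equals gap" counts as
washed out.

## Detection and readout

Circle detection: green channel → Gaussian smoothing (σ = 2 px) → Canny
edges with hysteresis thresholds anchored at the Otsu level → circular
Hough accumulator over the requested radius range. Among the five strongest
(perimeter-normalised) accumulator peaks, the circle with the greatest
integrated green intensity wins — the tie-break that picks the brighter of
two candidate zones. A featureless frame (contrast < 5 gray levels), an
empty edge map, or a best response below 0.25 raises `NoCircleFound`.

Pixel extraction defaults to *all* in-mask pixels; `luminous_fraction`
exposes ranking by green value (ties broken row-major) because a "luminous
points" readout may mean only the bright subset. Mean chromaticity is the
luminance-weighted mean of per-pixel (x, y) — dark pixels should not drag
the hue — with an unweighted option; mean Y, grayscale, and channel means
are plain arithmetic means. Grayscale uses BT.601 weights
(0.299, 0.587, 0.114) on encoded values, matching common imaging software;
the colorimetric path gamma-decodes before the sRGB→XYZ matrix (consumer
CMOS output is sRGB-encoded; the flag is exposed for raw-linear data).

## Assay statistics

* Normalisation divides by the maximum (max → 1.0 exactly).
* Linear calibration: OLS of per-concentration replicate means over the
  linear range; the 4PL fit is bounded nonlinear least squares initialised
  from the data (baseline = min mean, top = max mean, EC50 = concentration
  nearest half-range, h = 1); flat data or solver failure returns a
  flagged, non-raising result.
* LOD: threshold = blank mean + 3·sample SD (n−1 denominator), inverted
  through the *linear* calibration; thresholds below the intercept clamp to
  0 with a flag.
* Cut-off: lowest tested concentration whose mean exceeds the blank
  threshold — the same rule as the LOD, applied to tested doses.
* Discrimination value: intensity at the highest tested dose divided by the
  blank intensity, computed per readout space (CIE Y, grayscale, green
  channel). Because Y lives in linear light while grayscale is computed on
  gamma-encoded values, the Y ratio is systematically larger on dim-blank /
  bright-positive scenes — the quantitative reason the xyY readout
  discriminates better.
* LFA integrated density: column-mean lane profile, background = median of
  out-of-band columns (the control line is excluded so it cannot bias the
  membrane estimate), one-sided clipped sum over the band. Densities are
  invariant to a global offset; a raw (unsubtracted) band sum is emitted
  alongside.

### Analytic noise propagation

`predicted_blank_sd` propagates the noise model through the readout by the
delta method: per-channel linear variance = shot variance (v/shot_scale)
plus (σ_read² + 1/12) mapped through the sRGB decode slope, combined with
the luminance row weights and divided by the number of in-circle pixels.
`predicted_lod` applies the blank + 3·SD rule to the *noise-free*
dose–response with that predicted SD — the same estimator the pipeline
uses, evaluated on ideal data — giving an independent yardstick for the
simulation-recovery tests.

## Problem sizes used in the simulation tests

Monte-Carlo recovery tests run on a 64×64 scene (radius 16 px) with the
default noise model: 50 calibration experiments of 8 concentrations × 3
replicates plus 10 blanks each (ten blanks being the conventional design
for blank-SD estimation — a 3-blank sample SD has a chi-distribution spread
of roughly ±70%), and 50 LFA dilution series of five 4-fold steps with 3
blank strips. Detection recovery uses twenty 128×128 frames with randomised
centers and radii. These sizes make the whole suite run in well under a
minute while leaving every statistical margin comfortably wide.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: a
saturating monotone dose–response, narrow-band green emission rendered
through a standard observer, a bright disk on a dark background with
realistic camera noise, CFA sampling, and dose-dependent strip bands. It
deliberately omits optical point-spread, vignetting, lens distortion,
illumination gradients, antibody-kinetics variability beyond the 4PL
(so replicate scatter is camera noise only — real inter-chip CVs are
larger, and real LODs correspondingly higher), microfluidic flow, and strip
housing artifacts. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not field performance on physical chips;
laboratory figures such as a 0.021 ng/mL detection limit depend on
instrument replicates the model does not claim to reproduce.

## Numerical conventions

Coordinates are (row, col), origin top-left, 0-based; intervals are
half-open; circle masks are inclusive (≤ r²). 8-bit quantisation rounds
half away from zero via floor(x + 0.5). Degenerate inputs are handled by
stated conventions: XYZ = 0 maps to the white point with Y = 0; blank-only
series report "not-detected"; flat dose–response data flag
non-convergence rather than raising.
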