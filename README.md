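# qdvision

Machine-vision readout for quantum-dot (QD) luminescence microfluidic
immunoassays, with lateral-flow-assay (LFA) densitometry for comparison.

## The problem

Point-of-care sandwich immunoassays for the tumor marker CEA
(carcinoembryonic antigen) can be read out optically: antibody-coated
polystyrene microspheres (~50 µm) capture the analyte, green-emitting
CdSe/ZnS quantum dots (~11 nm, emission peak ≈ 530 nm) label it, and a
microfluidic chip with a 30 µm pillar gap retains the labelled microspheres
in a circular filtration zone while free QDs wash out. A consumer CMOS
camera photographs the zone under 365 nm UV excitation; the brightness of
the green circle encodes the analyte concentration.

`qdvision` implements the full quantification chain for such images, plus a
synthetic image generator so every stage is testable without the physical
device:

1. **synth** — renders biochip frames (4PL dose–response → Gaussian emission
   spectrum → CIE 1931 observer → linear sRGB → shot/read noise → 8-bit,
   optional RGGB Bayer mosaic + bilinear demosaic) and two-line LFA strips,
   with ground truth attached.
2. **imaging** — luminescent-circle recognition (Gaussian smoothing, Canny
   edges, circular Hough transform) and extraction of in-circle pixels.
3. **colorimetry** — RGB → grayscale / CIE XYZ / CIE xyY; the luminance Y is
   the assay signal, the chromaticity (x, y) the emission hue.
4. **quantify** — max-normalisation, linear and four-parameter-logistic
   calibration, limit of detection (blank mean + 3·SD), cut-off
   concentration, discrimination values, specificity ranking.
5. **lfa** — strip grayscale conversion, lane profiles, background-subtracted
   integrated density of the test line, and the LFA cut-off.

## Core model

Expected signal at concentration $c$ follows the four-parameter logistic

$$I(c) = I_\mathrm{min} + (I_\mathrm{max} - I_\mathrm{min})\,
\frac{c^{h}}{\mathrm{EC}_{50}^{h} + c^{h}},$$

measured as the mean CIE luminance $\bar Y$ of the detected circle, where
$(x, y, Y)$ come from sRGB via the IEC 61966-2-1 matrix (D65, 2° observer)
after gamma decoding. The limit of detection applies the blank + 3·SD rule
to an ordinary-least-squares calibration over the assay's linear range
(0.01–1 ng/mL); the cut-off is the lowest tested concentration whose mean
signal clears the same threshold.

## Worked example

Simulate a default assay (8 concentrations × 3 replicates + 3 blanks,
128×128 frames) and analyze it:

```bash
qdvision simulate --out sim --seed 0
qdvision analyze --manifest sim/manifest.csv --out results \
    --min-radius 15 --max-radius 45
```

`results/summary.json` (abridged):

```json
{
  "n_images": 27,
  "linear_calibration": {"slope": 0.02426, "intercept": 0.04255, "r_squared": 0.9999},
  "lod": {"lod_ng_per_ml": 0.01043, "blank_sd": 0.000109},
  "dose_response": {"ec50": 19.88, "hill": 1.002, "converged": true},
  "cutoff_ng_per_ml": 0.05,
  "discrimination": {"cie_Y": 9.57, "grayscale": 2.76, "rgb_G": 2.91}
}
```

Reading this: all 27 circles were detected; the calibration over
0.01–1 ng/mL is linear (r² ≈ 1) with an estimated detection limit of
≈ 0.010 ng/mL; the 4PL fit recovers the generator's EC50 of 20 ng/mL to
0.6%; the lowest concentration distinguishable from blanks is 0.05 ng/mL;
and the CIE-Y readout separates blank from saturated samples about 3.5×
better than encoded-domain grayscale — the motivation for reading the assay
in xyY rather than grayscale or raw RGB.

`qdvision simulate --kind lfa` and `qdvision lfa` run the analogous strip
simulation and densitometry; `qdvision calibrate` refits statistics from a
previously written records CSV.

## Layout

```
src/qdvision/   synth, imaging, colorimetry, quantify, lfa, workflow, cli, io
tests/          unit + property tests and system-level acceptance tests
docs/methods.md model assumptions, parameter choices, limitations
```
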