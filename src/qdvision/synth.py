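"""Synthetic biochip and LFA-strip image generator.

Emulates the measurement chain of a quantum-dot (QD) luminescence sandwich
immunoassay read out by a consumer CMOS camera:

* a saturating four-parameter-logistic (4PL) dose–response of emission
  intensity versus analyte (CEA) concentration, with blank controls;
* narrow-band green emission (Gaussian spectrum peaking near 530 nm) rendered
  through the CIE 1931 observer into linear sRGB;
* a circular luminous filtration zone on a dark chip background, with Poisson
  shot noise, Gaussian read noise, 8-bit quantisation, and an optional RGGB
  Bayer mosaic + bilinear demosaic;
* two-line lateral-flow strips, colorimetric (dark bands on a light strip) or
  fluorescent (bright bands on a dark strip);
* particle populations (≈11 nm QDs, ≈50 µm polystyrene microspheres) and the
  size-based pillar-gap filtration predicate that separates them.

Every output is a pure function of its configuration and seed, so the
generator doubles as the ground-truth oracle for the detection and
quantification stages.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage

from ._cmf import spectral_to_xyz
from .colorimetry import SRGB_TO_XYZ, srgb_decode, srgb_encode

__all__ = [
    "EmissionSpectrumModel",
    "BindingModel",
    "ParticlePopulation",
    "SceneGeometry",
    "NoiseModel",
    "AssayConfig",
    "LFAStripConfig",
    "simulate_binding",
    "sample_particles",
    "filtration_predicate",
    "spectrum_to_rgb",
    "render_biochip_image",
    "bayer_mosaic",
    "demosaic_bilinear",
    "render_lfa_strip",
    "predicted_blank_sd",
    "predicted_lod",
]

_Y_ROW = SRGB_TO_XYZ[1]  # luminance weights of linear sRGB


class EmissionSpectrumModel(BaseModel):
    """Gaussian emission line of the CdSe/ZnS QD label.

    Defaults follow the measured photoluminescence: peak near 530 nm (bright
    green under 365 nm UV excitation) within a 450–640 nm window; the FWHM of
    35 nm is a typical narrow QD linewidth.
    """

    model_config = ConfigDict(frozen=True)

    peak_wavelength: float = 530.0
    fwhm: float = 35.0
    amplitude: float = 1.0
    support: tuple[float, float] = (450.0, 640.0)

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.support
        if not lo < hi:
            raise ValueError("support must be an increasing interval")
        if not (lo <= self.peak_wavelength <= hi):
            raise ValueError("peak_wavelength must lie inside the support")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        return self

    def radiance(self, wavelengths_nm) -> np.ndarray:
        """Relative spectral radiance; zero outside the support."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        val = self.amplitude * np.exp(-0.5 * ((lam - self.peak_wavelength) / sigma) ** 2)
        lo, hi = self.support
        return np.where((lam >= lo) & (lam <= hi), val, 0.0)

    def grid(self, step_nm: float = 1.0) -> np.ndarray:
        lo, hi = self.support
        return np.arange(lo, hi + 0.5 * step_nm, step_nm)


class BindingModel(BaseModel):
    """Four-parameter logistic (Hill) dose–response on linear concentration.

    ``baseline`` is the blank signal (non-specific adsorption plus chip
    autofluorescence), ``top`` the saturated signal, ``ec50`` the
    half-saturation concentration in ng/mL, ``hill`` the slope. hill = 1 with
    ec50 = 20 ng/mL gives decelerating growth toward the top of the
    0.01–50 ng/mL assay range while staying near-linear over 0.01–1 ng/mL,
    the calibration's linear range. Intensity is in luminance units; the
    default top of 0.55 keeps the rendered green channel inside the 8-bit
    range at saturation (the QD green chromaticity sits outside the sRGB
    gamut, so unit luminance already needs G ≈ 1.4 in linear light).
    """

    model_config = ConfigDict(frozen=True)

    baseline: float = 0.04
    top: float = 0.55
    ec50: float = 20.0
    hill: float = 1.0

    @model_validator(mode="after")
    def _check(self):
        if not (self.top > self.baseline >= 0):
            raise ValueError("require top > baseline >= 0")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be > 0")
        return self


class ParticlePopulation(BaseModel):
    """Lognormal particle-size population (nm for QDs, µm for PS spheres)."""

    model_config = ConfigDict(frozen=True)

    species: str = "QD"
    mean_diameter: float = 11.0
    cv: float = 0.1
    count: int = 10_000
    unit: str = "nm"

    @model_validator(mode="after")
    def _check(self):
        if self.species not in ("QD", "PS_microsphere"):
            raise ValueError("species must be 'QD' or 'PS_microsphere'")
        if self.mean_diameter <= 0:
            raise ValueError("mean_diameter must be > 0")
        if self.cv < 0 or self.count < 0:
            raise ValueError("cv and count must be >= 0")
        if self.unit not in ("nm", "um"):
            raise ValueError("unit must be 'nm' or 'um'")
        return self

    @classmethod
    def qd_default(cls, count: int = 10_000) -> "ParticlePopulation":
        return cls(species="QD", mean_diameter=11.0, cv=0.1, count=count, unit="nm")

    @classmethod
    def ps_default(cls, count: int = 10_000) -> "ParticlePopulation":
        return cls(species="PS_microsphere", mean_diameter=50.0, cv=0.02, count=count, unit="um")

    @property
    def mean_diameter_um(self) -> float:
        return self.mean_diameter * (1e-3 if self.unit == "nm" else 1.0)


class SceneGeometry(BaseModel):
    """Placement of the luminous filtration-zone disk in the frame."""

    model_config = ConfigDict(frozen=True)

    image_shape: tuple[int, int] = (128, 128)
    circle_center: tuple[float, float] = (64.0, 64.0)
    circle_radius: float = 30.0
    background_level: int = 8

    @model_validator(mode="after")
    def _check(self):
        rows, cols = self.image_shape
        r0, c0 = self.circle_center
        r = self.circle_radius
        if rows < 1 or cols < 1:
            raise ValueError("image_shape must be positive")
        if r < 3:
            raise ValueError("circle_radius must be >= 3 px")
        if not (r <= r0 <= rows - 1 - r and r <= c0 <= cols - 1 - r):
            raise ValueError("circle must lie fully inside the image")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must be an 8-bit intensity")
        return self


class NoiseModel(BaseModel):
    """Camera noise: Poisson shot noise on linear intensity + Gaussian read noise.

    ``shot_scale`` is the electron count corresponding to unit linear
    intensity (sets the shot SNR); ``read_sigma`` is the read-noise standard
    deviation in 8-bit gray levels, applied after sRGB encoding.
    """

    model_config = ConfigDict(frozen=True)

    shot_scale: float = 2000.0
    read_sigma: float = 1.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.shot_scale <= 0:
            raise ValueError("shot_scale must be > 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")
        return self


class AssayConfig(BaseModel):
    """Full generative description of a synthetic biochip experiment."""

    model_config = ConfigDict(frozen=True)

    binding: BindingModel = BindingModel()
    spectrum: EmissionSpectrumModel = EmissionSpectrumModel()
    geometry: SceneGeometry = SceneGeometry()
    noise: NoiseModel = NoiseModel()
    concentrations: tuple[float, ...] = (0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 50.0)
    replicates: int = 3
    apply_bayer: bool = False
    pillar_gap: float = 30.0  # µm

    @model_validator(mode="after")
    def _check(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if self.pillar_gap <= 0:
            raise ValueError("pillar_gap must be > 0")
        return self


class LFAStripConfig(BaseModel):
    """Two-line lateral-flow strip: control band fixed, test band dose-dependent.

    Colorimetric strips (colloidal-gold label) show dark bands on a light
    membrane; fluorescent strips show bright bands on a dark background.
    Amplitudes are in 8-bit gray levels.
    """

    model_config = ConfigDict(frozen=True)

    mode: str = "colorimetric"
    strip_shape: tuple[int, int] = (40, 160)
    test_line_col_window: tuple[int, int] = (90, 102)
    control_line_col_window: tuple[int, int] = (120, 132)
    background_gray: int = 200
    control_amplitude: float = 60.0
    line_amplitude_model: BindingModel = BindingModel(baseline=0.0, top=40.0, ec50=300.0, hill=1.0)
    noise: NoiseModel = NoiseModel(read_sigma=1.0)

    @model_validator(mode="after")
    def _check(self):
        if self.mode not in ("colorimetric", "fluorescent"):
            raise ValueError("mode must be 'colorimetric' or 'fluorescent'")
        rows, cols = self.strip_shape
        for lo, hi in (self.test_line_col_window, self.control_line_col_window):
            if not (0 <= lo < hi <= cols):
                raise ValueError("line windows must be non-empty and inside the strip")
        t, c = self.test_line_col_window, self.control_line_col_window
        if max(t[0], c[0]) < min(t[1], c[1]):
            raise ValueError("test and control windows must be disjoint")
        if not (0 <= self.background_gray <= 255):
            raise ValueError("background_gray must be an 8-bit intensity")
        return self

    @classmethod
    def colorimetric_default(cls) -> "LFAStripConfig":
        return cls()

    @classmethod
    def fluorescent_default(cls) -> "LFAStripConfig":
        return cls(
            mode="fluorescent",
            background_gray=25,
            control_amplitude=80.0,
            line_amplitude_model=BindingModel(baseline=0.0, top=60.0, ec50=15.0, hill=1.0),
        )


# ---------------------------------------------------------------------------
# operations


def simulate_binding(c: float, model: BindingModel) -> float:
    """Expected (noise-free) signal at concentration ``c`` under the 4PL.

    I(c) = baseline + (top − baseline) · c^h / (ec50^h + c^h); monotone
    non-decreasing in c, I(0) = baseline.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c == 0:
        return model.baseline
    ch = c**model.hill
    return model.baseline + (model.top - model.baseline) * ch / (model.ec50**model.hill + ch)


def sample_particles(pop: ParticlePopulation, seed: int) -> np.ndarray:
    """Draw ``pop.count`` diameters from a lognormal with the stated mean and CV.

    The lognormal is parameterised so that its arithmetic mean equals
    ``mean_diameter`` exactly: σ² = ln(1 + cv²), µ = ln(mean) − σ²/2.
    cv = 0 degenerates to a point mass at the mean.
    """
    if pop.count == 0:
        return np.empty(0)
    if pop.cv == 0:
        return np.full(pop.count, float(pop.mean_diameter))
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(pop.cv**2)
    mu = np.log(pop.mean_diameter) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=pop.count)


def filtration_predicate(diameter: float, gap: float) -> bool:
    """True iff a particle of ``diameter`` is retained by a pillar gap of ``gap``.

    Both lengths in the same unit. Retention requires the diameter to strictly
    exceed the gap: 50 µm microspheres are held back by the 30 µm gap while
    11 nm QDs wash through to the outlet.
    """
    if diameter <= 0 or gap <= 0:
        raise ValueError("diameter and gap must be > 0")
    return diameter > gap


def spectrum_to_rgb(spec: EmissionSpectrumModel, intensity: float) -> np.ndarray:
    """Render a spectrum at the given intensity into non-negative linear sRGB.

    The spectrum is integrated against the CIE 1931 2° observer on a 1 nm
    grid, converted through the inverse sRGB matrix, gamut-clipped at zero
    (the saturated green QD line lies outside the sRGB gamut), and normalised
    so that the clipped triplet's luminance equals ``intensity × amplitude``
    exactly. The triplet scales linearly with ``intensity``.
    """
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    lam = spec.grid(1.0)
    xyz = spectral_to_xyz(lam, spec.radiance(lam))
    if xyz[1] <= 0 or intensity == 0:
        return np.zeros(3)
    rgb = np.clip(np.linalg.inv(SRGB_TO_XYZ) @ xyz, 0.0, None)
    lum = float(_Y_ROW @ rgb)
    if lum <= 0:
        return np.zeros(3)
    return rgb / lum * intensity * spec.amplitude


def unit_luminance_rgb(spec: EmissionSpectrumModel) -> np.ndarray:
    """Gamut-clipped linear RGB of the spectrum at unit luminance (helper)."""
    return spectrum_to_rgb(spec, 1.0) / max(spec.amplitude, 1e-300)


def _circle_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _quantize(encoded01: np.ndarray, read_sigma: float, rng: np.random.Generator | None) -> np.ndarray:
    out = encoded01 * 255.0
    if rng is not None and read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, size=out.shape)
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def render_biochip_image(
    cfg: AssayConfig,
    c: float,
    replicate_seed: int,
    noise: bool = True,
):
    """Render one biochip frame at concentration ``c``.

    Returns ``(pixels, truth)`` where ``pixels`` is an (H, W, 3) uint8 array
    and ``truth`` a dict with the ground-truth circle (center, radius, mask)
    and the expected in-circle linear luminance, for detector testing.

    The scene is additive in linear light: an achromatic background at the
    decoded ``background_level`` plus the QD emission (4PL intensity rendered
    through the spectrum) inside the circle. With ``noise`` on, Poisson shot
    noise acts on linear intensity and Gaussian read noise on the encoded
    8-bit values; ``apply_bayer`` inserts an RGGB mosaic + bilinear demosaic
    before quantisation. Deterministic given (cfg, c, replicate_seed).
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    geom = cfg.geometry
    shape = geom.image_shape
    bg_lin = srgb_decode(geom.background_level / 255.0)
    intensity = simulate_binding(c, cfg.binding)
    emission = spectrum_to_rgb(cfg.spectrum, intensity)

    linear = np.full(shape + (3,), bg_lin, dtype=float)
    mask = _circle_mask(shape, geom.circle_center, geom.circle_radius)
    linear[mask] += emission

    rng = None
    if noise:
        rng = np.random.default_rng([int(cfg.noise.seed), int(replicate_seed)])
        electrons = rng.poisson(np.clip(linear, 0.0, None) * cfg.noise.shot_scale)
        linear = electrons / cfg.noise.shot_scale

    encoded = srgb_encode(linear)
    if cfg.apply_bayer:
        # mosaic in the encoded domain (the CFA sits in front of the ADC),
        # requires even dimensions
        cfa, _ = bayer_mosaic(np.clip(encoded * 255.0, 0, 255))
        encoded = demosaic_bilinear(cfa) / 255.0

    pixels = _quantize(encoded, cfg.noise.read_sigma if noise else 0.0, rng)
    truth = {
        "center": geom.circle_center,
        "radius": geom.circle_radius,
        "mask": mask,
        "intensity": intensity,
        "emission_rgb_linear": emission,
        "expected_Y": float(bg_lin * _Y_ROW.sum() + _Y_ROW @ emission),
    }
    return pixels, truth


def bayer_mosaic(img: np.ndarray):
    """Sample an RGB raster through an RGGB color-filter array.

    Returns ``(cfa, pattern)``: a single-channel raster where each site keeps
    only its filter's channel, and the pattern descriptor. In each 2×2 unit
    red sits at (0,0), green at (0,1) and (1,0), blue at (1,1) — green sites
    are half of all sites, matching the eye's greater green sensitivity.
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    h, w = arr.shape[:2]
    if h % 2 or w % 2:
        raise ValueError("Bayer mosaic requires even image dimensions")
    cfa = np.zeros((h, w), dtype=arr.dtype)
    cfa[0::2, 0::2] = arr[0::2, 0::2, 0]  # R
    cfa[0::2, 1::2] = arr[0::2, 1::2, 1]  # G
    cfa[1::2, 0::2] = arr[1::2, 0::2, 1]  # G
    cfa[1::2, 1::2] = arr[1::2, 1::2, 2]  # B
    return cfa, "RGGB"


_BILINEAR_KERNEL = np.array([[0.25, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 0.25]])


def demosaic_bilinear(cfa: np.ndarray, pattern: str = "RGGB") -> np.ndarray:
    """Bilinear demosaic of an RGGB CFA raster back to (H, W, 3).

    Each channel is interpolated from its own sites by normalised
    neighbourhood averaging; a constant-color mosaic is recovered exactly.
    """
    if pattern != "RGGB":
        raise ValueError("only the RGGB pattern is supported")
    arr = np.asarray(cfa, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a single-channel CFA raster")
    h, w = arr.shape
    masks = np.zeros((h, w, 3), dtype=bool)
    masks[0::2, 0::2, 0] = True
    masks[0::2, 1::2, 1] = True
    masks[1::2, 0::2, 1] = True
    masks[1::2, 1::2, 2] = True
    out = np.empty((h, w, 3), dtype=float)
    for ch in range(3):
        vals = np.where(masks[..., ch], arr, 0.0)
        num = ndimage.convolve(vals, _BILINEAR_KERNEL, mode="mirror")
        den = ndimage.convolve(masks[..., ch].astype(float), _BILINEAR_KERNEL, mode="mirror")
        out[..., ch] = num / den
    return out


def render_lfa_strip(cfg: LFAStripConfig, c: float, seed: int, noise: bool = True):
    """Render one LFA strip at concentration ``c``.

    The strip is an achromatic raster at ``background_gray`` with a control
    band of fixed amplitude and a test band whose amplitude follows the 4PL
    ``line_amplitude_model``. Colorimetric mode subtracts band amplitude from
    the background, fluorescent mode adds. Gaussian read noise (σ =
    ``noise.read_sigma`` gray levels) is applied when ``noise`` is on;
    reflective strips under ambient light are read-noise dominated, so no
    shot term is used here.

    Returns ``(pixels, truth)``; ``truth`` records band windows, amplitudes,
    and a ``clipped`` flag when a band pushes pixels outside [0, 255].
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    rows, cols = cfg.strip_shape
    test_amp = simulate_binding(c, cfg.line_amplitude_model)
    sign = -1.0 if cfg.mode == "colorimetric" else 1.0

    gray = np.full((rows, cols), float(cfg.background_gray))
    t_lo, t_hi = cfg.test_line_col_window
    c_lo, c_hi = cfg.control_line_col_window
    gray[:, t_lo:t_hi] += sign * test_amp
    gray[:, c_lo:c_hi] += sign * cfg.control_amplitude

    clipped = bool(gray.min() < 0 or gray.max() > 255)
    if noise and cfg.noise.read_sigma > 0:
        rng = np.random.default_rng([int(cfg.noise.seed), int(seed)])
        gray = gray + rng.normal(0.0, cfg.noise.read_sigma, size=gray.shape)
    gray8 = np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)
    pixels = np.repeat(gray8[:, :, None], 3, axis=2)
    truth = {
        "test_window": cfg.test_line_col_window,
        "control_window": cfg.control_line_col_window,
        "test_amplitude": float(test_amp),
        "control_amplitude": float(cfg.control_amplitude),
        "mode": cfg.mode,
        "clipped": clipped,
    }
    return pixels, truth


# ---------------------------------------------------------------------------
# delta-method noise propagation (the generator's own prediction of what the
# readout should measure, used as an independent check on the pipeline)


def _decode_derivative(encoded01: np.ndarray) -> np.ndarray:
    u = np.asarray(encoded01, dtype=float)
    return np.where(u <= 0.04045, 1.0 / 12.92, (2.4 / 1.055) * ((u + 0.055) / 1.055) ** 1.4)


def predicted_blank_sd(cfg: AssayConfig) -> float:
    """Predicted SD of the circle-mean CIE Y of a blank frame.

    Delta-method propagation of shot noise (var v/shot_scale on linear
    channel value v), read noise and quantisation (var σ_r² + 1/12 on the
    encoded 8-bit value, mapped to linear through the decode slope) into the
    luminance of a single pixel, divided by √N over the in-circle pixels.
    """
    geom = cfg.geometry
    bg_lin = float(srgb_decode(geom.background_level / 255.0))
    emission = spectrum_to_rgb(cfg.spectrum, cfg.binding.baseline)
    v = bg_lin + emission  # per-channel linear value inside the circle
    enc = srgb_encode(v)
    slope = _decode_derivative(enc) / 255.0  # d(linear)/d(8-bit counts)
    var_lin = v / cfg.noise.shot_scale + (cfg.noise.read_sigma**2 + 1.0 / 12.0) * slope**2
    var_pix_Y = float(_Y_ROW**2 @ var_lin)
    n_pix = int(_circle_mask(geom.image_shape, geom.circle_center, geom.circle_radius).sum())
    return float(np.sqrt(var_pix_Y / n_pix))


def predicted_lod(cfg: AssayConfig, conc_range: tuple[float, float] = (0.01, 1.0)) -> float:
    """Analytic LOD implied by the generator's noise model.

    Applies the blank + 3·SD rule to the *noise-free* dose–response: the OLS
    calibration is fitted to the ideal mean-Y curve over the configured
    concentrations inside ``conc_range`` (the assay's linear range), the
    blank SD is the delta-method prediction of :func:`predicted_blank_sd`,
    and the threshold is inverted through that ideal calibration — exactly
    the estimator the pipeline applies, evaluated on noiseless expectations.
    """
    geom = cfg.geometry
    bg_Y = float(srgb_decode(geom.background_level / 255.0) * _Y_ROW.sum())
    cs = np.array([c for c in cfg.concentrations if conc_range[0] <= c <= conc_range[1]])
    if len(cs) < 2:
        raise ValueError("need >= 2 configured concentrations inside conc_range")

    def mean_Y(c):
        return bg_Y + float(_Y_ROW @ spectrum_to_rgb(cfg.spectrum, simulate_binding(c, cfg.binding)))

    slope, intercept = np.polyfit(cs, [mean_Y(c) for c in cs], 1)
    threshold = mean_Y(0.0) + 3.0 * predicted_blank_sd(cfg)
    return max(float((threshold - intercept) / slope), 0.0)
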