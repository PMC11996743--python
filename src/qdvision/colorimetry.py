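"""RGB → grayscale / CIE XYZ / CIE xyY conversions.

The assay readout compares three color spaces on the same extracted pixels:
an encoded-domain grayscale, the raw RGB channels, and CIE xyY, where the
luminance Y carries the signal and the chromaticity (x, y) carries the
emission hue. The default transform is the IEC 61966-2-1 sRGB → XYZ matrix
(D65 white, 2° observer) with the standard electro-optical decoding applied
before the matrix, which is what a consumer CMOS camera's output calls for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColorTransform",
    "CIEXYZ",
    "CIExyY",
    "GrayWeights",
    "SRGB_TO_XYZ",
    "D65_WHITE_XY",
    "srgb_decode",
    "srgb_encode",
    "rgb8_to_xyz",
    "xyz_to_xyY",
    "xyY_to_xyz",
    "grayscale",
    "mean_color_stats",
]

# IEC 61966-2-1 sRGB primaries, D65 white, 2° observer.
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
D65_WHITE_XY = (0.3127, 0.3290)

_GRAY_WEIGHT_PRESETS = {
    "bt601": (0.299, 0.587, 0.114),
    "bt709": (0.2126, 0.7152, 0.0722),
    "equal": (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
}


def srgb_decode(u):
    """sRGB electro-optical decoding, encoded [0,1] → linear [0,1]."""
    u = np.asarray(u, dtype=float)
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def srgb_encode(v):
    """Inverse of :func:`srgb_decode`; linear values are clipped to [0,1] first."""
    v = np.clip(np.asarray(v, dtype=float), 0.0, 1.0)
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1 / 2.4) - 0.055)


@dataclass(frozen=True)
class ColorTransform:
    """Linear RGB → XYZ matrix plus the decoding convention.

    ``rgb_to_xyz_matrix @ (1, 1, 1)`` is the white point's XYZ with Y = 1.
    """

    rgb_to_xyz_matrix: np.ndarray = field(default_factory=lambda: SRGB_TO_XYZ.copy())
    white_point: tuple[float, float] = D65_WHITE_XY
    gamma_decode: bool = True

    def __post_init__(self):
        m = np.asarray(self.rgb_to_xyz_matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("rgb_to_xyz_matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("rgb_to_xyz_matrix must be invertible")
        object.__setattr__(self, "rgb_to_xyz_matrix", m)

    @classmethod
    def from_name(cls, name: str, gamma_decode: bool = True) -> "ColorTransform":
        if name.lower() in ("srgb-d65", "srgb"):
            return cls(gamma_decode=gamma_decode)
        raise KeyError(f"unknown color transform {name!r}")

    @property
    def xyz_to_rgb_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.rgb_to_xyz_matrix)


@dataclass(frozen=True)
class CIEXYZ:
    X: float
    Y: float
    Z: float

    def __post_init__(self):
        if self.X < 0 or self.Y < 0 or self.Z < 0:
            raise ValueError("tristimulus values must be non-negative")


@dataclass(frozen=True)
class CIExyY:
    x: float
    y: float
    Y: float

    def __post_init__(self):
        if self.x < 0 or self.y < 0 or self.x + self.y > 1 + 1e-12:
            raise ValueError("chromaticity must satisfy x, y >= 0 and x + y <= 1")
        if self.Y < 0:
            raise ValueError("luminance must be non-negative")


@dataclass(frozen=True)
class GrayWeights:
    wr: float = 0.299
    wg: float = 0.587
    wb: float = 0.114

    def __post_init__(self):
        w = (self.wr, self.wg, self.wb)
        if any(x < 0 for x in w):
            raise ValueError("gray weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("gray weights must sum to 1")

    @classmethod
    def from_name(cls, name: str) -> "GrayWeights":
        try:
            return cls(*_GRAY_WEIGHT_PRESETS[name.lower()])
        except KeyError:
            raise KeyError(f"unknown gray-weight preset {name!r}") from None

    def as_array(self) -> np.ndarray:
        return np.array([self.wr, self.wg, self.wb])


def _decode_rgb8(rgb, transform: ColorTransform) -> np.ndarray:
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB triplets")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("8-bit RGB values must lie in [0, 255]")
    lin = arr / 255.0
    if transform.gamma_decode:
        lin = srgb_decode(lin)
    return lin


def rgb8_to_xyz(rgb, transform: ColorTransform | None = None) -> CIEXYZ:
    """Convert one 8-bit RGB triplet to CIE XYZ (white has Y = 1)."""
    t = transform or ColorTransform()
    lin = _decode_rgb8(rgb, t)
    X, Y, Z = t.rgb_to_xyz_matrix @ lin
    return CIEXYZ(max(X, 0.0), max(Y, 0.0), max(Z, 0.0))


def rgb8_array_to_xyz(rgb, transform: ColorTransform | None = None) -> np.ndarray:
    """Vectorised form of :func:`rgb8_to_xyz`: (..., 3) uint8 → (..., 3) XYZ."""
    t = transform or ColorTransform()
    lin = _decode_rgb8(rgb, t)
    return np.clip(lin @ t.rgb_to_xyz_matrix.T, 0.0, None)


def xyz_to_xyY(v: CIEXYZ, white: tuple[float, float] = D65_WHITE_XY) -> CIExyY:
    """Project XYZ to chromaticity + luminance.

    The black point (X = Y = Z = 0) has no chromaticity; by convention it is
    assigned the transform's white point with Y = 0.
    """
    s = v.X + v.Y + v.Z
    if s == 0:
        return CIExyY(white[0], white[1], 0.0)
    return CIExyY(v.X / s, v.Y / s, v.Y)


def xyY_to_xyz(c: CIExyY) -> CIEXYZ:
    """Inverse of :func:`xyz_to_xyY`; y = 0 with Y > 0 is undefined."""
    if c.Y == 0:
        return CIEXYZ(0.0, 0.0, 0.0)
    if c.y == 0:
        raise ValueError("xyY with y = 0 and Y > 0 has no finite XYZ")
    X = c.x / c.y * c.Y
    Z = (1.0 - c.x - c.y) / c.y * c.Y
    return CIEXYZ(X, c.Y, max(Z, 0.0))


def grayscale(rgb, weights: GrayWeights | None = None) -> int:
    """Weighted gray of one encoded 8-bit triplet, rounded and clamped to [0, 255]."""
    w = weights or GrayWeights()
    arr = np.asarray(rgb, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected a single RGB triplet")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("8-bit RGB values must lie in [0, 255]")
    g = w.wr * arr[0] + w.wg * arr[1] + w.wb * arr[2]
    return int(np.clip(np.floor(g + 0.5), 0, 255))


def grayscale_array(rgb, weights: GrayWeights | None = None) -> np.ndarray:
    """Vectorised grayscale: (..., 3) → (...), uint8, same rounding as :func:`grayscale`."""
    w = weights or GrayWeights()
    arr = np.asarray(rgb, dtype=float)
    g = arr @ w.as_array()
    return np.clip(np.floor(g + 0.5), 0, 255).astype(np.uint8)


def mean_color_stats(
    sample,
    transform: ColorTransform | None = None,
    weights: GrayWeights | None = None,
    chroma_weighting: str = "luminance",
) -> dict:
    """Per-pixel conversion of a PixelSample followed by averaging.

    ``mean_Y``, ``mean_gray`` and the channel means are plain arithmetic means.
    Mean chromaticity is the luminance-weighted mean of the per-pixel (x, y)
    by default — pixels that carry no light should not pull the hue — with
    ``chroma_weighting="uniform"`` giving the unweighted mean instead. A
    sample with zero total luminance falls back to the unweighted mean.
    """
    t = transform or ColorTransform()
    w = weights or GrayWeights()
    rgb = np.asarray(getattr(sample, "rgb_values", sample), dtype=float)
    if rgb.ndim != 2 or rgb.shape[1] != 3 or rgb.shape[0] == 0:
        raise ValueError("sample must contain at least one RGB triplet")
    if chroma_weighting not in ("luminance", "uniform"):
        raise ValueError("chroma_weighting must be 'luminance' or 'uniform'")

    xyz = rgb8_array_to_xyz(rgb, t)
    s = xyz.sum(axis=1)
    wx, wy = t.white_point
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(s > 0, xyz[:, 0] / np.where(s > 0, s, 1.0), wx)
        y = np.where(s > 0, xyz[:, 1] / np.where(s > 0, s, 1.0), wy)
    Y = xyz[:, 1]

    if chroma_weighting == "luminance" and Y.sum() > 0:
        cw = Y / Y.sum()
    else:
        cw = np.full(len(Y), 1.0 / len(Y))

    gray = grayscale_array(rgb, w).astype(float)
    return {
        "mean_x": float(x @ cw),
        "mean_y": float(y @ cw),
        "mean_Y": float(Y.mean()),
        "mean_gray": float(gray.mean()),
        "mean_R": float(rgb[:, 0].mean()),
        "mean_G": float(rgb[:, 1].mean()),
        "mean_B": float(rgb[:, 2].mean()),
    }
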