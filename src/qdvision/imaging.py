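"""Luminescent-circle recognition and pixel extraction.

First two stages of the readout workflow: find the bright circular
filtration zone in a biochip frame, then pull out the RGB values of its
luminescent pixels for colorimetric analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny
from skimage.filters import gaussian, threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks

from .colorimetry import ColorTransform, mean_color_stats

__all__ = [
    "RGBImage",
    "CircleRegion",
    "PixelSample",
    "NoCircleFound",
    "detect_circle",
    "extract_luminous_pixels",
    "classify_sample",
]


class NoCircleFound(RuntimeError):
    """No circular candidate exceeded the accumulator response threshold."""


@dataclass
class RGBImage:
    """8-bit three-channel raster, the unit of all image analysis."""

    pixels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class CircleRegion:
    """Detected luminous circle: center (row, col), radius, aligned mask, score."""

    center: tuple[float, float]
    radius: float
    mask: np.ndarray
    score: float = 0.0

    @classmethod
    def from_geometry(
        cls, image_shape: tuple[int, int], center: tuple[float, float], radius: float, score: float = 0.0
    ) -> "CircleRegion":
        if radius <= 0:
            raise ValueError("radius must be > 0")
        rr, cc = np.ogrid[: image_shape[0], : image_shape[1]]
        mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
        return cls(center=tuple(center), radius=float(radius), mask=mask, score=float(score))


@dataclass
class PixelSample:
    """RGB triplets extracted from a circle region, row-major within rank order."""

    rgb_values: np.ndarray
    origin: CircleRegion | None = None

    def __post_init__(self):
        arr = np.asarray(self.rgb_values)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
            raise ValueError("rgb_values must be a non-empty (N, 3) array")
        self.rgb_values = arr

    @property
    def count(self) -> int:
        return self.rgb_values.shape[0]


def _integrated_green(green: np.ndarray, center: tuple[float, float], radius: float) -> float:
    rr, cc = np.ogrid[: green.shape[0], : green.shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return float(green[mask].sum())


def detect_circle(
    img: RGBImage,
    min_radius: int,
    max_radius: int,
    response_threshold: float = 0.25,
) -> CircleRegion:
    """Locate the luminescent circle by a gradient-based circular Hough transform.

    The green channel is Gaussian-smoothed (σ = 2 px); Canny edges with
    hysteresis thresholds anchored at the Otsu level feed a circular Hough
    accumulator over ``[min_radius, max_radius]``. Among the strongest
    accumulator peaks the circle with the greatest integrated green intensity
    is returned; ``score`` is its normalised accumulator response (fraction
    of the perimeter supported by edges).

    Raises :class:`NoCircleFound` when the image is featureless or no
    candidate reaches ``response_threshold``.
    """
    if min_radius > max_radius or min_radius < 1:
        raise ValueError("require 1 <= min_radius <= max_radius")
    green = img.pixels[:, :, 1].astype(float)
    if green.size == 0:
        raise ValueError("empty image")
    if green.max() - green.min() < 5:
        raise NoCircleFound("image has no contrast")

    smoothed = gaussian(green, sigma=2.0, preserve_range=True)
    otsu = threshold_otsu(smoothed)
    edges = canny(smoothed, sigma=1.0, low_threshold=0.5 * otsu, high_threshold=otsu)
    if not edges.any():
        raise NoCircleFound("no edges above the Otsu-anchored thresholds")

    radii = np.arange(min_radius, max_radius + 1)
    accum = hough_circle(edges, radii)  # perimeter-normalised votes in [0, 1]
    accums, cxs, cys, rads = hough_circle_peaks(accum, radii, total_num_peaks=5)
    if len(accums) == 0:
        raise NoCircleFound("empty accumulator")
    responses = np.asarray(accums, dtype=float)
    keep = responses >= max(response_threshold, 0.5 * responses.max())
    if not keep.any() or responses.max() < response_threshold:
        raise NoCircleFound(f"best accumulator response {responses.max():.3f} below threshold")

    best, best_green = None, -np.inf
    for resp, cx, cy, rad in zip(responses[keep], cxs[keep], cys[keep], rads[keep]):
        g = _integrated_green(green, (cy, cx), rad)
        if g > best_green:
            best_green = g
            best = (float(cy), float(cx), float(rad), float(resp))
    cy, cx, rad, resp = best
    return CircleRegion.from_geometry(img.shape, (cy, cx), rad, score=resp)


def extract_luminous_pixels(
    img: RGBImage, region: CircleRegion, luminous_fraction: float = 1.0
) -> PixelSample:
    """Extract the brightest ``luminous_fraction`` of in-mask pixels.

    Pixels are ranked by green channel, descending, ties broken by row-major
    position; the default fraction of 1.0 keeps every in-mask pixel.
    """
    if not (0 < luminous_fraction <= 1):
        raise ValueError("luminous_fraction must lie in (0, 1]")
    if region.mask.shape != img.shape:
        raise ValueError("region mask is not aligned to the image")
    rows, cols = np.nonzero(region.mask)
    n = len(rows)
    if n == 0:
        raise ValueError("empty mask")
    rgb = img.pixels[rows, cols].astype(np.uint8)
    k = max(1, int(round(luminous_fraction * n)))
    if k < n:
        order = np.lexsort((np.arange(n), -rgb[:, 1].astype(int)))
        rgb = rgb[order[:k]]
    return PixelSample(rgb_values=rgb, origin=region)


def classify_sample(
    img: RGBImage,
    region: CircleRegion,
    y_threshold: float,
    transform: ColorTransform | None = None,
    luminous_fraction: float = 1.0,
) -> str:
    """Label a frame ``"positive"`` or ``"negative"``.

    Positive iff the mean CIE Y of the extracted pixels exceeds
    ``y_threshold`` (typically the blank mean + 3·SD from calibration).
    """
    sample = extract_luminous_pixels(img, region, luminous_fraction)
    stats = mean_color_stats(sample, transform=transform)
    return "positive" if stats["mean_Y"] > y_threshold else "negative"
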