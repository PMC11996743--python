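"""LFA strip densitometry: lane profiles, background subtraction, integrated density.

Quantifies lateral-flow strips the way gel/strip densitometry does: convert
to grayscale, average a lane of rows into a column profile, estimate the
membrane background as the median of out-of-band columns, and sum the
band's one-sided excursion (dark bands below background for colorimetric
strips, bright bands above for fluorescent ones). The cut-off concentration
uses the same blank mean + 3·SD rule as the biochip readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorimetry import GrayWeights, grayscale_array
from .quantify import NOT_DETECTED

__all__ = [
    "LaneProfile",
    "BandWindow",
    "IntegratedDensityResult",
    "to_grayscale_image",
    "lane_profile",
    "integrated_density",
    "find_band",
    "lfa_cutoff",
]


@dataclass(frozen=True)
class BandWindow:
    """Half-open column interval holding one line, with its polarity."""

    col_lo: int
    col_hi: int
    polarity: str = "dark-band"

    def __post_init__(self):
        if not self.col_lo < self.col_hi:
            raise ValueError("require col_lo < col_hi")
        if self.polarity not in ("dark-band", "bright-band"):
            raise ValueError("polarity must be 'dark-band' or 'bright-band'")

    @property
    def width(self) -> int:
        return self.col_hi - self.col_lo


@dataclass
class LaneProfile:
    """Column-wise mean gray over a lane of rows."""

    positions: np.ndarray
    values: np.ndarray
    lane_rows: tuple[int, int]

    def __post_init__(self):
        self.positions = np.asarray(self.positions)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must align")


@dataclass(frozen=True)
class IntegratedDensityResult:
    integrated_density: float
    background_level: float
    band: BandWindow
    raw_sum: float


def to_grayscale_image(img, weights: GrayWeights | None = None) -> np.ndarray:
    """Per-pixel weighted grayscale of an RGB raster (uint8 output)."""
    arr = np.asarray(getattr(img, "pixels", img))
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    return grayscale_array(arr, weights)


def lane_profile(gray: np.ndarray, lane_rows: tuple[int, int]) -> LaneProfile:
    """Column-wise mean over the half-open row interval ``lane_rows``."""
    arr = np.asarray(gray, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a single-channel raster")
    lo, hi = lane_rows
    if not (0 <= lo < hi <= arr.shape[0]):
        raise ValueError("lane_rows must be a non-empty interval inside the image")
    vals = arr[lo:hi].mean(axis=0)
    return LaneProfile(positions=np.arange(arr.shape[1]), values=vals, lane_rows=(lo, hi))


def integrated_density(
    profile: LaneProfile,
    band: BandWindow,
    exclude: tuple[BandWindow, ...] | list = (),
) -> IntegratedDensityResult:
    """Background-subtracted one-sided sum of the band's gray excursion.

    Background is the median of profile columns outside the band and outside
    any ``exclude`` windows (use the control line here so it cannot bias the
    membrane estimate). Dark bands sum max(background − value, 0); bright
    bands sum max(value − background, 0). Invariant to adding a constant to
    the whole profile.
    """
    n = len(profile.values)
    if not (0 <= band.col_lo and band.col_hi <= n):
        raise ValueError("band window outside profile support")
    bg_mask = np.ones(n, dtype=bool)
    bg_mask[band.col_lo : band.col_hi] = False
    for w in exclude:
        bg_mask[max(w.col_lo, 0) : min(w.col_hi, n)] = False
    if not bg_mask.any():
        raise ValueError("no columns left to estimate the background")
    background = float(np.median(profile.values[bg_mask]))
    segment = profile.values[band.col_lo : band.col_hi]
    if band.polarity == "dark-band":
        excursion = np.clip(background - segment, 0.0, None)
    else:
        excursion = np.clip(segment - background, 0.0, None)
    return IntegratedDensityResult(
        integrated_density=float(excursion.sum()),
        background_level=background,
        band=band,
        raw_sum=float(segment.sum()),
    )


def find_band(profile: LaneProfile, width: int, polarity: str = "dark-band") -> BandWindow:
    """Convenience auto-detection: center a window of ``width`` on the profile extremum.

    A flat-bottomed band is a plateau of equal extreme values; the window is
    centred on the plateau's midpoint, not its first column.
    """
    if not (0 < width <= len(profile.values)):
        raise ValueError("width must be positive and fit the profile")
    extreme = profile.values.min() if polarity == "dark-band" else profile.values.max()
    idx = float(np.mean(np.flatnonzero(profile.values == extreme)))
    lo = int(np.clip(round(idx) - width // 2, 0, len(profile.values) - width))
    return BandWindow(lo, lo + width, polarity)


def lfa_cutoff(densities, blanks):
    """Smallest concentration whose integrated density clears blank mean + 3·SD.

    ``densities`` is an iterable of (concentration, integrated_density);
    ``blanks`` the blank-strip densities. Returns ``NOT_DETECTED`` when no
    concentration clears the threshold.
    """
    blanks = np.asarray(list(blanks), dtype=float)
    if blanks.size == 0:
        raise ValueError("no blank densities supplied")
    sd = float(blanks.std(ddof=1)) if blanks.size > 1 else 0.0
    threshold = float(blanks.mean()) + 3.0 * sd
    pairs = sorted((float(c), float(d)) for c, d in densities)
    if not pairs:
        raise ValueError("no densities supplied")
    for c, d in pairs:
        if d > threshold:
            return c
    return NOT_DETECTED
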