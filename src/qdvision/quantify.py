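"""Assay statistics: normalisation, calibration, LOD, cut-off, discrimination.

Turns per-image intensity readouts (mean CIE Y, grayscale, or a raw channel)
into the quantities a dose–response immunoassay reports:

* max-normalised intensities (highest signal set to 1.0);
* an ordinary-least-squares calibration over the assay's linear range;
* a four-parameter-logistic (4PL) fit over the full dose range;
* limit of detection from the blank mean + 3·SD rule, inverted through the
  linear calibration;
* the cut-off concentration (lowest tested dose distinguishable from blank);
* the discrimination value (highest-dose / blank intensity ratio) used to
  compare readout color spaces;
* a specificity report ranking the target analyte against interferents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth import BindingModel, simulate_binding

__all__ = [
    "ConcentrationSeries",
    "LinearCalibration",
    "LODResult",
    "DoseResponseFit",
    "DiscriminationResult",
    "SpecificityPanel",
    "normalize_intensities",
    "fit_linear",
    "fit_dose_response",
    "lod",
    "cutoff_concentration",
    "discrimination_value",
    "specificity_report",
    "NOT_DETECTED",
]

NOT_DETECTED = "not-detected"


@dataclass
class ConcentrationSeries:
    """Replicated (concentration, intensity) measurements; concentration 0 = blank."""

    entries: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.entries)
        required = {"concentration", "intensity"}
        if not required.issubset(df.columns):
            raise ValueError("entries need 'concentration' and 'intensity' columns")
        if "replicate" not in df.columns:
            df = df.assign(replicate=df.groupby("concentration").cumcount())
        if not np.isfinite(df["intensity"]).all():
            raise ValueError("intensities must be finite")
        if (df["concentration"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        self.entries = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "ConcentrationSeries":
        return cls(pd.DataFrame.from_records(records, columns=["concentration", "replicate", "intensity"]))

    @property
    def blanks(self) -> np.ndarray:
        return self.entries.loc[self.entries["concentration"] == 0, "intensity"].to_numpy()

    def mean_by_concentration(self, include_blanks: bool = True) -> pd.Series:
        df = self.entries if include_blanks else self.entries[self.entries["concentration"] > 0]
        return df.groupby("concentration")["intensity"].mean()


@dataclass(frozen=True)
class LinearCalibration:
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    def __post_init__(self):
        if not self.conc_range[0] < self.conc_range[1]:
            raise ValueError("conc_range must be increasing")
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def inverse(self, intensity: float) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("calibration slope is zero")
        return (intensity - self.intercept) / self.slope


@dataclass(frozen=True)
class LODResult:
    lod: float
    blank_mean: float
    blank_sd: float
    threshold_intensity: float
    n_blanks: int
    clamped: bool = False


@dataclass(frozen=True)
class DoseResponseFit:
    model: BindingModel
    converged: bool
    residual_norm: float
    message: str = ""


@dataclass(frozen=True)
class DiscriminationResult:
    method: str
    blank_intensity: float
    max_intensity: float

    @property
    def value(self) -> float:
        return self.max_intensity / self.blank_intensity


@dataclass
class SpecificityPanel:
    """Per-analyte intensities with one designated target."""

    rows: list = field(default_factory=list)  # (analyte label, intensity)
    target_analyte: str = "CEA"


def normalize_intensities(values) -> np.ndarray:
    """Divide by the maximum so the strongest signal is exactly 1.0."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or arr.max() <= 0:
        raise ValueError("need at least one strictly positive intensity")
    return arr / arr.max()


def fit_linear(series: ConcentrationSeries, conc_range: tuple[float, float]) -> LinearCalibration:
    """OLS of mean intensity per concentration vs concentration, within range."""
    lo, hi = conc_range
    means = series.mean_by_concentration()
    means = means[(means.index >= lo) & (means.index <= hi)]
    if means.index.nunique() < 2:
        raise ValueError("need >= 2 distinct concentrations inside the range")
    res = stats.linregress(means.index.to_numpy(float), means.to_numpy(float))
    return LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        conc_range=(float(lo), float(hi)),
    )


def _4pl(c, baseline, top, ec50, hill):
    c = np.asarray(c, dtype=float)
    with np.errstate(over="ignore"):
        ch = np.where(c > 0, c, np.nan) ** hill
        out = baseline + (top - baseline) * ch / (ec50**hill + ch)
    return np.where(c > 0, out, baseline)


def fit_dose_response(series: ConcentrationSeries) -> DoseResponseFit:
    """Nonlinear least squares for the 4PL on per-concentration means.

    Initialised from the data (baseline = min mean, top = max mean, ec50 =
    concentration nearest the half-range intensity, hill = 1). Degenerate
    (flat) data or solver failure yields ``converged = False`` rather than an
    exception.
    """
    means = series.mean_by_concentration()
    concs = means.index.to_numpy(float)
    ys = means.to_numpy(float)
    if (concs > 0).sum() < 4:
        raise ValueError("need >= 4 distinct non-blank concentrations")
    lo_y, hi_y = ys.min(), ys.max()
    if hi_y - lo_y < 1e-12 * max(abs(hi_y), 1.0):
        flat = BindingModel.model_construct(baseline=lo_y, top=hi_y, ec50=1.0, hill=1.0)
        return DoseResponseFit(flat, converged=False, residual_norm=0.0, message="flat data: hill unidentifiable")
    half = (lo_y + hi_y) / 2.0
    ec50_0 = float(concs[concs > 0][np.argmin(np.abs(ys[concs > 0] - half))])
    p0 = [max(lo_y, 1e-12), hi_y, ec50_0, 1.0]
    bounds = ([0.0, 0.0, 1e-9, 1e-3], [np.inf, np.inf, np.inf, 20.0])
    try:
        popt, _ = optimize.curve_fit(
            _4pl, concs, ys, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-12, ftol=1e-12
        )
    except (RuntimeError, ValueError) as exc:
        model = BindingModel.model_construct(baseline=p0[0], top=p0[1], ec50=p0[2], hill=p0[3])
        return DoseResponseFit(model, converged=False, residual_norm=np.inf, message=str(exc))
    resid = float(np.linalg.norm(_4pl(concs, *popt) - ys))
    if popt[1] <= popt[0]:
        model = BindingModel.model_construct(
            baseline=float(popt[0]), top=float(popt[1]), ec50=float(popt[2]), hill=float(popt[3])
        )
        return DoseResponseFit(model, converged=False, residual_norm=resid, message="top <= baseline")
    model = BindingModel(
        baseline=float(popt[0]), top=float(popt[1]), ec50=float(popt[2]), hill=float(popt[3])
    )
    return DoseResponseFit(model, converged=True, residual_norm=resid)


def lod(blanks, cal: LinearCalibration) -> LODResult:
    """Limit of detection: (blank mean + 3·SD − intercept) / slope.

    Sample SD uses the n−1 denominator. A threshold below the intercept
    clamps the LOD at 0 with the ``clamped`` flag set.
    """
    arr = np.asarray(blanks, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 blank replicates")
    if cal.slope <= 0:
        raise ValueError("calibration slope must be > 0 to invert")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    threshold = mean + 3.0 * sd
    raw = (threshold - cal.intercept) / cal.slope
    clamped = raw < 0
    return LODResult(
        lod=max(raw, 0.0),
        blank_mean=mean,
        blank_sd=sd,
        threshold_intensity=threshold,
        n_blanks=int(arr.size),
        clamped=clamped,
    )


def cutoff_concentration(series: ConcentrationSeries):
    """Lowest tested concentration whose mean intensity clears blank mean + 3·SD.

    Returns ``NOT_DETECTED`` when no tested concentration clears the
    threshold; consistent with the blank+3SD LOD rule.
    """
    blanks = series.blanks
    if blanks.size == 0:
        raise ValueError("series contains no blanks")
    means = series.mean_by_concentration(include_blanks=False)
    if means.empty:
        raise ValueError("series contains no non-blank concentrations")
    sd = float(blanks.std(ddof=1)) if blanks.size > 1 else 0.0
    threshold = float(blanks.mean()) + 3.0 * sd
    above = means[means > threshold]
    if above.empty:
        return NOT_DETECTED
    return float(above.index.min())


def discrimination_value(blank: float, max_conc: float, method: str = "cie_Y") -> DiscriminationResult:
    """Ratio of the highest-concentration intensity to the blank intensity."""
    if method not in ("cie_Y", "grayscale", "rgb_G"):
        raise ValueError("method must be one of cie_Y, grayscale, rgb_G")
    if blank <= 0:
        raise ValueError("blank intensity must be > 0")
    return DiscriminationResult(method=method, blank_intensity=float(blank), max_intensity=float(max_conc))


def specificity_report(panel: SpecificityPanel) -> dict:
    """Rank analytes by max-normalised intensity; check the target dominates.

    ``margin`` is the target's normalised intensity minus the strongest
    non-target's; ``target_is_max`` is True when the margin is positive.
    """
    if not panel.rows:
        raise ValueError("empty specificity panel")
    labels = [r[0] for r in panel.rows]
    if panel.target_analyte not in labels:
        raise ValueError(f"target analyte {panel.target_analyte!r} not in panel")
    norm = normalize_intensities([r[1] for r in panel.rows])
    table = pd.DataFrame({"analyte": labels, "normalized_intensity": norm}).sort_values(
        "normalized_intensity", ascending=False, kind="stable"
    ).reset_index(drop=True)
    target_val = float(table.loc[table["analyte"] == panel.target_analyte, "normalized_intensity"].max())
    others = table.loc[table["analyte"] != panel.target_analyte, "normalized_intensity"]
    margin = target_val - (float(others.max()) if not others.empty else 0.0)
    return {"table": table, "target_is_max": margin > 0, "margin": margin}
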