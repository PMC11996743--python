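"""End-to-end orchestration: simulate → detect → convert → quantify → compare.

Library-level implementations behind the CLI subcommands. Every run writes a
provenance block (config hash, seed, tool version) so any numeric output is
traceable to an input file or seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colorimetry import ColorTransform, GrayWeights, mean_color_stats
from .imaging import NoCircleFound, RGBImage, detect_circle, extract_luminous_pixels
from .io import config_hash, read_image, read_manifest, write_image, write_manifest
from .lfa import BandWindow, integrated_density, lane_profile, lfa_cutoff, to_grayscale_image
from .quantify import (
    NOT_DETECTED,
    ConcentrationSeries,
    cutoff_concentration,
    discrimination_value,
    fit_dose_response,
    fit_linear,
    lod,
)
from .synth import AssayConfig, LFAStripConfig, render_biochip_image, render_lfa_strip

log = logging.getLogger("qdvision")


def _provenance(cfg_payload, seed: int) -> dict:
    return {"config_hash": config_hash(cfg_payload), "seed": int(seed), "tool_version": __version__}


def simulate_biochip_set(
    cfg: AssayConfig,
    out_dir,
    seed: int = 0,
    blank_replicates: int = 3,
    image_format: str = "png",
) -> pd.DataFrame:
    """Render the configured concentration series plus blanks; write manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    jobs = [(c, "sample") for c in cfg.concentrations for _ in range(cfg.replicates)]
    jobs += [(0.0, "blank")] * blank_replicates
    rep_counter: dict[float, int] = {}
    for c, role in jobs:
        rep = rep_counter.get(c, 0)
        rep_counter[c] = rep + 1
        rep_seed = int(np.random.SeedSequence([seed, int(round(c * 1e6)), rep]).generate_state(1)[0] % (2**31))
        pixels, _ = render_biochip_image(cfg, c, rep_seed)
        fname = f"chip_c{c:g}_r{rep}.{image_format}"
        write_image(out_dir / fname, pixels)
        rows.append(
            {
                "filename": fname,
                "concentration_ng_per_ml": c,
                "replicate": rep,
                "seed": rep_seed,
                "role": role,
                "analyte": "CEA",
            }
        )
    manifest = write_manifest(out_dir / "manifest.csv", rows)
    payload = cfg.model_dump() | {"blank_replicates": blank_replicates}
    (out_dir / "provenance.json").write_text(json.dumps(_provenance(payload, seed), indent=2))
    log.info("simulate: wrote %d images to %s", len(rows), out_dir)
    return manifest


def simulate_lfa_set(
    cfg: LFAStripConfig,
    concentrations,
    out_dir,
    seed: int = 0,
    replicates: int = 1,
    blank_replicates: int = 3,
    image_format: str = "png",
) -> pd.DataFrame:
    """Render an LFA dilution series plus blank strips; write manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    jobs = [(float(c), "sample") for c in concentrations for _ in range(replicates)]
    jobs += [(0.0, "blank")] * blank_replicates
    rep_counter: dict[float, int] = {}
    for c, role in jobs:
        if c < 0:
            raise ValueError("concentrations must be non-negative")
        rep = rep_counter.get(c, 0)
        rep_counter[c] = rep + 1
        rep_seed = int(np.random.SeedSequence([seed, int(round(c * 1e6)), rep]).generate_state(1)[0] % (2**31))
        pixels, _ = render_lfa_strip(cfg, c, rep_seed)
        fname = f"strip_{cfg.mode}_c{c:g}_r{rep}.{image_format}"
        write_image(out_dir / fname, pixels)
        rows.append(
            {
                "filename": fname,
                "concentration_ng_per_ml": c,
                "replicate": rep,
                "seed": rep_seed,
                "role": role,
                "analyte": "CEA",
            }
        )
    manifest = write_manifest(out_dir / "manifest.csv", rows)
    (out_dir / "provenance.json").write_text(json.dumps(_provenance(cfg.model_dump(), seed), indent=2))
    log.info("simulate-lfa: wrote %d strips to %s", len(rows), out_dir)
    return manifest


def analyze_manifest(
    manifest_path,
    images_dir=None,
    min_radius: int = 10,
    max_radius: int = 60,
    luminous_fraction: float = 1.0,
    transform: ColorTransform | None = None,
    weights: GrayWeights | None = None,
    linear_range: tuple[float, float] = (0.01, 1.0),
) -> dict:
    """Run detect → extract → color stats → quantification over a manifest.

    Returns ``{"records": DataFrame, "summary": dict}``. Unreadable images or
    detection failures flag the row and are skipped; the skipped count is
    reported in the summary.
    """
    manifest_path = Path(manifest_path)
    images_dir = Path(images_dir) if images_dir else manifest_path.parent
    manifest = read_manifest(manifest_path)
    t = transform or ColorTransform()
    w = weights or GrayWeights()

    records, skipped = [], 0
    for _, row in manifest.iterrows():
        rec = {
            "filename": row["filename"],
            "concentration": float(row["concentration_ng_per_ml"]),
            "replicate": int(row["replicate"]),
            "role": row["role"],
            "analyte": row["analyte"],
        }
        try:
            img = RGBImage(read_image(images_dir / row["filename"]))
            region = detect_circle(img, min_radius, max_radius)
            sample = extract_luminous_pixels(img, region, luminous_fraction)
            stats = mean_color_stats(sample, transform=t, weights=w)
        except (OSError, ValueError, NoCircleFound) as exc:
            log.warning("analyze: skipping %s (%s)", row["filename"], exc)
            skipped += 1
            records.append(rec | {"skipped": True, "error": str(exc)})
            continue
        rec |= {
            "skipped": False,
            "center_row": region.center[0],
            "center_col": region.center[1],
            "radius": region.radius,
            "score": region.score,
            "n_pixels": sample.count,
        }
        rec |= stats
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    summary = {"n_images": len(manifest), "n_skipped": skipped}
    ok = df[~df["skipped"]] if "skipped" in df else df

    if not ok.empty and (ok["analyte"].nunique() <= 1):
        series = ConcentrationSeries(
            ok.rename(columns={"mean_Y": "intensity"})[["concentration", "replicate", "intensity"]]
        )
        summary |= _quantify_series(series, ok, linear_range)
    summary["provenance"] = _provenance({"manifest": str(manifest_path)}, 0)
    return {"records": df, "summary": summary}


def _quantify_series(series: ConcentrationSeries, ok: pd.DataFrame, linear_range) -> dict:
    out: dict = {}
    means = series.mean_by_concentration()
    blanks = series.blanks
    try:
        cal = fit_linear(series, linear_range)
        out["linear_calibration"] = {
            "slope": cal.slope,
            "intercept": cal.intercept,
            "r_squared": cal.r_squared,
            "conc_range": list(cal.conc_range),
        }
        if blanks.size >= 2:
            res = lod(blanks, cal)
            out["lod"] = {
                "lod_ng_per_ml": res.lod,
                "blank_mean": res.blank_mean,
                "blank_sd": res.blank_sd,
                "threshold_intensity": res.threshold_intensity,
                "n_blanks": res.n_blanks,
                "clamped": res.clamped,
            }
    except ValueError as exc:
        out["linear_calibration"] = {"error": str(exc)}
    try:
        fit = fit_dose_response(series)
        out["dose_response"] = {
            "baseline": fit.model.baseline,
            "top": fit.model.top,
            "ec50": fit.model.ec50,
            "hill": fit.model.hill,
            "converged": fit.converged,
            "residual_norm": fit.residual_norm,
        }
    except ValueError as exc:
        out["dose_response"] = {"error": str(exc)}
    if blanks.size > 0 and not means[means.index > 0].empty:
        cutoff = cutoff_concentration(series)
        out["cutoff_ng_per_ml"] = cutoff if cutoff == NOT_DETECTED else float(cutoff)
        c_max = means.index.max()
        blank_df = ok[ok["concentration"] == 0]
        top_df = ok[ok["concentration"] == c_max]
        out["discrimination"] = {}
        for method, col in (("cie_Y", "mean_Y"), ("grayscale", "mean_gray"), ("rgb_G", "mean_G")):
            b, m = float(blank_df[col].mean()), float(top_df[col].mean())
            if b > 0:
                out["discrimination"][method] = discrimination_value(b, m, method).value
    return out


def analyze_lfa_manifest(
    manifest_path,
    images_dir=None,
    lane_rows: tuple[int, int] = (15, 25),
    test_window: tuple[int, int] = (90, 102),
    control_window: tuple[int, int] = (120, 132),
    polarity: str = "dark-band",
    weights: GrayWeights | None = None,
) -> dict:
    """Lane profiles + integrated densities + cut-off over a strip manifest."""
    manifest_path = Path(manifest_path)
    images_dir = Path(images_dir) if images_dir else manifest_path.parent
    manifest = read_manifest(manifest_path)
    band = BandWindow(*test_window, polarity=polarity)
    control = BandWindow(*control_window, polarity=polarity)

    rows = []
    for _, row in manifest.iterrows():
        gray = to_grayscale_image(read_image(images_dir / row["filename"]), weights)
        profile = lane_profile(gray, lane_rows)
        res = integrated_density(profile, band, exclude=(control,))
        rows.append(
            {
                "filename": row["filename"],
                "concentration": float(row["concentration_ng_per_ml"]),
                "role": row["role"],
                "background": res.background_level,
                "integrated_density": res.integrated_density,
                "raw_sum": res.raw_sum,
            }
        )
    df = pd.DataFrame(rows)
    blanks = df.loc[df["concentration"] == 0, "integrated_density"].to_numpy()
    densities = list(
        df[df["concentration"] > 0].groupby("concentration")["integrated_density"].mean().items()
    )
    cutoff = lfa_cutoff(densities, blanks) if blanks.size and densities else NOT_DETECTED if blanks.size else None
    summary = {
        "n_strips": len(df),
        "cutoff_ng_per_ml": cutoff if cutoff in (None, NOT_DETECTED) else float(cutoff),
        "provenance": _provenance({"manifest": str(manifest_path)}, 0),
    }
    return {"records": df, "summary": summary}
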