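"""Image and manifest I/O.

Images are 8-bit RGB PNG (default) or TIFF. The manifest CSV maps image
files to analyte concentrations and replicates with columns:
filename, concentration_ng_per_ml, replicate, seed, role, analyte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

MANIFEST_COLUMNS = ["filename", "concentration_ng_per_ml", "replicate", "seed", "role", "analyte"]


def write_image(path, pixels: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(pixels, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr, extension=path.suffix or ".png")


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def write_manifest(path, rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def config_hash(obj) -> str:
    """Stable sha256 over a JSON-serialisable config (provenance key)."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
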