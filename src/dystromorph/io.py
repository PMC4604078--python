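"""Shared readers and writers: calibrated TIFF images/volumes, CSV tables.

Calibration (um per pixel / voxel) travels in the TIFF ImageDescription tag
as a small JSON payload, so a write-then-read round trip restores both the
array and its pitch.  Tables are plain CSV with a header row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class CalibrationError(ValueError):
    pass


def write_image(path, image: np.ndarray, um_per_px: float) -> None:
    if um_per_px <= 0:
        raise CalibrationError("um_per_px must be positive")
    desc = json.dumps({"um_per_px": um_per_px})
    tifffile.imwrite(path, np.asarray(image), description=desc)


def read_image(path) -> tuple[np.ndarray, float]:
    """Returns (array, um_per_px); raises if the calibration is missing."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    if "um_per_px" not in meta and "um_per_vox" not in meta:
        raise CalibrationError(
            f"{path}: no um-per-pixel calibration in TIFF metadata; "
            "pass the pitch explicitly")
    return arr, float(meta.get("um_per_px", meta.get("um_per_vox")))


def write_volume(path, volume: np.ndarray, um_per_vox: float) -> None:
    if um_per_vox <= 0:
        raise CalibrationError("um_per_vox must be positive")
    desc = json.dumps({"um_per_vox": um_per_vox})
    tifffile.imwrite(path, np.asarray(volume), description=desc)


read_volume = read_image   # same container, same metadata convention


def write_table(records, path) -> None:
    """Write records (DataFrame, or a list of dataclasses/dicts) as CSV."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                for r in records]
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_roi_polygons(path) -> list[np.ndarray]:
    """ROI polygons from CSV: columns x,y in pixels, blank line or a
    ``polygon`` id column separating polygons."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError("ROI CSV needs x and y columns")
    if "polygon" in cols:
        return [g[[cols["x"], cols["y"]]].to_numpy(float)
                for _, g in df.groupby(cols["polygon"], sort=False)]
    return [df[[cols["x"], cols["y"]]].to_numpy(float)]


def provenance_record(out_dir, seed, config: dict | None = None) -> Path:
    """Write a provenance JSON (config hash, seed, version) next to outputs."""
    from . import __version__
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    rec = {
        "software": "dystromorph",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config or {},
    }
    out = Path(out_dir) / "provenance.json"
    out.write_text(json.dumps(rec, indent=2, default=str) + "\n")
    return out
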