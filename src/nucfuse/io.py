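"""Reading/writing the pipeline's external formats (TIFF, CSV, JSON, YAML)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .image import TwoChannelImage

DEFAULT_CONFIG = {
    "w_g": 0.6,
    "w_r": 0.4,
    "local_window": 701,
    "sigma": 2.0,
    "r": 0.928,
    "min_area": 80,
    "min_mean_intensity": None,
    "w2": 0.4,
    "glcm_offset": 7,
    "glcm_levels": 32,
    "probability_threshold": 0.90,
    "cv_folds": 3,
    "mi_bins": 10,
    "P": None,  # dataset-wide ceiling; None: per-image max fallback
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict:
    """YAML config merged over the documented defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def read_pair(green_path: str | Path, red_path: str | Path, P: float | None = None) -> TwoChannelImage:
    green = tifffile.imread(green_path).astype(float)
    red = tifffile.imread(red_path).astype(float)
    return TwoChannelImage(green=green, red=red, P=P or 0.0)


def write_image(path: str | Path, raster: np.ndarray) -> None:
    """16-bit grayscale TIFF (labels and masks included)."""
    arr = np.asarray(raster)
    if arr.dtype.kind == "f":
        arr = np.clip(arr, 0, 65535)
    tifffile.imwrite(path, arr.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_classes_csv(path: str | Path, classes: dict[int, str]) -> None:
    pd.DataFrame(
        {"nucleus_id": list(classes), "tissue_class": list(classes.values())}
    ).to_csv(path, index=False)


def read_classes_csv(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path)
    return dict(zip(df["nucleus_id"].astype(int), df["tissue_class"]))


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
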