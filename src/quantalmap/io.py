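"""TIFF / CSV / YAML interchange helpers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def write_movie_tiff(path, movie: np.ndarray) -> None:
    """One page per frame."""
    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.float32))


def write_stack_tiff(path, stack: np.ndarray) -> None:
    """One page per plane (single channel) or per plane per channel."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    try:
        return tifffile.imread(str(path))
    except Exception as exc:  # corrupt/unreadable input
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc


def write_ground_truth_csv(path, gt) -> None:
    gt.to_frame().to_csv(path, index=False)


def read_roi_csv(path) -> pd.DataFrame:
    """User-supplied ROI table: id, x_um, y_um."""
    df = pd.read_csv(path)
    missing = {"id", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV {path} lacks columns {sorted(missing)}")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_run_log(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
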