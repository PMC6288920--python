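"""Image, annotation and table I/O.

Images travel as 8- or 16-bit grayscale PNG/TIFF; vessel and region masks
as 0/255 PNG; disc annotations as CSV (``subject_id, eye, x_min, y_min,
x_max, y_max``, 0-based, max-exclusive); densities and QC outcomes as tidy
CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .regions import DiscAnnotation

__all__ = [
    "read_image", "write_image", "write_mask", "read_mask",
    "read_annotations", "sha256_file", "write_json",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as float64; multi-channel inputs are averaged."""
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image")
    return arr


def write_image(path: str | Path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write an intensity grid as 8- or 16-bit grayscale PNG (clipped)."""
    if bit_depth == 8:
        out = np.clip(np.round(image), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), out)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as a 0/255 PNG."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 127


def read_annotations(path: str | Path) -> Dict[Tuple[str, str], DiscAnnotation]:
    """Read disc bounding boxes keyed by (subject_id, eye)."""
    df = pd.read_csv(path, comment="#")
    required = {"subject_id", "eye", "x_min", "y_min", "x_max", "y_max"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[(str(row["subject_id"]), str(row["eye"]))] = DiscAnnotation(
            bbox=(float(row["x_min"]), float(row["y_min"]),
                  float(row["x_max"]), float(row["y_max"])))
    return out


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path: str | Path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
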