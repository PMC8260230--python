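"""File I/O: multi-page TIFF images, ground-truth sidecars, expression tables.

Tracks use the CSV dialect of :class:`streakdyn.tracks.TrackSet`
(``to_csv`` / ``from_csv``); color and barcode tables are plain pandas
CSV.  Images travel as multi-page TIFF (one page per channel) with a JSON
sidecar for any ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dynamics import ExpressionOrdering

__all__ = [
    "write_image_pair",
    "read_image_pair",
    "write_sidecar",
    "read_sidecar",
    "write_expression",
    "read_expression",
]


def write_image_pair(path, *channels: np.ndarray) -> None:
    """Write channels as pages of one TIFF (float32)."""
    tifffile.imwrite(str(path), np.stack([np.asarray(c, dtype=np.float32) for c in channels]))


def read_image_pair(path) -> list[np.ndarray]:
    """Read all pages of a TIFF as float arrays."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        return [arr.astype(float)]
    return [page.astype(float) for page in arr]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sidecar(path, truth: dict) -> None:
    """Write a ground-truth dict next to an image as JSON."""
    Path(path).write_text(json.dumps(_jsonable(truth), indent=2))


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def write_expression(path, ordering: ExpressionOrdering) -> None:
    """Write a cells x genes matrix as CSV (cells as rows, in order)."""
    ordering.to_frame().to_csv(path)


def read_expression(path) -> ExpressionOrdering:
    df = pd.read_csv(path, index_col=0)
    return ExpressionOrdering.from_frame(df)
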