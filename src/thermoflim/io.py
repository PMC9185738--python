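"""File I/O for FLIM data products.

A FLIM stack on disk is a multi-page TIFF (one page per arrival-time bin,
uint16 counts) with a ``*.meta.json`` sidecar (``bin_width_ns``,
``period_ns``, ``n_bins`` plus generator metadata) and a single-page uint16
label TIFF mask (0 = background).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_flim_stack",
    "read_flim_stack",
    "write_mask",
    "read_mask",
    "write_temperature_image",
    "read_calibration_csv",
]


def write_flim_stack(
    stack: np.ndarray, meta: dict, path: str | Path
) -> tuple[Path, Path]:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))
    meta_path = path.with_suffix("").with_suffix(".meta.json")
    meta = dict(meta)
    meta.setdefault("n_bins", int(stack.shape[0]))
    meta_path.write_text(json.dumps(meta, indent=1))
    return path, meta_path


def read_flim_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    stack = tifffile.imread(path)
    meta_path = path.with_suffix("").with_suffix(".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("bin_width_ns", "period_ns"):
        if key not in meta:
            raise KeyError(f"metadata sidecar lacks required key {key!r}")
    return stack, meta


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_temperature_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def read_calibration_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"T_C", "tau_M_ns"} - set(df.columns)
    if missing:
        raise KeyError(f"calibration CSV lacks columns {sorted(missing)}")
    return df
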