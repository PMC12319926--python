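"""NIfTI and report input/output.

Functional lines are stored as NIfTI-1 with shape (readout, 1, 1, TR) so
the readout voxel size and TR travel in the header zooms; 2D structural
images as (readout, phase, 1).  Reports are plain structured text
(key=value) and tabular CSV so they stay diffable and auditable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "write_line_nifti",
    "read_line_nifti",
    "write_image_nifti",
    "read_image_nifti",
    "write_report",
    "read_report",
    "write_table",
]


def write_line_nifti(
    data: np.ndarray,
    path: str | Path,
    voxel_mm: float = 0.39,
    tr_s: float = 0.25,
    line_width_mm: float = 3.0,
) -> Path:
    """Store a (readout, TR) line time series as a 4D NIfTI."""
    arr = np.asarray(data)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("expected (readout,) or (readout, TR) data")
    vol = arr.reshape(arr.shape[0], 1, 1, arr.shape[1]).astype(np.float32)
    img = nib.Nifti1Image(vol, affine=np.diag([voxel_mm, line_width_mm, line_width_mm, 1.0]))
    img.header.set_zooms((voxel_mm, line_width_mm, line_width_mm, tr_s))
    img.header.set_xyzt_units("mm", "sec")
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_line_nifti(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Read a line time series; returns (data (readout, TR), voxel_mm, tr_s)."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    if vol.ndim != 4 or vol.shape[1] != 1 or vol.shape[2] != 1:
        raise ValueError(f"{path}: not a line time series (shape {vol.shape})")
    zooms = img.header.get_zooms()
    return vol[:, 0, 0, :], float(zooms[0]), float(zooms[3])


def write_image_nifti(
    data: np.ndarray, path: str | Path, voxel_mm: tuple[float, float] = (0.39, 0.39)
) -> Path:
    """Store a 2D (readout, phase) image as a 3D NIfTI."""
    arr = np.asarray(data)
    if arr.ndim != 2:
        raise ValueError("expected a 2D image")
    vol = arr[:, :, None].astype(np.float32)
    img = nib.Nifti1Image(vol, affine=np.diag([voxel_mm[0], voxel_mm[1], 1.0, 1.0]))
    img.header.set_zooms((voxel_mm[0], voxel_mm[1], 1.0))
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_image_nifti(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj)[:, :, 0]


def write_report(values: Mapping[str, object], path: str | Path) -> Path:
    """Write a key=value report, one entry per line."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in values.items():
            fh.write(f"{key}={value}\n")
    return path


def read_report(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            key, value = line.split("=", 1)
            out[key] = value
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
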