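"""File I/O: NIfTI volumes, capnograph traces and cohort tables."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_capno",
    "load_capno",
    "save_table",
    "load_table",
    "save_json",
]


def _affine(voxel_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])


def save_nifti(path: str | Path, data: np.ndarray,
               voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_mm))
    img.header.set_zooms(tuple(voxel_mm) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.get_fdata()), tuple(float(z) for z in zooms)


def save_capno(path: str | Path, t: np.ndarray, co2: np.ndarray) -> Path:
    """Two-column delimited text: time_s, co2_mmHg."""
    path = Path(path)
    pd.DataFrame({"time_s": t, "co2_mmHg": co2}).to_csv(path, sep="\t", index=False)
    return path


def load_capno(path: str | Path):
    from .capno import CapnoTrace

    df = pd.read_csv(path, sep="\t")
    return CapnoTrace(t=df["time_s"].values, co2=df["co2_mmHg"].values)


def save_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_json(path: str | Path, obj: Any) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path
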