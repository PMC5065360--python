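"""File I/O: NIfTI scalar volumes and masks, cohort CSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "save_map",
    "load_map",
    "save_mask",
    "load_mask",
    "save_cohort",
    "load_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ["subject_id", "label", "ad_min", "md_min", "rd_min"]


def _affine(voxel_size) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_map(volume: np.ndarray, path: str | Path, voxel_size=(1.8, 1.8, 4.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), _affine(voxel_size)), path)
    return path


def load_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_mask(mask: np.ndarray, path: str | Path, voxel_size=(1.8, 1.8, 4.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size)), path)
    return path


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort CSV (diffusivities in 1e-3 mm^2/s)."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[COHORT_COLUMNS].to_csv(path, index=False, float_format="%.6f")
    return path


def load_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} missing columns {missing}")
    if not set(table["label"].unique()) <= {0, 1}:
        raise ValueError("cohort labels must be 0 (stable) or 1 (transformed)")
    return table
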