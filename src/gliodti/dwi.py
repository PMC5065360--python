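"""Container and NIfTI/FSL I/O for 4D diffusion-weighted volumes."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .gradients import GradientScheme, load_bval_bvec, save_bval_bvec

__all__ = ["DWIVolume", "save_dwi", "load_dwi"]


@dataclass
class DWIVolume:
    """A 4D stack of diffusion-weighted signal intensities.

    ``data`` is indexed (x, y, z, measurement); the 4th axis matches the
    gradient scheme entry by entry. Intensities are arbitrary scanner
    units, finite and non-negative.
    """

    data: np.ndarray
    scheme: GradientScheme
    voxel_size: tuple[float, float, float] = (1.8, 1.8, 4.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] != self.scheme.n_measurements:
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) must match the "
                f"{self.scheme.n_measurements} scheme entries"
            )
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("DWI intensities must be finite and >= 0")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_dwi(dwi: DWIVolume, out_dir: str | Path, stem: str = "dwi") -> dict[str, Path]:
    """Write NIfTI (.nii.gz) plus FSL bval/bvec next to it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nifti": out / f"{stem}.nii.gz",
        "bval": out / f"{stem}.bval",
        "bvec": out / f"{stem}.bvec",
    }
    nib.save(nib.Nifti1Image(dwi.data.astype(np.float32), _affine(dwi.voxel_size)), paths["nifti"])
    save_bval_bvec(dwi.scheme, paths["bval"], paths["bvec"])
    return paths


def load_dwi(nifti_path: str | Path, bval_path: str | Path, bvec_path: str | Path) -> DWIVolume:
    img = nib.load(str(nifti_path))
    scheme = load_bval_bvec(bval_path, bvec_path)
    zooms = img.header.get_zooms()[:3]
    return DWIVolume(np.asarray(img.dataobj, dtype=float), scheme, tuple(float(z) for z in zooms))
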