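"""Voxel-wise diffusion tensor estimation and diffusivity maps.

The signal model is the mono-exponential Stejskal–Tanner decay

    S_i = S0 * exp(-b_i * g_i^T D g_i),

with D a symmetric positive semi-definite 3x3 tensor in mm^2/s. Fitting
log-linearizes the model and solves, per voxel, the least-squares system

    ln S_i = ln S0 - b_i g_i^T D g_i

for the 6 unique tensor components plus ln S0. The scalar maps follow
from the descending-sorted eigenvalues l1 >= l2 >= l3:

    AD = l1,   RD = (l2 + l3) / 2,   MD = (l1 + l2 + l3) / 3.

AD (axial diffusivity) measures diffusion along the principal fiber
direction, RD (radial) across it, and MD — identical to the ADC — their
orientation-free average. All internal units are mm^2/s; reporting
layers rescale to the conventional 1e-3 mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TensorField",
    "DiffusivityMaps",
    "fit_tensor",
    "eigendecompose",
    "compute_maps",
    "EIGENVALUE_FLOOR",
]

#: Clamp floor for negative eigenvalues, mm^2/s. Negative eigenvalues are a
#: noise artifact of the unconstrained linear fit; clamping keeps the maps
#: physical while the clamp counter keeps the problem visible.
EIGENVALUE_FLOOR = 1e-12

# index order of the 6 unique components
_COMP = ["xx", "yy", "zz", "xy", "xz", "yz"]


@dataclass
class TensorField:
    """A voxel grid of symmetric diffusion tensors.

    ``tensors`` stores the 6 unique components (Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz) in mm^2/s. ``eigenvalues`` (when populated) are sorted
    descending per voxel. ``valid_mask`` flags voxels whose fit (or
    construction) succeeded; invalid voxels carry NaN downstream.
    """

    tensors: np.ndarray
    s0_est: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    n_clamped: int = 0
    voxel_size: tuple[float, float, float] = (1.8, 1.8, 4.0)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 4 or self.tensors.shape[-1] != 6:
            raise ValueError(f"tensors must be (nx, ny, nz, 6), got {self.tensors.shape}")
        if self.valid_mask is None:
            self.valid_mask = np.all(np.isfinite(self.tensors), axis=-1)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Expand the 6 unique components into full (..., 3, 3) matrices."""
        t = self.tensors
        m = np.empty(t.shape[:-1] + (3, 3), dtype=float)
        m[..., 0, 0] = t[..., 0]
        m[..., 1, 1] = t[..., 1]
        m[..., 2, 2] = t[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = t[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = t[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = t[..., 5]
        return m

    @staticmethod
    def pack_matrices(matrices: np.ndarray) -> np.ndarray:
        m = np.asarray(matrices, dtype=float)
        return np.stack(
            [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2], m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
            axis=-1,
        )


@dataclass
class DiffusivityMaps:
    """Co-registered AD/MD/RD scalar volumes (mm^2/s) from one tensor field.

    Invalid voxels are NaN in all three maps. The maps satisfy
    ad >= md >= rd and md == (ad + 2 rd)/3 at every valid voxel.
    """

    ad: np.ndarray
    md: np.ndarray
    rd: np.ndarray
    valid_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.8, 1.8, 4.0)

    def __getitem__(self, name: str) -> np.ndarray:
        key = name.lower()
        if key not in ("ad", "md", "rd"):
            raise KeyError(f"unknown map {name!r}; expected AD, MD or RD")
        return getattr(self, key)


def design_matrix(scheme) -> np.ndarray:
    """Rows [-b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz, 1]."""
    b = scheme.b_values
    g = scheme.directions
    return np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones_like(b),
        ]
    )


def fit_tensor(dwi, weighted: bool = False) -> TensorField:
    """Fit a diffusion tensor per voxel by log-linear least squares.

    Voxels containing any non-positive signal cannot be log-transformed
    and are flagged invalid instead of fitted. With ``weighted=True`` a
    second pass reweights each measurement by its predicted squared
    signal (WLS), which counters the noise amplification of the log
    transform at low signal; the default is the plain OLS fit.

    Raises
    ------
    ValueError
        If the gradient scheme cannot identify all 7 unknowns
        (rank-deficient design, e.g. collinear directions).
    """
    scheme = dwi.scheme
    scheme.validate()
    B = design_matrix(scheme)
    rank = np.linalg.matrix_rank(B)
    if rank < 7:
        raise ValueError(
            f"gradient scheme is rank-deficient: design matrix rank {rank} < 7 "
            "(directions collinear or too few); tensor not identifiable"
        )

    shape = dwi.grid_shape
    signals = dwi.data.reshape(-1, scheme.n_measurements)
    valid = np.all(signals > 0, axis=1)

    coeffs = np.full((signals.shape[0], 7), np.nan)
    if np.any(valid):
        logs = np.log(signals[valid])
        sol = np.linalg.lstsq(B, logs.T, rcond=None)[0].T  # (nvalid, 7)
        if weighted:
            # WLS with weights = predicted squared signals, one reweighting pass
            pred = (B @ sol.T).T
            w = np.exp(2.0 * pred)
            for i in range(sol.shape[0]):
                Wb = B * w[i][:, None]
                sol[i] = np.linalg.lstsq(B.T @ Wb, (B * w[i][:, None]).T @ logs[i], rcond=None)[0]
        coeffs[valid] = sol

    tensors = coeffs[:, :6].reshape(shape + (6,))
    s0 = np.exp(coeffs[:, 6]).reshape(shape)
    field = TensorField(
        tensors=tensors,
        s0_est=s0,
        valid_mask=valid.reshape(shape),
        voxel_size=dwi.voxel_size,
    )
    return eigendecompose(field)


def eigendecompose(field: TensorField) -> TensorField:
    """Populate descending-sorted eigenvalues, clamping negatives.

    Eigenvalues below :data:`EIGENVALUE_FLOOR` are raised to the floor
    and the affected voxels counted in ``n_clamped``. Voxels with
    non-finite tensor components are flagged invalid.
    """
    finite = np.all(np.isfinite(field.tensors), axis=-1)
    valid = field.valid_mask & finite

    evals = np.full(field.grid_shape + (3,), np.nan)
    if np.any(valid):
        mats = field.as_matrices()[valid]
        ev = np.linalg.eigvalsh(mats)[:, ::-1]  # eigvalsh ascending -> descending
        evals[valid] = ev

    below = evals < EIGENVALUE_FLOOR
    n_clamped = int(np.count_nonzero(np.any(below & valid[..., None], axis=-1)))
    evals = np.where(below, EIGENVALUE_FLOOR, evals)

    field.eigenvalues = evals
    field.valid_mask = valid
    field.n_clamped = n_clamped
    return field


def compute_maps(field: TensorField) -> DiffusivityMaps:
    """Derive the AD/MD/RD scalar volumes from sorted eigenvalues."""
    if field.eigenvalues is None:
        raise ValueError("eigenvalues not populated; run eigendecompose first")
    ev = field.eigenvalues
    ad = ev[..., 0].copy()
    rd = (ev[..., 1] + ev[..., 2]) / 2.0
    md = (ev[..., 0] + ev[..., 1] + ev[..., 2]) / 3.0
    invalid = ~field.valid_mask
    for m in (ad, md, rd):
        m[invalid] = np.nan
    return DiffusivityMaps(ad=ad, md=md, rd=rd, valid_mask=field.valid_mask.copy(),
                           voxel_size=field.voxel_size)
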