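"""Diffusion gradient schemes and FSL-dialect bval/bvec I/O.

A scheme pairs each DWI measurement with a b-value (s/mm^2) and a unit
encoding direction. The default acquisition mirrors a clinical 1.5 T
protocol: one b = 0 reference plus 12 directions at b = 1000 s/mm^2.
The 12-direction set is a fixed electrostatic-repulsion arrangement
(minimum antipodal Coulomb energy on the sphere), shipped as a text
fixture so every run uses bit-identical directions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GradientScheme", "default_scheme", "load_bval_bvec", "save_bval_bvec"]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class GradientScheme:
    """b-values and unit gradient directions, one entry per DWI measurement.

    Directions attached to b = 0 entries are ignored by the signal model
    and are conventionally zero vectors in FSL bvec files; only b > 0
    entries must carry unit vectors.
    """

    b_values: np.ndarray
    directions: np.ndarray
    _skip_validation: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "b_values", np.asarray(self.b_values, dtype=float))
        object.__setattr__(self, "directions", np.asarray(self.directions, dtype=float))
        if self._skip_validation:
            return
        self.validate()

    def validate(self) -> None:
        b, g = self.b_values, self.directions
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise ValueError(
                f"directions must be (n, 3) matching {b.size} b-values, got {g.shape}"
            )
        if np.any(b < 0) or not np.all(np.isfinite(b)) or not np.all(np.isfinite(g)):
            raise ValueError("b-values must be finite and >= 0; directions finite")
        dw = b > 0
        norms = np.linalg.norm(g[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"diffusion-weighted direction {bad} has norm {norms[bad]!r}, "
                f"expected 1 within {_UNIT_TOL}"
            )
        if np.count_nonzero(~dw) < 1:
            raise ValueError("scheme needs at least one b = 0 entry")
        if np.count_nonzero(dw) < 6:
            raise ValueError("tensor estimation needs >= 6 diffusion-weighted entries")

    @property
    def n_measurements(self) -> int:
        return int(self.b_values.size)

    @property
    def dw_mask(self) -> np.ndarray:
        return self.b_values > 0

    def rotated(self, rotation: np.ndarray) -> "GradientScheme":
        """Scheme with all directions rotated by an orthonormal 3x3 matrix."""
        R = np.asarray(rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        return GradientScheme(self.b_values.copy(), self.directions @ R.T)


def _bundled_directions() -> np.ndarray:
    ref = importlib.resources.files("gliodti.data").joinpath("dir12.txt")
    return np.loadtxt(str(ref), comments="#")


def default_scheme(b: float = 1000.0, n_b0: int = 1) -> GradientScheme:
    """One (or more) b = 0 measurement plus the fixed 12-direction shell.

    Parameters
    ----------
    b : diffusion weighting of the shell in s/mm^2 (default 1000).
    n_b0 : number of b = 0 reference measurements (default 1).
    """
    dirs = _bundled_directions()
    b_values = np.concatenate([np.zeros(n_b0), np.full(len(dirs), float(b))])
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(b_values, directions)


def load_bval_bvec(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    """Read an FSL-dialect gradient table.

    bval: one whitespace-separated row of b-values. bvec: three rows
    holding the x, y, z components of each direction.
    """
    b = np.loadtxt(bval_path, ndmin=1)
    g = np.loadtxt(bvec_path, ndmin=2)
    if g.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, got {g.shape[0]}")
    return GradientScheme(b, g.T)


def save_bval_bvec(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.10f")
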