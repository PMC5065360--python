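"""Ground-truth tensor phantoms for the post-resection glioma geometry.

The default phantom emulates the anatomy the follow-up analysis assumes:
a white-matter background, a CSF-filled resection cavity, an adjacent
T2w-hyperintense zone (residual tumor / gliosis), and a focal
recurrence nested inside that zone in which diffusion is restricted.
Region diffusivities default to the cohort group means of the stable
and transformed patients, so the phantom's tumor-to-surround contrast
matches the effect size the biomarker analysis targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .tensor import TensorField, eigendecompose

__all__ = [
    "TensorModel",
    "isotropic",
    "anisotropic",
    "Box",
    "Sphere",
    "Region",
    "PhantomSpec",
    "PhantomVolumes",
    "build_phantom",
    "default_phantom_spec",
    "GROUP_MEANS",
]

REGION_LABELS = ("background_wm", "cavity_csf", "t2_hyperintense", "lesion")

#: Cohort group means of the minimum-diffusivity biomarkers, 1e-3 mm^2/s,
#: used as default region diffusivities (stable -> T2w zone, transformed
#: -> lesion). Keys: (group, parameter).
GROUP_MEANS = {
    ("stable", "ad"): 1.28,
    ("stable", "md"): 1.00,
    ("stable", "rd"): 0.97,
    ("transformed", "ad"): 0.72,
    ("transformed", "md"): 0.64,
    ("transformed", "rd"): 0.56,
}


@dataclass(frozen=True)
class TensorModel:
    """Eigenvalues (mm^2/s, descending) plus the principal eigenvector.

    The tensor is D = R diag(l1, l2, l3) R^T where the first column of R
    is ``principal_direction``; the remaining axes are a deterministic
    orthonormal completion (irrelevant for the axially symmetric models
    used by the default phantoms).
    """

    eigenvalues: tuple[float, float, float]
    principal_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 >= 0):
            raise ValueError(f"eigenvalues must satisfy l1 >= l2 >= l3 >= 0, got {self.eigenvalues}")
        v = np.asarray(self.principal_direction, dtype=float)
        if abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise ValueError(f"principal_direction must be a unit vector, got norm {np.linalg.norm(v)}")

    def matrix(self) -> np.ndarray:
        v1 = np.asarray(self.principal_direction, dtype=float)
        aux = np.array([0.0, 1.0, 0.0]) if abs(v1[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
        v2 = aux - v1 * (aux @ v1)
        v2 /= np.linalg.norm(v2)
        v3 = np.cross(v1, v2)
        R = np.column_stack([v1, v2, v3])
        return R @ np.diag(self.eigenvalues) @ R.T


def isotropic(d: float) -> TensorModel:
    """Isotropic tensor with diffusivity d in mm^2/s."""
    return TensorModel((d, d, d))


def anisotropic(l1: float, l2: float, l3: float,
                principal_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)) -> TensorModel:
    return TensorModel((l1, l2, l3), principal_direction)


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, half-open voxel index ranges [lo, hi)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        sl = tuple(slice(max(l, 0), min(h, n)) for l, h, n in zip(self.lo, self.hi, grid_shape))
        m[sl] = True
        return m


@dataclass(frozen=True)
class Sphere:
    """Sphere in voxel index coordinates."""

    center: tuple[float, float, float]
    radius: float

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=float)
        d2 = sum((idx[k] - self.center[k]) ** 2 for k in range(3))
        return d2 <= self.radius**2


@dataclass(frozen=True)
class Region:
    label: str
    geometry: Box | Sphere
    tensor_model: TensorModel
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}; expected one of {REGION_LABELS}")
        if not self.s0 > 0:
            raise ValueError(f"region {self.label}: s0 must be > 0, got {self.s0}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + tensor model of a synthetic post-resection brain.

    Later regions overwrite earlier ones; every voxel must end up
    assigned, and when both are present the lesion must lie inside the
    T2w-hyperintense zone. ``artifact_voxels`` marks voxels (e.g. blood
    products) to be excluded from minimum-value readout downstream.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size: tuple[float, float, float] = (1.8, 1.8, 4.0)
    regions: tuple[Region, ...] = ()
    artifact_voxels: tuple[tuple[int, int, int], ...] = dc_field(default=())

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not self.regions:
            raise ValueError("at least one region required")


@dataclass
class PhantomVolumes:
    """A built phantom: ground-truth field plus the label/ROI volumes."""

    field: TensorField
    labels: np.ndarray  # per-voxel region index into region_names
    region_names: tuple[str, ...]
    masks: dict[str, np.ndarray]  # final (post-overwrite) mask per region label
    s0: np.ndarray
    exclusion_mask: np.ndarray  # artifact voxels, honored by ROI readout

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.masks["lesion"]

    @property
    def t2w_mask(self) -> np.ndarray:
        return self.masks["t2_hyperintense"]


def build_phantom(spec: PhantomSpec) -> PhantomVolumes:
    """Paint the regions onto the grid and assemble the ground-truth field.

    Raises a geometry error when the lesion extends outside the
    T2w-hyperintense zone (before later regions overwrite either), or
    when some voxel is left unassigned.
    """
    shape = spec.grid_shape
    geo_masks = [r.geometry.mask(shape) for r in spec.regions]

    by_label: dict[str, np.ndarray] = {}
    for r, m in zip(spec.regions, geo_masks):
        by_label[r.label] = by_label.get(r.label, np.zeros(shape, bool)) | m
    if "lesion" in by_label and "t2_hyperintense" in by_label:
        if np.any(by_label["lesion"] & ~by_label["t2_hyperintense"]):
            n_out = int(np.count_nonzero(by_label["lesion"] & ~by_label["t2_hyperintense"]))
            raise ValueError(
                f"geometry error: lesion extends {n_out} voxels outside the t2_hyperintense zone"
            )

    labels = np.full(shape, -1, dtype=int)
    for i, m in enumerate(geo_masks):
        labels[m] = i
    if np.any(labels < 0):
        raise ValueError(
            f"geometry error: {int(np.count_nonzero(labels < 0))} voxels belong to no region"
        )

    tensors = np.empty(shape + (6,), dtype=float)
    s0 = np.empty(shape, dtype=float)
    for i, r in enumerate(spec.regions):
        sel = labels == i
        tensors[sel] = TensorField.pack_matrices(r.tensor_model.matrix())
        s0[sel] = r.s0

    field = TensorField(tensors=tensors, s0_est=s0, voxel_size=spec.voxel_size)
    field = eigendecompose(field)

    masks = {r.label: labels == i for i, r in enumerate(spec.regions)}
    # merge duplicate labels (final ownership after overwrites)
    final_masks: dict[str, np.ndarray] = {}
    for i, r in enumerate(spec.regions):
        final_masks[r.label] = final_masks.get(r.label, np.zeros(shape, bool)) | (labels == i)

    exclusion = np.zeros(shape, dtype=bool)
    for v in spec.artifact_voxels:
        exclusion[tuple(v)] = True

    return PhantomVolumes(
        field=field,
        labels=labels,
        region_names=tuple(r.label for r in spec.regions),
        masks=final_masks,
        s0=s0,
        exclusion_mask=exclusion,
    )


def _scaled(x: float) -> float:
    return x * 1e-3


def default_phantom_spec(style: str = "prolate", snr_artifacts: bool = False) -> PhantomSpec:
    """The reference resection-cavity phantom on a 48 x 48 x 24 grid.

    ``style="prolate"`` (default for pipeline runs) gives the T2w zone
    and lesion axially symmetric tensors whose l1 equals the group-mean
    axial diffusivity and l2 = l3 the group-mean radial diffusivity
    (stable group for the T2w zone, transformed group for the lesion),
    so the AD/MD/RD maps carry distinct contrasts. ``style="isotropic"``
    makes both regions isotropic at the group-mean axial diffusivity,
    which is convenient for exactness checks (every map equals the
    region diffusivity).

    Background is white matter with literature-typical eigenvalues
    (1.7, 0.4, 0.3) x 1e-3 mm^2/s; the cavity is CSF-like isotropic
    3.0e-3 mm^2/s. These two are package defaults, not cohort-derived.
    """
    if style == "prolate":
        t2_model = anisotropic(
            _scaled(GROUP_MEANS[("stable", "ad")]),
            _scaled(GROUP_MEANS[("stable", "rd")]),
            _scaled(GROUP_MEANS[("stable", "rd")]),
            (0.0, 0.0, 1.0),
        )
        lesion_model = anisotropic(
            _scaled(GROUP_MEANS[("transformed", "ad")]),
            _scaled(GROUP_MEANS[("transformed", "rd")]),
            _scaled(GROUP_MEANS[("transformed", "rd")]),
            (0.0, 0.0, 1.0),
        )
    elif style == "isotropic":
        t2_model = isotropic(_scaled(GROUP_MEANS[("stable", "ad")]))
        lesion_model = isotropic(_scaled(GROUP_MEANS[("transformed", "ad")]))
    else:
        raise ValueError(f"unknown phantom style {style!r}")

    regions = (
        Region("background_wm", Box((0, 0, 0), (48, 48, 24)),
               anisotropic(1.7e-3, 0.4e-3, 0.3e-3, (1.0, 0.0, 0.0)), s0=1.0),
        Region("cavity_csf", Sphere((15.0, 24.0, 12.0), 6.0), isotropic(3.0e-3), s0=2.0),
        Region("t2_hyperintense", Sphere((29.0, 24.0, 12.0), 9.0), t2_model, s0=1.5),
        Region("lesion", Sphere((32.0, 24.0, 12.0), 3.5), lesion_model, s0=1.4),
    )
    artifacts = ((36, 24, 12),) if snr_artifacts else ()
    return PhantomSpec(regions=regions, artifact_voxels=artifacts)
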