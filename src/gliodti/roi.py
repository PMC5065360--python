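"""ROI readout, the two-reader CNR statistic, and the signal-drop ratio.

Per ROI the readout reports mean, sample SD, minimum, and the location
of the minimum voxel; the minimum within the tumor ROI is the
per-patient biomarker (AD_min/MD_min/RD_min). NaN voxels (failed fits)
and voxels on an explicit exclusion mask (bleed/susceptibility
artifacts) are dropped before any statistic is computed.

The contrast-to-noise ratio contrasts the tumor ROI against the
surrounding T2w-hyperintense tissue, averaging two readers:

    CNR = [ (D_t2w,r1 + D_t2w,r2)/2 - (D_tum,r1 + D_tum,r2)/2 ] / STD
    STD = (SD_t2w,r1 + SD_t2w,r2)/2 + (SD_tum,r1 + SD_tum,r2)/2

where D is the ROI mean and SD the ROI standard deviation of the map
at hand. The signal-drop ratio expresses a transformed-group mean as a
percentage of the stable-group level, 100 * event / reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ROIStats",
    "CNRResult",
    "extract_roi_stats",
    "perturb_mask",
    "compute_cnr",
    "signal_drop_percent",
]


@dataclass(frozen=True)
class ROIStats:
    """Summary statistics of one scalar map inside one reader's mask.

    ``sd`` is the sample standard deviation (n-1 denominator); ``argmin``
    is the voxel index of the minimum, ties broken toward the smallest
    x-fastest linear index so reruns are bit-identical.
    """

    map_name: str
    roi_name: str
    reader_id: str
    mean: float
    sd: float
    minimum: float
    argmin: tuple[int, int, int]
    n_voxels: int
    n_excluded: int


@dataclass(frozen=True)
class CNRResult:
    map_name: str
    cnr: float
    pooled_sd: float
    inputs: tuple[ROIStats, ROIStats, ROIStats, ROIStats]


def extract_roi_stats(
    scalar_map: np.ndarray,
    mask: np.ndarray,
    reader_id: str = "reader1",
    roi_name: str = "tumor",
    map_name: str = "AD",
    exclusion_mask: np.ndarray | None = None,
) -> ROIStats:
    """Mean/SD/min/argmin of a scalar map over the valid in-mask voxels.

    NaN voxels and voxels on ``exclusion_mask`` are excluded and counted
    in ``n_excluded``. An effectively empty mask raises, naming the ROI.
    """
    m = np.asarray(scalar_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if m.shape != mask.shape:
        raise ValueError(f"map shape {m.shape} != mask shape {mask.shape}")
    eff = mask & np.isfinite(m)
    if exclusion_mask is not None:
        eff &= ~np.asarray(exclusion_mask, dtype=bool)
    n_excluded = int(np.count_nonzero(mask) - np.count_nonzero(eff))
    n_voxels = int(np.count_nonzero(eff))
    if n_voxels == 0:
        raise ValueError(f"ROI {roi_name!r} ({reader_id}): no valid voxels after exclusions")

    vals_f = m.ravel(order="F")
    eff_f = eff.ravel(order="F")
    in_vals = vals_f[eff_f]
    mean = float(np.mean(in_vals))
    sd = float(np.std(in_vals, ddof=1)) if n_voxels > 1 else 0.0
    minimum = float(np.min(in_vals))
    # smallest x-fastest linear index among tied minima
    lin = np.flatnonzero(eff_f & (vals_f == minimum))[0]
    argmin = tuple(int(i) for i in np.unravel_index(lin, m.shape, order="F"))
    return ROIStats(
        map_name=map_name,
        roi_name=roi_name,
        reader_id=reader_id,
        mean=mean,
        sd=sd,
        minimum=minimum,
        argmin=argmin,
        n_voxels=n_voxels,
        n_excluded=n_excluded,
    )


def perturb_mask(mask: np.ndarray, seed: int, flip_prob: float = 0.3) -> np.ndarray:
    """Emulate an independent second reader's ROI.

    Boundary voxels of the reference mask are randomly toggled: each
    voxel of the one-voxel outer shell is added and each voxel of the
    inner shell removed with probability ``flip_prob``. The result is
    guaranteed non-empty and deterministic under the seed.
    """
    mask = np.asarray(mask, dtype=bool)
    if not 0 <= flip_prob <= 1:
        raise ValueError("flip_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    outer = ndimage.binary_dilation(mask) & ~mask
    inner = mask & ~ndimage.binary_erosion(mask)
    out = mask.copy()
    out[outer] = rng.random(int(outer.sum())) < flip_prob
    remove = rng.random(int(inner.sum())) < flip_prob
    idx = np.argwhere(inner)
    out[tuple(idx[remove].T)] = False
    if not out.any():  # degenerate tiny ROI: fall back to the reference
        out = mask.copy()
    return out


def compute_cnr(
    t2w_r1: ROIStats, t2w_r2: ROIStats, tumor_r1: ROIStats, tumor_r2: ROIStats
) -> CNRResult:
    """Two-reader tumor-vs-T2w contrast-to-noise ratio for one map."""
    four = (t2w_r1, t2w_r2, tumor_r1, tumor_r2)
    names = {s.map_name for s in four}
    if len(names) != 1:
        raise ValueError(f"all four ROI stats must share a map, got {sorted(names)}")
    for s, role in zip(four, ("t2w", "t2w", "tumor", "tumor")):
        if s.roi_name != role:
            raise ValueError(f"expected roi_name {role!r} in position, got {s.roi_name!r}")
    std = (t2w_r1.sd + t2w_r2.sd) / 2.0 + (tumor_r1.sd + tumor_r2.sd) / 2.0
    if std == 0:
        raise ZeroDivisionError(
            f"CNR undefined for map {t2w_r1.map_name}: all four ROI SDs are zero"
        )
    numer = (t2w_r1.mean + t2w_r2.mean) / 2.0 - (tumor_r1.mean + tumor_r2.mean) / 2.0
    return CNRResult(map_name=t2w_r1.map_name, cnr=numer / std, pooled_sd=std, inputs=four)


def signal_drop_percent(group_mean_event: float, group_mean_reference: float) -> tuple[float, float]:
    """Event-group biomarker as a percentage of the reference-group level.

    Returns ``(rounded, exact)`` — the one-decimal percentage used in
    reports alongside the unrounded value.
    """
    if not group_mean_reference > 0:
        raise ValueError(f"reference mean must be > 0, got {group_mean_reference}")
    exact = 100.0 * group_mean_event / group_mean_reference
    return round(exact, 1), exact
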