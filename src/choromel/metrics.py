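"""En-face maps: choroidal thickness, melanin-tissue thickness, occupancy.

Per A-line,

* choroidal thickness = (z_out − z_in) · Δz,
* thickness of MeCh   = (# voxels low-DOPU ∧ stroma ∧ choroid) · Δz,
* occupancy rate      = that count ÷ (# stroma voxels).

An A-line without a segmented choroid is invalid in every map; an A-line
with zero stroma voxels is additionally invalid in the occupancy map.
Region aggregates of occupancy use total counts (sum of qualifying voxels
over the region divided by the sum of stroma voxels), not a mean of
per-A-line ratios; a flag switches to the latter.
"""

from __future__ import annotations

import numpy as np

from .segmentation import ChoroidBoundaries, choroid_mask
from .volumes import EnFaceMap

__all__ = [
    "choroidal_thickness_map",
    "mech_thickness_map",
    "occupancy_map",
    "count_maps",
    "region_occupancy",
]


def choroidal_thickness_map(
    boundaries: ChoroidBoundaries, dz: float | None = None, pitch=(1.0, 1.0)
) -> EnFaceMap:
    """Choroid thickness (μm) per A-line from the segmented surfaces."""
    dz = boundaries.dz if dz is None else dz
    valid = boundaries.valid
    vals = np.where(valid, (boundaries.z_out - boundaries.z_in) * dz, 0.0)
    return EnFaceMap(vals, valid, "choroidal_thickness_um", tuple(pitch))


def count_maps(
    low_dopu: np.ndarray,
    stroma: np.ndarray,
    boundaries: ChoroidBoundaries,
    inner_guard_px: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-A-line counts of (low-DOPU ∧ stroma ∧ choroid) and stroma voxels.

    ``inner_guard_px`` excludes that many rows below the inner boundary
    from both counts: a DOPU kernel centred there straddles the
    depolarizing RPE band above the choroid, so its low-DOPU reading does
    not reflect stromal melanin. The default guard equals zero; pipelines
    should pass the kernel's axial half-width.
    """
    if low_dopu.shape != stroma.shape:
        raise ValueError("masks must share one grid")
    cmask = choroid_mask(boundaries, low_dopu.shape[0])
    if inner_guard_px > 0:
        zz = np.arange(low_dopu.shape[0], dtype=np.float64)[:, None, None]
        with np.errstate(invalid="ignore"):
            cmask &= zz >= (boundaries.z_in[None] + inner_guard_px)
    s = stroma & cmask
    return (low_dopu & s).sum(axis=0), s.sum(axis=0)


def mech_thickness_map(
    low_dopu: np.ndarray,
    stroma: np.ndarray,
    boundaries: ChoroidBoundaries,
    dz: float | None = None,
    pitch=(1.0, 1.0),
    inner_guard_px: int = 0,
) -> EnFaceMap:
    """Thickness of melanin-containing tissue in the choroid (μm) per A-line."""
    dz = boundaries.dz if dz is None else dz
    low_cnt, _ = count_maps(low_dopu, stroma, boundaries, inner_guard_px)
    valid = boundaries.valid
    return EnFaceMap(np.where(valid, low_cnt * dz, 0.0), valid, "mech_thickness_um", tuple(pitch))


def occupancy_map(
    low_dopu: np.ndarray,
    stroma: np.ndarray,
    boundaries: ChoroidBoundaries,
    pitch=(1.0, 1.0),
    inner_guard_px: int = 0,
) -> EnFaceMap:
    """Choroidal melanin occupancy rate per A-line (low-DOPU ÷ stroma voxels)."""
    low_cnt, s_cnt = count_maps(low_dopu, stroma, boundaries, inner_guard_px)
    valid = boundaries.valid & (s_cnt > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(valid, low_cnt / np.maximum(s_cnt, 1), 0.0)
    return EnFaceMap(vals, valid, "occupancy", tuple(pitch))


def region_occupancy(
    low_counts: np.ndarray,
    stroma_counts: np.ndarray,
    region: np.ndarray,
    valid: np.ndarray | None = None,
    mean_of_ratios: bool = False,
) -> float:
    """Occupancy of a 2-D region, aggregate-of-counts by default.

    ``low_counts``/``stroma_counts`` are per-A-line voxel counts; ``region``
    is a boolean en-face mask. A-lines with zero stroma are excluded from
    numerator and denominator (no imputation).
    """
    sel = region & (stroma_counts > 0)
    if valid is not None:
        sel &= valid
    if not sel.any():
        return float("nan")
    if mean_of_ratios:
        return float(np.mean(low_counts[sel] / stroma_counts[sel]))
    return float(low_counts[sel].sum() / stroma_counts[sel].sum())
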