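"""Fovea-centered sector grid and per-sector statistics.

The 6 × 6 mm en-face field is divided by two circles centred on the fovea
(diameters 2 and 5 mm): the *whole* area is the 5-mm disc, the *center*
area the 2-mm disc, and the *outer ring* the annulus between them. The
outer ring is split evenly into superior, inferior, nasal and temporal
quadrants by the ±45° diagonals through the fovea (an ETDRS-style X-cut).

Transverse magnification depends on the eye's axial length; pixel pitch is
rescaled by the ratio of Bennett–Littman ocular magnification factors
q(AL) = 0.01306·(AL − 1.82) relative to a reference axial length, and the
circle radii are applied on the calibrated grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import region_occupancy
from .volumes import EnFaceMap

__all__ = [
    "SECTOR_ORDER",
    "SectorMasks",
    "transverse_scale",
    "make_sector_masks",
    "sector_means",
]

SECTOR_ORDER = ("whole", "center", "superior", "inferior", "nasal", "temporal", "outer_ring")

#: Bennett–Littman q-factor constants (AL in mm)
_Q_SLOPE = 0.01306
_Q_OFFSET = 1.82


def transverse_scale(
    axial_length_mm: float, nominal_pitch_um: float, al_ref_mm: float = 24.2
) -> float:
    """Calibrated transverse pixel pitch (μm/px) for a given axial length.

    pitch = nominal · q(AL)/q(AL_ref), with q(AL) = 0.01306·(AL − 1.82).
    """
    if not (15.0 <= axial_length_mm <= 35.0):
        raise ValueError(f"axial length {axial_length_mm} mm outside the plausible range [15, 35]")
    q = _Q_SLOPE * (axial_length_mm - _Q_OFFSET)
    q_ref = _Q_SLOPE * (al_ref_mm - _Q_OFFSET)
    return nominal_pitch_um * q / q_ref


@dataclass
class SectorMasks:
    """Boolean en-face masks for the seven sectors, on the (x, y) grid."""

    masks: dict[str, np.ndarray]
    fovea_px: tuple[float, float]
    pitch: tuple[float, float]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __iter__(self):
        return iter(SECTOR_ORDER)


def make_sector_masks(
    dims: tuple[int, int],
    fovea_px: tuple[float, float],
    pitch: tuple[float, float],
    nasal_side: str = "image_left",
    inner_diameter_mm: float = 2.0,
    outer_diameter_mm: float = 5.0,
) -> SectorMasks:
    """Build the seven sector masks on an (n_x, n_y) grid.

    ``pitch`` is the calibrated (x, y) pixel pitch in μm/px. ``nasal_side``
    maps anatomy onto the image: ``"image_left"`` means nasal is toward
    x = 0. Superior is toward y = 0. A pixel belongs to a disc when its
    centre lies within the radius; pixels exactly on a ±45° diagonal are
    assigned to the clockwise-following quadrant (superior→right→
    inferior→left in image coordinates).
    """
    if nasal_side not in ("image_left", "image_right"):
        raise ValueError("nasal_side must be 'image_left' or 'image_right'")
    if not inner_diameter_mm < outer_diameter_mm:
        raise ValueError("inner circle diameter must be smaller than the outer")
    n_x, n_y = dims
    px, py = pitch
    dx_um = (np.arange(n_x) - fovea_px[0])[:, None] * px
    dy_um = (np.arange(n_y) - fovea_px[1])[None, :] * py

    r_out = outer_diameter_mm * 1000.0 / 2.0
    r_in = inner_diameter_mm * 1000.0 / 2.0
    for sign, lim, axis in ((-1, fovea_px[0] * px, "x-"), (1, (n_x - 1 - fovea_px[0]) * px, "x+"),
                            (-1, fovea_px[1] * py, "y-"), (1, (n_y - 1 - fovea_px[1]) * py, "y+")):
        if lim < r_out:
            raise ValueError(
                f"outer {outer_diameter_mm} mm circle exceeds the field on the {axis} side "
                f"by {(r_out - lim) / 1000.0:.3f} mm"
            )

    r2 = dx_um**2 + dy_um**2
    whole = r2 <= r_out**2
    center = r2 <= r_in**2
    ring = whole & ~center

    ax, ay = np.abs(dx_um), np.abs(dy_um)
    up = dy_um < 0
    right = dx_um > 0
    # strict quadrants, then the documented clockwise tie rule on diagonals
    superior = (ay > ax) & up
    inferior = (ay > ax) & ~up
    q_right = (ax > ay) & right
    q_left = (ax > ay) & ~right
    tie = (ax == ay) & (r2 > 0)
    superior |= tie & ~right & up  # left-upper diagonal → superior
    q_right |= tie & right & up  # right-upper diagonal → right quadrant
    inferior |= tie & right & ~up  # right-lower diagonal → inferior
    q_left |= tie & ~right & ~up  # left-lower diagonal → left quadrant

    nasal, temporal = (q_left, q_right) if nasal_side == "image_left" else (q_right, q_left)
    masks = {
        "whole": whole,
        "center": center,
        "outer_ring": ring,
        "superior": superior & ring,
        "inferior": inferior & ring,
        "nasal": nasal & ring,
        "temporal": temporal & ring,
    }
    return SectorMasks(masks=masks, fovea_px=tuple(fovea_px), pitch=(px, py))


def sector_means(
    maps: dict[str, EnFaceMap],
    masks: SectorMasks,
    low_counts: np.ndarray | None = None,
    stroma_counts: np.ndarray | None = None,
    occupancy_mean_of_ratios: bool = False,
) -> pd.DataFrame:
    """Per-sector means of the three en-face maps.

    Thickness maps are averaged over valid pixels; occupancy uses the
    aggregate-of-counts rule when ``low_counts``/``stroma_counts`` are
    supplied, otherwise the mean of per-A-line ratios. Sectors without any
    valid pixel get NaN.
    """
    rows = []
    for name in SECTOR_ORDER:
        sector = masks[name]
        row: dict[str, object] = {"sector": name}
        n_valid = 0
        for role in ("choroidal_thickness_um", "mech_thickness_um"):
            m = maps.get(role)
            if m is None:
                row[f"mean_{role}"] = np.nan
                continue
            sel = sector & m.valid
            row[f"mean_{role}"] = float(m.values[sel].mean()) if sel.any() else np.nan
            n_valid = max(n_valid, int(sel.sum()))
        occ = maps.get("occupancy")
        if occ is not None:
            if low_counts is not None and stroma_counts is not None and not occupancy_mean_of_ratios:
                row["mean_occupancy"] = region_occupancy(
                    low_counts, stroma_counts, sector, valid=occ.valid
                )
            else:
                sel = sector & occ.valid
                row["mean_occupancy"] = float(occ.values[sel].mean()) if sel.any() else np.nan
            n_valid = max(n_valid, int((sector & occ.valid).sum()))
        else:
            row["mean_occupancy"] = np.nan
        row["n_valid_px"] = n_valid
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "sector",
            "mean_choroidal_thickness_um",
            "mean_mech_thickness_um",
            "mean_occupancy",
            "n_valid_px",
        ],
    )
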