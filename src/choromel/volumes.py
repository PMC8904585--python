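"""Voxel-level data containers shared across the pipeline.

Axis convention (fixed throughout the package): volumes are indexed
``[z, x, y]`` where ``z`` is depth (increasing into the tissue), ``x`` is
the A-line index within a B-scan (fast scan axis) and ``y`` is the B-scan
index (slow scan axis). En-face arrays are indexed ``[x, y]``.
All physical spacings are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["JonesVolume", "StokesVolume", "DOPUVolume", "EnFaceMap"]


@dataclass
class JonesVolume:
    """Polarization-resolved tomogram: two complex detection channels per voxel.

    Parameters
    ----------
    h, v
        Complex backscattered field in the horizontal / vertical detection
        channel, shape ``(n_z, n_x, n_y)``.
    dz, dx, dy
        Voxel pitch in micrometres along depth, A-line and B-scan axes.
    axial_length_mm
        Axial length of the imaged eye (used for transverse magnification
        calibration downstream).
    laterality
        ``"right"`` or ``"left"``.
    fovea_px
        ``(x, y)`` pixel coordinate of the foveal centre. Defaults to the
        grid centre.
    """

    h: np.ndarray
    v: np.ndarray
    dz: float
    dx: float
    dy: float
    axial_length_mm: float = 24.2
    laterality: str = "right"
    fovea_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h)
        self.v = np.asarray(self.v)
        if self.h.shape != self.v.shape or self.h.ndim != 3:
            raise ValueError("channel arrays must share a 3-D (z, x, y) shape")
        if not (self.dz > 0 and self.dx > 0 and self.dy > 0):
            raise ValueError("voxel spacings must be positive")
        if self.laterality not in ("right", "left"):
            raise ValueError(f"laterality must be 'right' or 'left', got {self.laterality!r}")
        for name, arr in (("H", self.h), ("V", self.v)):
            finite = np.isfinite(arr)
            if not finite.all():
                bad = np.argwhere(~finite)[0]
                raise ValueError(f"non-finite value in channel {name} at voxel (z,x,y)={tuple(bad)}")
        if self.fovea_px is None:
            self.fovea_px = ((self.n_x - 1) / 2.0, (self.n_y - 1) / 2.0)

    @property
    def n_z(self) -> int:
        return self.h.shape[0]

    @property
    def n_x(self) -> int:
        return self.h.shape[1]

    @property
    def n_y(self) -> int:
        return self.h.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.h.shape


@dataclass
class StokesVolume:
    """Per-voxel Stokes parameters I, Q, U, V on the acquisition grid."""

    i: np.ndarray
    q: np.ndarray
    u: np.ndarray
    v: np.ndarray
    dz: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.i, self.q, self.u, self.v)}
        if len(shapes) != 1:
            raise ValueError("Stokes components must share one shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.i.shape


@dataclass
class DOPUVolume:
    """Degree of polarization uniformity per voxel, with validity flags.

    ``dopu`` lies in [0, 1] wherever ``valid`` is True; invalid voxels
    (kernel-mean intensity at or below the noise floor) are excluded from
    every downstream count.
    """

    dopu: np.ndarray
    valid: np.ndarray
    dz: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dopu.shape != self.valid.shape:
            raise ValueError("dopu and valid must share one shape")
        vals = self.dopu[self.valid]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("valid DOPU values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dopu.shape


@dataclass
class EnFaceMap:
    """A 2-D en-face map over the (x, y) raster.

    ``role`` is one of ``"choroidal_thickness_um"``, ``"mech_thickness_um"``
    or ``"occupancy"``; ``pitch`` is the calibrated transverse pixel pitch
    (μm/px) along (x, y).
    """

    values: np.ndarray
    valid: np.ndarray
    role: str
    pitch: tuple[float, float] = field(default=(1.0, 1.0))

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape or self.values.ndim != 2:
            raise ValueError("values and valid must share one 2-D shape")
        vals = self.values[self.valid]
        if vals.size:
            if self.role.endswith("_um") and vals.min() < 0:
                raise ValueError("thickness values must be non-negative")
            if self.role == "occupancy" and (vals.min() < 0 or vals.max() > 1):
                raise ValueError("occupancy values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
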