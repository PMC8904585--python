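"""Stokes vectors and the noise-corrected degree of polarization uniformity.

The DOPU of a voxel is the norm of the kernel-averaged Stokes vector
divided by the kernel-averaged intensity,

    DOPU = sqrt(Q̄² + Ū² + V̄²) / Ī,

computed over a small kernel within each B-scan. Additive detector noise
biases Ī upward and Q̄ toward (n_H − n_V); the noise correction subtracts
those biases before averaging:

    I_c = I − (n_H + n_V),   Q_c = Q − (n_H − n_V),

while U and V are unbiased under circular complex noise and are left
unchanged. DOPU is 1 where the polarization state is spatially uniform and
drops toward 0 where scatterers (melanin) randomize it.

Stokes sign convention (fixed; any consistent choice leaves DOPU invariant):

    I = |H|² + |V|²,  Q = |H|² − |V|²,  U = 2·Re(H·V*),  V = −2·Im(H·V*).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volumes import DOPUVolume, JonesVolume, StokesVolume

__all__ = [
    "DOPUKernel",
    "NoiseEstimate",
    "jones_to_stokes",
    "estimate_noise",
    "compute_dopu",
    "binarize_dopu",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DOPUKernel:
    """Averaging kernel for DOPU, 2-D within a B-scan (axial × lateral).

    Default half-widths of 1 give a 3 × 3 pixel kernel; with the default
    acquisition pitch (≈4.3 μm axial, ≈11.7 μm lateral) that is ≈13 μm
    axially and ≈35 μm laterally. No averaging across B-scans.
    """

    half_axial: int = 1
    half_lateral: int = 1

    def __post_init__(self) -> None:
        if self.half_axial < 0 or self.half_lateral < 0:
            raise ValueError("kernel half-widths must be >= 0")

    @property
    def size(self) -> tuple[int, int]:
        """(axial, lateral) extent in pixels; always odd."""
        return (2 * self.half_axial + 1, 2 * self.half_lateral + 1)

    def extent_um(self, dz: float, dx: float) -> tuple[float, float]:
        """Physical (axial, lateral) footprint in micrometres."""
        return (self.size[0] * dz, self.size[1] * dx)


@dataclass(frozen=True)
class NoiseEstimate:
    """Mean additive noise power per detection channel."""

    n_h: float
    n_v: float

    def __post_init__(self) -> None:
        if self.n_h < 0 or self.n_v < 0:
            raise ValueError("noise powers must be non-negative")

    @property
    def total(self) -> float:
        return self.n_h + self.n_v


def jones_to_stokes(jones: JonesVolume) -> StokesVolume:
    """Convert the two complex detection channels to Stokes parameters."""
    h, v = jones.h, jones.v
    ah2 = (h.real * h.real + h.imag * h.imag)
    av2 = (v.real * v.real + v.imag * v.imag)
    hv = h * np.conj(v)
    return StokesVolume(
        i=ah2 + av2,
        q=ah2 - av2,
        u=2.0 * hv.real,
        v=-2.0 * hv.imag,
        dz=jones.dz,
        dx=jones.dx,
        dy=jones.dy,
    )


def vitreous_region(jones: JonesVolume, n_rows: int = 30) -> tuple[slice, slice, slice]:
    """Index set of the top ``n_rows`` depth rows (vitreous, signal-free)."""
    return (slice(0, n_rows), slice(None), slice(None))


def estimate_noise(
    jones: JonesVolume,
    region: tuple[slice, slice, slice] | np.ndarray | None = None,
    min_voxels: int = 100,
) -> NoiseEstimate:
    """Estimate per-channel noise power from a signal-free region.

    ``region`` is either an index expression (tuple of slices) or a boolean
    mask on the volume grid; by default the top 30 depth rows are used.
    """
    if region is None:
        region = vitreous_region(jones)
    h = jones.h[region]
    v = jones.v[region]
    if h.size < min_voxels:
        raise ValueError(f"noise region has {h.size} voxels; need >= {min_voxels}")
    return NoiseEstimate(float(np.mean(np.abs(h) ** 2)), float(np.mean(np.abs(v) ** 2)))


def _kernel_mean(arr: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Truncated kernel mean over (z, x) within each B-scan.

    Border kernels average over the voxels actually available (no padding
    values are invented).
    """
    kz, kx = size
    num = ndi.uniform_filter(arr, size=(kz, kx, 1), mode="constant", cval=0.0)
    ones = np.ones(arr.shape[:2] + (1,), dtype=arr.dtype)
    den = ndi.uniform_filter(ones, size=(kz, kx, 1), mode="constant", cval=0.0)
    return num / den


def compute_dopu(
    stokes: StokesVolume,
    kernel: DOPUKernel | None = None,
    noise: NoiseEstimate | None = None,
    eps_valid: float = 2.0,
) -> DOPUVolume:
    """Noise-corrected DOPU by unweighted Stokes averaging over the kernel.

    Voxels whose kernel-mean corrected intensity is at or below
    ``eps_valid × (n_H + n_V)`` (or ≤ 0 when the noise estimate is zero)
    are flagged invalid. Valid values are clamped to [0, 1]: the noise
    correction can overshoot slightly above 1.
    """
    kernel = kernel or DOPUKernel()
    noise = noise or NoiseEstimate(0.0, 0.0)
    kz, kx = kernel.size
    n_z, n_x = stokes.shape[:2]
    if kz > n_z or kx > n_x:
        raise ValueError(f"kernel {kz}x{kx} larger than B-scan {n_z}x{n_x}")

    i_c = stokes.i - noise.total
    q_c = stokes.q - (noise.n_h - noise.n_v)
    i_bar = _kernel_mean(i_c, (kz, kx))
    q_bar = _kernel_mean(q_c, (kz, kx))
    u_bar = _kernel_mean(stokes.u, (kz, kx))
    v_bar = _kernel_mean(stokes.v, (kz, kx))

    floor = eps_valid * noise.total
    valid = i_bar > max(floor, 0.0)
    norm = np.sqrt(q_bar * q_bar + u_bar * u_bar + v_bar * v_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        dopu = norm / i_bar
    dopu = np.where(valid, dopu, 0.0)
    dopu = np.clip(dopu, 0.0, 1.0)
    return DOPUVolume(dopu=dopu, valid=valid, dz=stokes.dz, dx=stokes.dx, dy=stokes.dy)


def binarize_dopu(dopu: DOPUVolume, threshold: float = 0.8) -> np.ndarray:
    """Low-DOPU mask: valid voxels with DOPU strictly below ``threshold``.

    The strict inequality matters at the boundary: DOPU exactly equal to
    the threshold is *not* low.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    return dopu.valid & (dopu.dopu < threshold)
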