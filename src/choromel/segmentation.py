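"""Choroid delineation and vessel/stroma binarization.

Two routes produce choroid boundaries: a bundled intensity heuristic
(`segment_choroid`) and an import path for externally computed surfaces
(`import_boundaries`). The commercial segmenter the measurement protocol
relies on is proprietary, so all quantitative work that needs exact
boundaries should use the import path; the heuristic is a documented,
testable substitute.

Within the choroid, bright pixels are interstitial stroma and dark pixels
are vessel lumina (flowing blood backscatters weakly in structural OCT).
The split uses a local Otsu threshold per pixel followed by binary median
filtering. Plain Otsu always cuts a window's histogram somewhere near its
middle, even when the window holds a single tissue class, so a bimodality
guard is applied by default: windows whose best between-class/total
variance ratio falls below ``min_separation`` are treated as single-class
(stroma, or vessel when the window mean sits below ``dark_floor_db``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "ChoroidBoundaries",
    "SegmentationError",
    "SegmentationParams",
    "segment_choroid",
    "import_boundaries",
    "export_boundaries",
    "otsu_threshold",
    "binarize_stroma",
    "choroid_mask",
]

log = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    """Raised when a volume cannot be segmented (too many failed A-lines)."""


@dataclass
class ChoroidBoundaries:
    """Inner/outer choroid surface depth per A-line, in pixels.

    ``z_in``/``z_out`` are float arrays of shape ``(n_x, n_y)``; NaN marks
    an unsegmented A-line. A voxel at depth index ``z`` belongs to the
    choroid iff ``z_in <= z < z_out``.
    """

    z_in: np.ndarray
    z_out: np.ndarray
    dz: float = 1.0

    def __post_init__(self) -> None:
        self.z_in = np.asarray(self.z_in, dtype=np.float64)
        self.z_out = np.asarray(self.z_out, dtype=np.float64)
        if self.z_in.shape != self.z_out.shape or self.z_in.ndim != 2:
            raise ValueError("z_in and z_out must share one 2-D (x, y) shape")
        both = np.isfinite(self.z_in) & np.isfinite(self.z_out)
        bad = both & ((self.z_in > self.z_out) | (self.z_in < 0))
        if bad.any():
            x, y = np.argwhere(bad)[0]
            raise ValueError(
                f"crossing or negative surfaces at A-line (x={x}, y={y}): "
                f"z_in={self.z_in[x, y]}, z_out={self.z_out[x, y]}"
            )
        # an A-line is unsegmented unless both surfaces are finite
        half = np.isfinite(self.z_in) ^ np.isfinite(self.z_out)
        if half.any():
            self.z_in[half] = np.nan
            self.z_out[half] = np.nan

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.z_in) & np.isfinite(self.z_out)

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_in.shape

    def thickness_um(self) -> np.ndarray:
        return (self.z_out - self.z_in) * self.dz


def choroid_mask(boundaries: ChoroidBoundaries, n_z: int) -> np.ndarray:
    """Boolean (n_z, n_x, n_y) volume of choroid voxels."""
    zz = np.arange(n_z, dtype=np.float64)[:, None, None]
    with np.errstate(invalid="ignore"):
        m = (zz >= boundaries.z_in[None]) & (zz < boundaries.z_out[None])
    return m & boundaries.valid[None]


# ---------------------------------------------------------------------------
# boundary import / export


def import_boundaries(path, shape: tuple[int, int], dz: float = 1.0) -> ChoroidBoundaries:
    """Read boundaries from CSV (columns x_px, y_px, z_inner_px, z_outer_px).

    Indices are 0-based; A-lines absent from the file are flagged
    unsegmented. Crossing surfaces are rejected with their coordinates.
    """
    df = pd.read_csv(path, comment="#")
    required = {"x_px", "y_px", "z_inner_px", "z_outer_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"boundary CSV must have columns {sorted(required)}")
    n_x, n_y = shape
    z_in = np.full(shape, np.nan)
    z_out = np.full(shape, np.nan)
    xs = df["x_px"].to_numpy(dtype=int)
    ys = df["y_px"].to_numpy(dtype=int)
    if (xs < 0).any() or (xs >= n_x).any() or (ys < 0).any() or (ys >= n_y).any():
        raise ValueError("boundary CSV indices fall outside the grid")
    z_in[xs, ys] = df["z_inner_px"].to_numpy(dtype=float)
    z_out[xs, ys] = df["z_outer_px"].to_numpy(dtype=float)
    missing = int(np.isnan(z_in).sum())
    if missing:
        log.warning("boundary file missing %d A-lines; flagged unsegmented", missing)
    return ChoroidBoundaries(z_in, z_out, dz=dz)


def export_boundaries(boundaries: ChoroidBoundaries, path) -> None:
    """Write valid A-lines of a boundary set to the CSV interchange format."""
    xs, ys = np.nonzero(boundaries.valid)
    pd.DataFrame(
        {
            "x_px": xs,
            "y_px": ys,
            "z_inner_px": boundaries.z_in[xs, ys],
            "z_outer_px": boundaries.z_out[xs, ys],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# heuristic choroid segmentation


@dataclass
class SegmentationParams:
    """Tunables of the bundled choroid heuristic (all in pixels / dB).

    The inner boundary sits ``inner_offset_px`` below the brightest thin
    band of the A-line (the RPE/Bruch's complex); the outer boundary is the
    deepest depth at which the smoothed intensity stays within
    ``outer_drop_db`` of the local choroid median for ``run_px``
    consecutive pixels.
    """

    lateral_smooth_px: int = 7
    axial_smooth_px: int = 3
    inner_offset_px: int = 2
    choroid_probe_px: int = 40
    outer_drop_db: float = 2.0
    run_px: int = 8
    min_thickness_px: int = 4
    min_peak_db: float = 8.0
    surface_median_px: int = 5
    max_unsegmented_frac: float = 0.2


def segment_choroid(
    intensity_db: np.ndarray,
    params: SegmentationParams | None = None,
    dz: float = 1.0,
) -> ChoroidBoundaries:
    """Heuristic choroid delineation on a log-scaled intensity volume.

    Raises :class:`SegmentationError` when more than
    ``params.max_unsegmented_frac`` of the A-lines fail.
    """
    p = params or SegmentationParams()
    vol = np.asarray(intensity_db, dtype=np.float32)
    if not np.isfinite(vol).all():
        raise ValueError("intensity volume must be finite (log-scaled)")
    n_z, n_x, n_y = vol.shape
    img = ndi.uniform_filter(vol, size=(p.axial_smooth_px, p.lateral_smooth_px, 1))

    peak = img.max(axis=0)
    peak_z = img.argmax(axis=0)
    floor = float(np.percentile(vol, 10.0))  # noise-floor proxy (vitreous-dominated)
    unseg = peak < floor + p.min_peak_db

    z_in = peak_z.astype(np.float64) + p.inner_offset_px
    z_out = np.full((n_x, n_y), np.nan)

    zz = np.arange(n_z)[:, None]
    for y in range(n_y):
        b = img[:, :, y]  # (n_z, n_x)
        zi = np.clip(z_in[:, y].astype(int), 0, n_z - 1)
        # B-scan-level choroid median over a probe window below the inner
        # boundary: robust to the dark vessel lumina of individual A-lines
        probe = (zz >= zi[None, :]) & (zz < zi[None, :] + p.choroid_probe_px)
        pv = b[probe]
        bright = pv[pv > floor + 6.0]  # ignore vessel-lumen pixels
        med = float(np.median(bright if bright.size else pv))
        above = b >= (med - p.outer_drop_db)
        c = np.cumsum(above, axis=0)
        run = np.zeros_like(above)
        run[p.run_px - 1 :] = (c[p.run_px - 1 :] - np.concatenate(
            [np.zeros((1, n_x), dtype=int), c[: -p.run_px]], axis=0
        )) == p.run_px
        # deepest run of `run_px` bright pixels ending at or below the inner boundary
        run[zz < (zi[None, :] + p.min_thickness_px)] = False
        has = run.any(axis=0)
        deepest = n_z - 1 - np.argmax(run[::-1], axis=0)
        z_out[:, y] = np.where(has, deepest + 1.0, np.nan)

    unseg |= ~np.isfinite(z_out)
    frac = float(unseg.mean())
    if frac > p.max_unsegmented_frac:
        raise SegmentationError(
            f"{frac:.0%} of A-lines unsegmented (limit {p.max_unsegmented_frac:.0%}); "
            "volume unusable"
        )

    z_in, z_out = _smooth_surfaces(z_in, z_out, unseg, p.surface_median_px)
    z_in[unseg] = np.nan
    z_out[unseg] = np.nan
    return ChoroidBoundaries(z_in, z_out, dz=dz)


def _smooth_surfaces(z_in, z_out, unseg, size):
    """Lateral median smoothing; unsegmented A-lines filled from nearest first."""
    if unseg.any() and not unseg.all():
        idx = ndi.distance_transform_edt(unseg, return_distances=False, return_indices=True)
        z_in = z_in[tuple(idx)]
        z_out = z_out[tuple(idx)]
    z_in = ndi.median_filter(z_in, size=size, mode="nearest")
    z_out = ndi.median_filter(z_out, size=size, mode="nearest")
    z_out = np.maximum(z_out, z_in)
    return z_in, z_out


# ---------------------------------------------------------------------------
# Otsu core


def otsu_threshold(hist: np.ndarray, bin_values: np.ndarray | None = None) -> float:
    """Between-class-variance-maximizing threshold of a 1-D histogram.

    Classes are ``value < t`` vs ``value >= t``; the returned ``t`` is the
    value of the first bin of the upper class. Ties are broken toward the
    lower threshold. A histogram with fewer than two occupied bins has no
    class separation and is rejected.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("hist must be a 1-D array with >= 2 bins")
    if bin_values is None:
        bin_values = np.arange(hist.size, dtype=np.float64)
    bin_values = np.asarray(bin_values, dtype=np.float64)
    if int((hist > 0).sum()) < 2:
        raise ValueError("histogram has fewer than 2 occupied bins; no separation exists")
    cut, _ = _otsu_cut(hist[None, :], bin_values)
    return float(bin_values[cut[0] + 1])


def _otsu_cut(counts: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Otsu over the last axis.

    Returns per-row the cut index k (lower class = bins <= k; the first
    occurrence of the maximum, i.e. the lowest threshold, wins ties) and
    the between-class variance at the cut, normalized by total count².
    """
    c = counts.astype(np.float64)
    n = c.sum(axis=-1, keepdims=True)
    cum_c = np.cumsum(c, axis=-1)[..., :-1]
    cum_s = np.cumsum(c * values, axis=-1)[..., :-1]
    tot_s = np.sum(c * values, axis=-1, keepdims=True)
    c1 = n - cum_c
    valid = (cum_c > 0) & (c1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_s / cum_c
        mu1 = (tot_s - cum_s) / c1
        sb = cum_c * c1 * (mu0 - mu1) ** 2
    sb = np.where(valid, sb, -np.inf)
    cut = np.argmax(sb, axis=-1)
    best = np.take_along_axis(sb, cut[..., None], axis=-1)[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        sb_norm = best / (n[..., 0] ** 2)
    return cut, sb_norm


# ---------------------------------------------------------------------------
# local-Otsu stroma binarization


def binarize_stroma(
    intensity_db: np.ndarray,
    boundaries: ChoroidBoundaries,
    window: int = 31,
    median_radius: int = 2,
    n_bins: int = 64,
    presmooth_px: int = 3,
    min_separation: float = 0.7,
    dark_floor_db: float | None = None,
) -> np.ndarray:
    """Split the choroid into interstitial stroma (True) and vessels (False).

    Per B-scan, each choroid pixel is thresholded at the Otsu cut of the
    intensity histogram of its ``window``×``window`` neighbourhood
    (restricted to choroid pixels), then cleaned with a binary median
    filter of the given radius. See the module docstring for the
    bimodality guard (``min_separation``/``dark_floor_db``).
    """
    if window < 16:
        raise ValueError("window must be >= 16 px")
    vol = np.asarray(intensity_db, dtype=np.float32)
    n_z, n_x, n_y = vol.shape
    cmask = choroid_mask(boundaries, n_z)
    if not cmask.any():
        return np.zeros(vol.shape, dtype=bool)

    # masked presmoothing: reduce speckle without bleeding in RPE/sclera values
    if presmooth_px > 1:
        sz = (presmooth_px, presmooth_px, 1)
        num = ndi.uniform_filter(np.where(cmask, vol, 0.0), size=sz)
        den = ndi.uniform_filter(cmask.astype(np.float32), size=sz)
        with np.errstate(invalid="ignore"):
            vol = np.where(cmask, num / np.maximum(den, 1e-12), 0.0)

    cvals = vol[cmask]
    lo, hi = np.percentile(cvals, [0.5, 99.5])
    if hi <= lo:
        hi = lo + 1.0
    q = np.clip(((vol - lo) / (hi - lo) * n_bins).astype(np.int32), 0, n_bins - 1)
    bin_vals = np.arange(n_bins, dtype=np.float64)

    stroma = np.zeros(vol.shape, dtype=bool)
    for y in range(n_y):
        cm = cmask[:, :, y]
        if not cm.any():
            continue
        qy = q[:, :, y]
        onehot = np.zeros((n_bins, n_z, n_x), dtype=np.float32)
        zz, xx = np.nonzero(cm)
        onehot[qy[zz, xx], zz, xx] = 1.0
        counts = ndi.uniform_filter(onehot, size=(1, window, window), mode="constant")
        counts = np.moveaxis(counts, 0, -1)  # (n_z, n_x, n_bins)
        total = counts.sum(axis=-1)
        distinct = (counts > 1e-9).sum(axis=-1)

        cut, sb_norm = _otsu_cut(counts, bin_vals)
        mean = counts @ bin_vals
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = mean / np.maximum(total, 1e-12)
            var = counts @ (bin_vals**2) / np.maximum(total, 1e-12) - mean**2
            eta = np.where(var > 0, sb_norm / var, 0.0)

        # single-class windows: no meaningful Otsu cut
        if dark_floor_db is not None:
            dark_bin = (dark_floor_db - lo) / (hi - lo) * n_bins
            single_dark = mean < dark_bin
        else:
            single_dark = np.zeros_like(mean, dtype=bool)
        weak = eta < min_separation
        cut = np.where(weak, np.where(single_dark, n_bins, -1), cut)

        bad = (distinct < 2) & cm & ~weak
        if bad.any():
            ok = (distinct >= 2) | weak
            if ok.any():
                idx = ndi.distance_transform_edt(~ok, return_distances=False, return_indices=True)
                cut = cut[tuple(idx)]
                log.debug("B-scan %d: %d pixels inherited nearest local threshold", y, int(bad.sum()))
            else:
                cut = np.full_like(cut, -1)
        stroma[:, :, y] = cm & (qy > cut)

    if median_radius > 0:
        size = 2 * median_radius + 1
        stroma = ndi.median_filter(stroma.astype(np.uint8), size=(size, size, 1)) > 0
        stroma &= cmask
    return stroma
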