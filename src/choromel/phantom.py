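"""Synthetic polarization-resolved OCT phantoms with voxel-level ground truth.

The phantom emulates a macular raster scan of a layered posterior eye:
vitreous, neural retina (with an optional foveal pit), a thin bright
depolarizing RPE band, the choroid — split into vessel lumina and
interstitial stroma, with a configurable fraction of the stroma occupied
by depolarizing melanin-rich tissue — and sclera. Polarization-preserving
voxels carry a shared pure polarization state under fully developed
speckle (circular complex Gaussian field, exponential intensity);
depolarizing voxels carry an independent random state uniform on the
Poincaré sphere; vessel lumina and vitreous are signal-free. Additive
circular complex Gaussian detection noise of configurable power completes
the measurement model.

Melanin placement is spatially clustered by default: a smoothed Gaussian
random field is rank-transformed to uniform within the stroma and
thresholded at the target occupancy ρ, so the stroma-conditional melanin
fraction equals ρ (to within 1/N) while melanin aggregates into clumps of
configurable correlation length — kernel-based DOPU detects contiguous
melanin-rich tissue, not isolated voxels. Set ``melanin_cluster_um = 0``
for voxel-independent placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .segmentation import ChoroidBoundaries
from .volumes import JonesVolume

__all__ = [
    "CLASS_NAMES",
    "VITREOUS",
    "RETINA",
    "RPE",
    "STROMA",
    "MELANIN",
    "VESSEL",
    "SCLERA",
    "GeometryError",
    "Vessel",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "simulate_speckle",
    "add_detection_noise",
    "demo_spec",
]

log = logging.getLogger(__name__)

# voxel class labels
VITREOUS, RETINA, RPE, STROMA, MELANIN, VESSEL, SCLERA = range(7)
CLASS_NAMES = ("vitreous", "retina", "rpe", "stroma", "melanin", "vessel", "sclera")

_DEPOLARIZING = (RPE, MELANIN)
_PRESERVING = (RETINA, STROMA, SCLERA)


class GeometryError(ValueError):
    """Raised when the requested layer surfaces are inconsistent."""


@dataclass(frozen=True)
class Vessel:
    """A straight vessel tube running along the fast (x) axis."""

    y_um: float
    depth_frac: float  # fractional depth inside the choroid, in (0, 1)
    radius_um: float


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic PS-OCT volume.

    Default grid and pitch follow the acquisition protocol modelled here:
    512 A-lines × 256 B-scans over 6.0 × 6.0 mm, ≈11.7 μm lateral and
    ≈4.33 μm axial pixel pitch (so a 3 × 3 kernel spans ≈35 × 13 μm),
    with 400 axial pixels as a plausible imaging depth.
    """

    n_z: int = 400
    n_x: int = 512
    n_y: int = 256
    dz: float = 13.0 / 3.0
    dx: float = 35.0 / 3.0
    dy: float = 6000.0 / 256.0

    # layer geometry (μm depth)
    retina_top_um: float = 160.0
    rpe_depth_um: float = 320.0
    rpe_thickness_um: float = 15.0
    choroid_thickness_um: float = 220.0
    central_bump_um: float = 60.0  # choroid thickening under the fovea
    bump_sigma_um: float = 900.0
    pit_depth_um: float = 60.0  # foveal pit (inner retina only)
    pit_sigma_um: float = 400.0

    # melanin / vessels
    rho: float = 0.38  # stroma-conditional melanin occupancy
    rho_map: np.ndarray | None = None  # optional per-A-line ρ, shape (n_x, n_y)
    melanin_cluster_um: float = 300.0  # 0 → independent Bernoulli placement
    vessels: tuple[Vessel, ...] | None = None  # None → n_random_vessels drawn
    n_random_vessels: int = 12
    vessel_radius_um: tuple[float, float] = (40.0, 80.0)
    vessel_margin_um: float = 40.0  # clearance kept from both choroid boundaries

    # optics
    reflectivity: dict = field(
        default_factory=lambda: {RETINA: 0.3, RPE: 1.0, STROMA: 0.5, MELANIN: 0.5, SCLERA: 0.1}
    )
    pol_state: tuple[complex, complex] = (2.0**-0.5, 2.0**-0.5)
    n_h: float = 0.0125
    n_v: float = 0.0125

    # metadata
    seed: int = 0
    axial_length_mm: float = 24.2
    laterality: str = "right"
    fovea_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.n_z, self.n_x, self.n_y) <= 0:
            raise ValueError("grid dimensions must be positive")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.rho_map is not None:
            rm = np.asarray(self.rho_map, dtype=np.float64)
            if rm.shape != (self.n_x, self.n_y):
                raise ValueError("rho_map must have shape (n_x, n_y)")
            if rm.min() < 0 or rm.max() > 1:
                raise ValueError("rho_map values must lie in [0, 1]")
            self.rho_map = rm
        if self.n_h < 0 or self.n_v < 0:
            raise ValueError("noise powers must be non-negative")
        if self.fovea_px is None:
            self.fovea_px = ((self.n_x - 1) / 2.0, (self.n_y - 1) / 2.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_z, self.n_x, self.n_y)

    def surfaces(self) -> dict[str, np.ndarray]:
        """Layer boundary depths (μm) per A-line, validated for ordering."""
        x_um = (np.arange(self.n_x) - self.fovea_px[0]) * self.dx
        y_um = (np.arange(self.n_y) - self.fovea_px[1]) * self.dy
        r2 = x_um[:, None] ** 2 + y_um[None, :] ** 2
        pit = self.pit_depth_um * np.exp(-r2 / (2 * self.pit_sigma_um**2))
        bump = self.central_bump_um * np.exp(-r2 / (2 * self.bump_sigma_um**2))
        retina_top = self.retina_top_um + pit
        rpe_top = np.full(r2.shape, self.rpe_depth_um)
        choroid_in = rpe_top + self.rpe_thickness_um
        choroid_out = choroid_in + self.choroid_thickness_um + bump
        depth = self.n_z * self.dz
        for lo, hi, strict, what in (
            (retina_top, rpe_top, True, "retina top vs RPE"),
            (rpe_top, choroid_in, True, "RPE vs choroid inner"),
            (choroid_in, choroid_out, False, "choroid inner vs outer"),
            (choroid_out, np.full(r2.shape, depth), True, "choroid outer vs volume depth"),
        ):
            bad = (lo >= hi) if strict else (lo > hi)
            if bad.any():
                x, y = np.argwhere(bad)[0]
                raise GeometryError(f"crossing surfaces ({what}) at A-line (x={x}, y={y})")
        return {
            "retina_top": retina_top,
            "rpe_top": rpe_top,
            "choroid_in": choroid_in,
            "choroid_out": choroid_out,
        }


@dataclass
class GroundTruth:
    """Voxel-level truth accompanying a phantom volume.

    All masks are (n_z, n_x, n_y); en-face arrays are (n_x, n_y). The
    melanin mask is contained in the stroma mask, which is contained in
    the choroid region.
    """

    classes: np.ndarray
    z_in_px: np.ndarray
    z_out_px: np.ndarray
    stroma_mask: np.ndarray
    melanin_mask: np.ndarray
    ct_um: np.ndarray
    mech_um: np.ndarray
    occupancy: np.ndarray  # NaN where an A-line has no stroma
    dz: float
    sector_table: object | None = None

    def boundaries(self) -> ChoroidBoundaries:
        return ChoroidBoundaries(
            self.z_in_px.astype(np.float64), self.z_out_px.astype(np.float64), dz=self.dz
        )

    @property
    def stroma_counts(self) -> np.ndarray:
        return self.stroma_mask.sum(axis=0)

    @property
    def melanin_counts(self) -> np.ndarray:
        return self.melanin_mask.sum(axis=0)


def demo_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A reduced-grid phantom (128 × 64 A-lines/B-scans, 160 depth px)
    still covering the nominal 6 × 6 mm field, suitable for fast runs."""
    kwargs = dict(
        n_z=160,
        n_x=128,
        n_y=64,
        dx=6000.0 / 128,
        dy=6000.0 / 64,
        seed=seed,
        n_random_vessels=8,
        vessel_radius_um=(50.0, 90.0),
    )
    kwargs.update(overrides)
    if "n_x" in overrides and "dx" not in overrides:
        kwargs["dx"] = 6000.0 / overrides["n_x"]
    if "n_y" in overrides and "dy" not in overrides:
        kwargs["dy"] = 6000.0 / overrides["n_y"]
    return PhantomSpec(**kwargs)


# ---------------------------------------------------------------------------


def _class_volume(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    surf = spec.surfaces()
    zc = (np.arange(spec.n_z, dtype=np.float64) + 0.5)[:, None, None] * spec.dz

    classes = np.zeros(spec.shape, dtype=np.uint8)
    classes[(zc >= surf["retina_top"][None]) & (zc < surf["rpe_top"][None])] = RETINA
    classes[(zc >= surf["rpe_top"][None]) & (zc < surf["choroid_in"][None])] = RPE
    chor = (zc >= surf["choroid_in"][None]) & (zc < surf["choroid_out"][None])
    classes[chor] = STROMA
    classes[zc >= surf["choroid_out"][None]] = SCLERA

    # vessels: straight tubes along x, following the local choroid contour,
    # kept strictly inside the choroid with a margin at both boundaries
    vessels = spec.vessels
    if vessels is None:
        field_y = spec.n_y * spec.dy
        vessels = tuple(
            Vessel(
                y_um=float(rng.uniform(0.05, 0.95) * field_y),
                depth_frac=float(rng.uniform(0.3, 0.7)),
                radius_um=float(rng.uniform(*spec.vessel_radius_um)),
            )
            for _ in range(spec.n_random_vessels)
        )
    if vessels:
        yc = (np.arange(spec.n_y, dtype=np.float64) + 0.5)[None, None, :] * spec.dy
        thick = surf["choroid_out"] - surf["choroid_in"]
        interior = (zc >= surf["choroid_in"][None] + spec.vessel_margin_um) & (
            zc < surf["choroid_out"][None] - spec.vessel_margin_um
        )
        vmask = np.zeros(spec.shape, dtype=bool)
        for ves in vessels:
            z0 = surf["choroid_in"] + ves.depth_frac * thick  # (n_x, n_y)
            d2 = (zc - z0[None]) ** 2 + (yc - ves.y_um) ** 2
            vmask |= d2 <= ves.radius_um**2
        classes[vmask & interior & chor] = VESSEL

    # melanin within the interstitial stroma
    stroma = classes == STROMA
    n_stroma = int(stroma.sum())
    if n_stroma:
        g = rng.standard_normal(spec.shape).astype(np.float32)
        if spec.melanin_cluster_um > 0:
            # clusters must span a few voxels on any grid: a melanin region
            # narrower than the pitch is a sub-voxel mixture the binary
            # label cannot represent, so the per-axis sigma is floored
            sigma = tuple(
                max(spec.melanin_cluster_um / (2 * d), 1.5)
                for d in (spec.dz, spec.dx, spec.dy)
            )
            g = ndi.gaussian_filter(g, sigma=sigma)
        vals = g[stroma]
        order = np.argsort(vals, kind="stable")
        u = np.empty(n_stroma, dtype=np.float64)
        u[order] = (np.arange(n_stroma) + 0.5) / n_stroma
        if spec.rho_map is not None:
            rho_vox = np.broadcast_to(spec.rho_map[None], spec.shape)[stroma]
        else:
            rho_vox = spec.rho
        mel = u < rho_vox
        zz, xx, yy = np.nonzero(stroma)
        classes[zz[mel], xx[mel], yy[mel]] = MELANIN
    return classes


def simulate_speckle(
    classes: np.ndarray, spec: PhantomSpec, rng: np.random.Generator | None = None
) -> JonesVolume:
    """Synthesize the dual-channel complex field for a labelled volume.

    Polarization-preserving voxels share ``spec.pol_state`` under fully
    developed speckle; depolarizing voxels get an independent random
    state, uniform on the Poincaré sphere, with the same amplitude
    statistics; vitreous and vessel lumina are signal-free.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    classes = np.asarray(classes)
    if classes.max() >= len(CLASS_NAMES):
        raise ValueError("unknown voxel class label")
    refl = np.zeros(len(CLASS_NAMES), dtype=np.float32)
    for cls, mu in spec.reflectivity.items():
        refl[cls] = mu
    refl[VITREOUS] = 0.0
    refl[VESSEL] = 0.0
    mu = refl[classes]

    g = rng.standard_normal((2,) + classes.shape, dtype=np.float32)
    amp = (g[0] + 1j * g[1]) * np.sqrt(mu / 2.0)

    e = np.array(spec.pol_state, dtype=np.complex64)
    e = e / np.sqrt(np.abs(e[0]) ** 2 + np.abs(e[1]) ** 2)
    h = amp * e[0]
    v = amp * e[1]

    dep = np.isin(classes, _DEPOLARIZING)
    n_dep = int(dep.sum())
    if n_dep:
        s = rng.standard_normal((4, n_dep), dtype=np.float32)
        a = s[0] + 1j * s[1]
        b = s[2] + 1j * s[3]
        norm = np.sqrt(np.abs(a) ** 2 + np.abs(b) ** 2)
        norm[norm == 0] = 1.0
        h[dep] = amp[dep] * (a / norm)
        v[dep] = amp[dep] * (b / norm)

    return JonesVolume(
        h=h,
        v=v,
        dz=spec.dz,
        dx=spec.dx,
        dy=spec.dy,
        axial_length_mm=spec.axial_length_mm,
        laterality=spec.laterality,
        fovea_px=spec.fovea_px,
    )


def add_detection_noise(
    jones: JonesVolume,
    n_h: float,
    n_v: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> JonesVolume:
    """Add independent circular complex Gaussian noise to each channel."""
    if n_h < 0 or n_v < 0:
        raise ValueError("noise powers must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_h == 0 and n_v == 0:
        return jones
    g = rng.standard_normal((4,) + jones.shape, dtype=np.float32)
    h = jones.h + (g[0] + 1j * g[1]) * np.float32(np.sqrt(n_h / 2.0))
    v = jones.v + (g[2] + 1j * g[3]) * np.float32(np.sqrt(n_v / 2.0))
    return JonesVolume(
        h=h,
        v=v,
        dz=jones.dz,
        dx=jones.dx,
        dy=jones.dy,
        axial_length_mm=jones.axial_length_mm,
        laterality=jones.laterality,
        fovea_px=jones.fovea_px,
    )


def make_phantom(spec: PhantomSpec) -> tuple[JonesVolume, GroundTruth]:
    """Generate a phantom volume and its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    classes = _class_volume(spec, rng)
    jones = simulate_speckle(classes, spec, rng)
    jones = add_detection_noise(jones, spec.n_h, spec.n_v, rng=rng)

    chor = (classes == STROMA) | (classes == MELANIN) | (classes == VESSEL)
    z_in = chor.argmax(axis=0).astype(np.int64)
    z_out = classes.shape[0] - chor[::-1].argmax(axis=0)
    stroma = (classes == STROMA) | (classes == MELANIN)
    melanin = classes == MELANIN

    s_cnt = stroma.sum(axis=0)
    m_cnt = melanin.sum(axis=0)
    ct = (z_out - z_in) * spec.dz
    mech = m_cnt * spec.dz
    with np.errstate(divide="ignore", invalid="ignore"):
        occ = np.where(s_cnt > 0, m_cnt / np.maximum(s_cnt, 1), np.nan)

    gt = GroundTruth(
        classes=classes,
        z_in_px=z_in,
        z_out_px=z_out,
        stroma_mask=stroma,
        melanin_mask=melanin,
        ct_um=ct.astype(np.float64),
        mech_um=mech.astype(np.float64),
        occupancy=occ,
        dz=spec.dz,
    )
    gt.sector_table = _truth_sector_table(spec, gt)
    return jones, gt


def _truth_sector_table(spec: PhantomSpec, gt: GroundTruth):
    from . import sectors
    from .volumes import EnFaceMap

    try:
        pitch = tuple(
            sectors.transverse_scale(spec.axial_length_mm, p) for p in (spec.dx, spec.dy)
        )
        masks = sectors.make_sector_masks(
            (spec.n_x, spec.n_y), spec.fovea_px, pitch, nasal_side="image_left"
        )
    except ValueError as exc:
        log.warning("truth sector table unavailable: %s", exc)
        return None
    valid = np.ones(gt.ct_um.shape, dtype=bool)
    occ_valid = gt.stroma_counts > 0
    maps = {
        "choroidal_thickness_um": EnFaceMap(gt.ct_um, valid, "choroidal_thickness_um", pitch),
        "mech_thickness_um": EnFaceMap(gt.mech_um, valid, "mech_thickness_um", pitch),
        "occupancy": EnFaceMap(
            np.where(occ_valid, gt.occupancy, 0.0), occ_valid, "occupancy", pitch
        ),
    }
    return sectors.sector_means(
        maps, masks, low_counts=gt.melanin_counts, stroma_counts=gt.stroma_counts
    )
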