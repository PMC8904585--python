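"""End-to-end orchestration: per-eye runs and cohort aggregation.

``run_eye`` composes the stages in measurement order: volume → Stokes →
noise estimate → noise-corrected DOPU → low-DOPU mask → choroid
segmentation (bundled heuristic or imported boundaries) → stroma
binarization → en-face maps → magnification-calibrated sector means.
``run_cohort`` concatenates per-eye tables and applies the cohort
statistics (simple regressions, stepwise models, sector contrasts).
Everything is deterministic given config + seed, and outputs carry a
provenance line (package version, config hash, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import metrics, polarimetry, sectors, segmentation, stats
from .volumes import JonesVolume

__all__ = ["RunConfig", "EyeResult", "run_eye", "run_cohort", "cohort_stats"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Per-eye pipeline configuration; defaults follow the measurement
    protocol modelled by this package (DOPU < 0.8 on a 3 × 3 kernel,
    2/5 mm circles)."""

    volume_path: str | None = None
    out_dir: str | None = None
    eye_id: str = "eye"
    dopu_threshold: float = 0.8
    kernel_half_axial: int = 1
    kernel_half_lateral: int = 1
    noise_region_rows: int = 30
    eps_valid: float = 2.0
    inner_guard_px: int | None = None  # None → kernel axial half-width
    seg_mode: str = "heuristic"  # or "imported"
    boundaries_csv: str | None = None
    otsu_window_px: int = 31
    median_radius_px: int = 2
    min_separation: float = 0.7
    n_bins: int = 64
    inner_diameter_mm: float = 2.0
    outer_diameter_mm: float = 5.0
    al_ref_mm: float = 24.2
    nasal_side: str = "image_left"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.dopu_threshold <= 1.0):
            raise ValueError("dopu_threshold must lie in (0, 1]")
        if not self.inner_diameter_mm < self.outer_diameter_mm:
            raise ValueError("inner circle diameter must be smaller than the outer")
        if self.seg_mode not in ("heuristic", "imported"):
            raise ValueError("seg_mode must be 'heuristic' or 'imported'")
        if self.seg_mode == "imported" and not self.boundaries_csv:
            raise ValueError("seg_mode 'imported' requires boundaries_csv")

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        # paths identify a filesystem location, not the analysis
        for key in ("volume_path", "out_dir", "boundaries_csv"):
            d.pop(key, None)
        return cio.config_hash(d)


@dataclass
class EyeResult:
    maps: dict
    sector_table: pd.DataFrame
    qc: dict
    boundaries: segmentation.ChoroidBoundaries
    stroma_mask: np.ndarray = field(repr=False, default=None)
    low_dopu_mask: np.ndarray = field(repr=False, default=None)
    dopu: object = field(repr=False, default=None)


def run_eye(config: RunConfig, volume: JonesVolume | None = None) -> EyeResult:
    """Run the full per-eye pipeline; write outputs if ``out_dir`` is set."""
    written: list[Path] = []
    try:
        return _run_eye(config, volume, written)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"eye {config.eye_id}: {exc}") from exc


def _run_eye(config: RunConfig, volume, written) -> EyeResult:
    if volume is None:
        if config.volume_path is None:
            raise ValueError("no volume given: set volume_path or pass a JonesVolume")
        volume = cio.load_volume(config.volume_path)

    stokes = polarimetry.jones_to_stokes(volume)
    noise = polarimetry.estimate_noise(
        volume, region=(slice(0, config.noise_region_rows), slice(None), slice(None))
    )
    kernel = polarimetry.DOPUKernel(config.kernel_half_axial, config.kernel_half_lateral)
    dopu = polarimetry.compute_dopu(stokes, kernel, noise, eps_valid=config.eps_valid)
    low = polarimetry.binarize_dopu(dopu, config.dopu_threshold)

    floor = max(noise.total, 1e-12)
    intensity_db = 10.0 * np.log10(np.maximum(stokes.i, floor * 1e-2))

    if config.seg_mode == "imported":
        bounds = segmentation.import_boundaries(
            config.boundaries_csv, shape=(volume.n_x, volume.n_y), dz=volume.dz
        )
    else:
        bounds = segmentation.segment_choroid(intensity_db, dz=volume.dz)

    stroma = segmentation.binarize_stroma(
        intensity_db,
        bounds,
        window=config.otsu_window_px,
        median_radius=config.median_radius_px,
        n_bins=config.n_bins,
        min_separation=config.min_separation,
        dark_floor_db=10.0 * np.log10(floor) + 3.0,
    )

    pitch = tuple(
        sectors.transverse_scale(volume.axial_length_mm, p, config.al_ref_mm)
        for p in (volume.dx, volume.dy)
    )
    guard = config.inner_guard_px
    if guard is None:
        guard = config.kernel_half_axial
    maps = {
        "choroidal_thickness_um": metrics.choroidal_thickness_map(bounds, volume.dz, pitch),
        "mech_thickness_um": metrics.mech_thickness_map(
            low, stroma, bounds, volume.dz, pitch, inner_guard_px=guard
        ),
        "occupancy": metrics.occupancy_map(low, stroma, bounds, pitch, inner_guard_px=guard),
    }
    low_cnt, s_cnt = metrics.count_maps(low, stroma, bounds, inner_guard_px=guard)
    masks = sectors.make_sector_masks(
        (volume.n_x, volume.n_y),
        volume.fovea_px,
        pitch,
        nasal_side=config.nasal_side,
        inner_diameter_mm=config.inner_diameter_mm,
        outer_diameter_mm=config.outer_diameter_mm,
    )
    table = sectors.sector_means(maps, masks, low_counts=low_cnt, stroma_counts=s_cnt)

    qc = {
        "eye_id": config.eye_id,
        "seed": config.seed,
        "config_hash": config.hash(),
        "seg_mode": config.seg_mode,
        "noise_estimate": {"n_h": noise.n_h, "n_v": noise.n_v},
        "invalid_aline_frac": float(1.0 - bounds.valid.mean()),
        "calibrated_pitch_um": list(pitch),
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ch = config.hash()

        def _w(path):
            written.append(path)
            return path

        cio.save_dopu_tiff(dopu.dopu, _w(out / "dopu.tif"))
        cio.save_mask_tiff(low, _w(out / "low_dopu_mask.tif"))
        cio.save_mask_tiff(stroma, _w(out / "stroma_mask.tif"))
        for role, m in maps.items():
            stem = out / role
            cio.save_enface_map(m, stem, cfg_hash=ch, seed=config.seed)
            written.extend([stem.with_suffix(".tif"), stem.with_suffix(".csv")])
        with open(_w(out / "sector_table.csv"), "w", newline="") as fh:
            fh.write(cio.provenance_line(ch, config.seed) + "\n")
            table.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
        _w(out / "qc.json").write_text(json.dumps(qc, indent=1, sort_keys=True))
        segmentation.export_boundaries(bounds, _w(out / "boundaries.csv"))

    return EyeResult(
        maps=maps,
        sector_table=table,
        qc=qc,
        boundaries=bounds,
        stroma_mask=stroma,
        low_dopu_mask=low,
        dopu=dopu,
    )


# ---------------------------------------------------------------------------
# cohort level


_TABLE1_PAIRS = (
    ("choroidal_thickness_um", "age_y"),
    ("choroidal_thickness_um", "axial_length_mm"),
    ("mech_thickness_um", "age_y"),
    ("mech_thickness_um", "axial_length_mm"),
    ("mech_thickness_um", "choroidal_thickness_um"),
    ("occupancy", "age_y"),
    ("occupancy", "axial_length_mm"),
    ("occupancy", "choroidal_thickness_um"),
)


def cohort_stats(df: pd.DataFrame, sector_values: dict[str, pd.DataFrame] | None = None) -> dict:
    """Cohort analysis report: simple regressions of each outcome against
    age/axial length/choroidal thickness, stepwise models, and (when
    per-sector matrices are supplied) the sector contrasts."""
    report: dict = {"n_eyes": int(len(df))}
    if len(df) < 3:
        report["notice"] = "fewer than 3 eyes: statistics skipped"
        return report

    simple = []
    for response, predictor in _TABLE1_PAIRS:
        res = stats.simple_linreg(df[predictor], df[response])
        simple.append({"response": response, "predictor": predictor, "r": res.r, "p": res.p})
    report["simple_regressions"] = simple

    step = {}
    res_ct = stats.stepwise_mlr(
        df["choroidal_thickness_um"], df[["age_y", "axial_length_mm"]]
    )
    step["choroidal_thickness_um"] = _step_to_dict(res_ct)
    res_occ = stats.stepwise_mlr(
        df["occupancy"], df[["age_y", "axial_length_mm", "choroidal_thickness_um"]]
    )
    step["occupancy"] = _step_to_dict(res_occ)
    report["stepwise"] = step

    if sector_values:
        report["sector_tests"] = {}
        for measure, mat in sector_values.items():
            entry = {}
            if {"center", "outer_ring"}.issubset(mat.columns):
                diffs = (mat["center"] - mat["outer_ring"]).to_numpy()
                entry["center_vs_outer_ring_p"] = stats.wilcoxon_signed_rank(diffs)
            five = [c for c in ("center", "superior", "inferior", "nasal", "temporal") if c in mat]
            if len(five) >= 3:
                chi2, p, pairs = stats.friedman_with_posthoc(mat[five])
                entry["friedman_chi2"] = chi2
                entry["friedman_p"] = p
                entry["posthoc"] = pairs.to_dict(orient="records")
            report["sector_tests"][measure] = entry
    return report


def _step_to_dict(res: stats.RegressionResult) -> dict:
    return {
        "retained": res.retained,
        "removed": res.removed,
        "coef": res.coef.reset_index().to_dict(orient="records"),
    }


def run_cohort(
    configs: list[RunConfig],
    metadata: pd.DataFrame,
    out_dir: str | None = None,
    volumes: list[JonesVolume] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run every eye, join with metadata, and apply the cohort statistics.

    ``metadata`` needs columns eye_id, age_y, axial_length_mm. Eyes with
    missing metadata are excluded with a warning; duplicate eye ids are
    rejected.
    """
    ids = [c.eye_id for c in configs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate eye id(s): {dup}")
    meta = metadata.set_index("eye_id")

    rows = []
    for i, cfg in enumerate(configs):
        vol = volumes[i] if volumes is not None else None
        if cfg.eye_id not in meta.index:
            log.warning("eye %s: missing metadata; excluded", cfg.eye_id)
            continue
        result = run_eye(cfg, volume=vol)
        whole = result.sector_table.set_index("sector").loc["whole"]
        rows.append(
            {
                "eye_id": cfg.eye_id,
                "age_y": float(meta.loc[cfg.eye_id, "age_y"]),
                "axial_length_mm": float(meta.loc[cfg.eye_id, "axial_length_mm"]),
                "choroidal_thickness_um": float(whole["mean_choroidal_thickness_um"]),
                "mech_thickness_um": float(whole["mean_mech_thickness_um"]),
                "occupancy": float(whole["mean_occupancy"]),
            }
        )
    df = pd.DataFrame(rows)
    report = cohort_stats(df)

    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "cohort.csv", index=False, float_format="%.10g")
        (out / "cohort_stats.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return df, report
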