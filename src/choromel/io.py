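"""File formats: raw volumes with JSON sidecars, TIFF stacks, CSV maps.

A polarization-resolved volume is stored as little-endian float32 raw
binary, channel-major: the array ``(4, n_z, n_x, n_y)`` holding
(Re H, Im H, Re V, Im V), with a JSON sidecar (same stem, ``.json``)
recording dims, spacings, eye metadata and layout. Volumes and masks are
written as multi-page TIFF (one B-scan per page); en-face maps as 32-bit
float TIFF plus a CSV of (x_px, y_px, value, valid). CSV outputs carry a
one-line provenance comment (version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .volumes import EnFaceMap, JonesVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_dopu_tiff",
    "save_mask_tiff",
    "save_enface_map",
    "load_enface_csv",
    "provenance_line",
    "config_hash",
]

_LAYOUT = "re_h,im_h,re_v,im_v x z x x x y"


def save_volume(jones: JonesVolume, path) -> None:
    """Write raw float32 binary plus JSON sidecar."""
    path = Path(path)
    arr = np.stack(
        [jones.h.real, jones.h.imag, jones.v.real, jones.v.imag]
    ).astype("<f4")
    arr.tofile(path)
    sidecar = {
        "dims": list(jones.shape),
        "spacings_um": [jones.dz, jones.dx, jones.dy],
        "axial_length_mm": jones.axial_length_mm,
        "laterality": jones.laterality,
        "fovea_px": list(jones.fovea_px),
        "byte_order": "little",
        "layout": _LAYOUT,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_volume(path) -> JonesVolume:
    """Read a raw volume; the JSON sidecar must sit next to it."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar: expected {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    n_z, n_x, n_y = meta["dims"]
    raw = np.fromfile(path, dtype="<f4")
    expect = 4 * n_z * n_x * n_y
    if raw.size != expect:
        raise ValueError(f"raw volume has {raw.size} floats, sidecar implies {expect}")
    raw = raw.reshape(4, n_z, n_x, n_y)
    dz, dx, dy = meta["spacings_um"]
    return JonesVolume(
        h=(raw[0] + 1j * raw[1]).astype(np.complex64),
        v=(raw[2] + 1j * raw[3]).astype(np.complex64),
        dz=dz,
        dx=dx,
        dy=dy,
        axial_length_mm=meta.get("axial_length_mm", 24.2),
        laterality=meta.get("laterality", "right"),
        fovea_px=tuple(meta["fovea_px"]) if meta.get("fovea_px") else None,
    )


def _pages(vol: np.ndarray) -> np.ndarray:
    # (z, x, y) -> one page per B-scan, each (z, x)
    return np.moveaxis(vol, 2, 0)


def save_dopu_tiff(dopu: np.ndarray, path) -> None:
    tifffile.imwrite(path, _pages(dopu.astype(np.float32)))


def save_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, _pages((mask.astype(np.uint8)) * 255))


def config_hash(config_dict: dict) -> str:
    """Deterministic short hash of a JSON-serializable configuration."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_line(cfg_hash: str, seed: int) -> str:
    from . import __version__

    return f"# choromel={__version__} config={cfg_hash} seed={seed}"


def save_enface_map(m: EnFaceMap, stem, cfg_hash: str = "na", seed: int = 0) -> None:
    """Write a map as float32 TIFF (y, x orientation) and provenance CSV."""
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".tif"), m.values.T.astype(np.float32))
    xs, ys = np.meshgrid(np.arange(m.shape[0]), np.arange(m.shape[1]), indexing="ij")
    df = pd.DataFrame(
        {
            "x_px": xs.ravel(),
            "y_px": ys.ravel(),
            "value": m.values.ravel(),
            "valid": m.valid.ravel().astype(int),
        }
    )
    with open(stem.with_suffix(".csv"), "w", newline="") as fh:
        fh.write(provenance_line(cfg_hash, seed) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def load_enface_csv(path, role: str, pitch=(1.0, 1.0)) -> EnFaceMap:
    df = pd.read_csv(path, comment="#")
    n_x = int(df["x_px"].max()) + 1
    n_y = int(df["y_px"].max()) + 1
    vals = np.zeros((n_x, n_y))
    valid = np.zeros((n_x, n_y), dtype=bool)
    vals[df["x_px"], df["y_px"]] = df["value"]
    valid[df["x_px"], df["y_px"]] = df["valid"].astype(bool)
    return EnFaceMap(vals, valid, role, tuple(pitch))
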