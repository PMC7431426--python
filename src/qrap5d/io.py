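"""Readers and writers for on-disk formats.

Frames travel as grayscale TIFF (16-bit preferred) or PNG with a JSON
sidecar recording wavelength, geometry, role and the reversible intensity
scale; configs are YAML; masks are CSV center lists with a JSON header.
Interface units are mm / nm / µm; everything is meters internally.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .mask import PinholeArray
from .optics import IntensityPattern, OpticalConfig

__all__ = [
    "write_intensity",
    "read_intensity",
    "load_config",
    "save_config",
    "write_mask_csv",
    "read_mask_csv",
]

_SIDECAR_SUFFIX = ".json"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDECAR_SUFFIX)


def write_intensity(path: str | Path, pattern: IntensityPattern,
                    seed: int | None = None) -> Path:
    """Write a frame plus its metadata sidecar.

    Integer input is stored as-is (lossless round trip).  Float data is
    rescaled to the full 16-bit range; the scale factor is recorded in the
    sidecar so physical values are recoverable.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".tif", ".tiff", ".png"):
        raise ValueError(f"unsupported frame format {suffix!r}")
    v = pattern.values
    integral = (np.issubdtype(v.dtype, np.integer)
                or (v.size and v.min() >= 0 and v.max() <= 65535
                    and np.all(v == np.rint(v))))
    if integral:
        raw = v.astype(np.uint16)
        scale = 1.0
    else:
        top = float(v.max())
        scale = top / 65535.0 if top > 0 else 1.0
        raw = np.round(v / scale).astype(np.uint16) if top > 0 else \
            np.zeros(v.shape, dtype=np.uint16)
    if suffix == ".png":
        iio.imwrite(path, raw.astype(np.uint16 if raw.dtype.itemsize > 1
                                     else raw.dtype))
    else:
        tifffile.imwrite(path, raw)
    meta = {
        "wavelength_nm": None if pattern.wavelength is None
        else pattern.wavelength * 1e9,
        "u_mm": None if pattern.z is None else pattern.z * 1e3,
        "v_mm": pattern.meta.get("v_mm"),
        "du_mm": None if pattern.du is None else pattern.du * 1e3,
        "role": pattern.role,
        "scale": scale,
        "seed": seed,
        "pitch_um": pattern.pitch * 1e6,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_intensity(path: str | Path) -> IntensityPattern:
    """Read a frame; apply the sidecar scale to recover physical values.

    A missing sidecar is tolerated with a warning — the frame loads with
    unknown metadata and unit scale.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        raw = iio.imread(path)
    else:
        raise ValueError(f"unsupported frame format {path.suffix!r}")
    if raw.ndim != 2:
        raise ValueError("only grayscale frames are supported")
    if raw.dtype not in (np.uint8, np.uint16) and not np.issubdtype(
            raw.dtype, np.floating):
        raise ValueError(f"unsupported bit depth {raw.dtype}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        warnings.warn(f"no metadata sidecar for {path.name}; metadata unknown",
                      stacklevel=2)
        meta = {}
    scale = meta.get("scale", 1.0)
    values = raw.astype(float) * scale if scale != 1.0 else raw
    lam = meta.get("wavelength_nm")
    u_mm = meta.get("u_mm")
    du_mm = meta.get("du_mm")
    return IntensityPattern(
        values=np.asarray(values),
        pitch=(meta.get("pitch_um") or 1.0) * 1e-6,
        wavelength=None if lam is None else lam / 1e9,
        z=None if u_mm is None else u_mm / 1e3,
        du=None if du_mm is None else du_mm / 1e3,
        role=meta.get("role", "unknown"),
        meta={"scale": scale, "seed": meta.get("seed"),
              "metadata_known": bool(meta)},
    )


def load_config(path: str | Path) -> OpticalConfig:
    """OpticalConfig from YAML (interface units: mm, nm, µm)."""
    data = yaml.safe_load(Path(path).read_text())
    return OpticalConfig(
        u=data["u_mm"] / 1e3,
        v=data["v_mm"] / 1e3,
        wavelength=data["wavelength_nm"] / 1e9,
        sensor_shape=tuple(data.get("sensor_shape", (256, 256))),
        pixel_pitch=data.get("pixel_pitch_um", 8.0) / 1e6,
        grid_oversample=data.get("grid_oversample", 1),
    )


def save_config(path: str | Path, config: OpticalConfig) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump({
        "u_mm": config.u * 1e3,
        "v_mm": config.v * 1e3,
        "wavelength_nm": config.wavelength * 1e9,
        "sensor_shape": list(config.sensor_shape),
        "pixel_pitch_um": config.pixel_pitch * 1e6,
        "grid_oversample": config.grid_oversample,
    }))
    return path


def write_mask_csv(path: str | Path, mask: PinholeArray) -> Path:
    """Mask exchange format: x_mm, y_mm rows + JSON header sidecar."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_mm", "y_mm"])
        for x, y in mask.centers:
            writer.writerow([f"{x * 1e3:.6f}", f"{y * 1e3:.6f}"])
    header = {"diameter_um": mask.pinhole_diameter * 1e6,
              "extent_mm": [mask.extent[0] * 1e3, mask.extent[1] * 1e3]}
    _sidecar_path(path).write_text(json.dumps(header, indent=2))
    return path


def read_mask_csv(path: str | Path) -> PinholeArray:
    path = Path(path)
    header = json.loads(_sidecar_path(path).read_text())
    with path.open() as fh:
        reader = csv.reader(fh)
        next(reader)  # header row
        centers = np.array([[float(x), float(y)] for x, y in reader]) / 1e3
    return PinholeArray(
        centers=centers,
        pinhole_diameter=header["diameter_um"] / 1e6,
        extent=(header["extent_mm"][0] / 1e3, header["extent_mm"][1] / 1e3),
    )
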