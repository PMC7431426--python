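"""Assembly of extracted channels into colour images and 5D datacubes.

Each channel extracted from a single monochrome frame is tagged with its
depth, wavelength and frame time.  For display, wavelengths are
computationally "stained": channels are placed on a synthetic RGGB Bayer
mosaic of 4× area (two green sites per 2×2 cell, as on a real sensor) or
summed directly into an RGB image.  The time axis is embarrassingly
separable — one frame per time point, extracted independently.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import scipy.ndimage as ndi
import xarray as xr

__all__ = [
    "ChannelSet",
    "wavelength_rgb_weights",
    "bayer_mosaic",
    "demosaic",
    "compose_colour",
    "assemble_5d",
]

# RGGB site offsets within each 2x2 cell
_SITES = {"R": [(0, 0)], "G": [(0, 1), (1, 0)], "B": [(1, 1)]}


def wavelength_rgb_weights(wavelength: float) -> tuple[float, float, float]:
    """Display-colour weights for a wavelength: nearest-primary staining.

    Wavelengths ≥ 570 nm are shown red, 495–570 nm green, < 495 nm blue;
    weights are normalized per wavelength.  This is a display convention,
    not radiometry.
    """
    nm = wavelength * 1e9 if wavelength < 1e-3 else wavelength
    if nm >= 570:
        return (1.0, 0.0, 0.0)
    if nm >= 495:
        return (0.0, 1.0, 0.0)
    return (0.0, 0.0, 1.0)


class ChannelSet:
    """Extracted channels indexed by (z, wavelength, t)."""

    def __init__(self) -> None:
        self.channels: dict[tuple[float, float, float], np.ndarray] = {}
        self.colour_weights: dict[float, tuple[float, float, float]] = {}

    def add(self, image, z: float, wavelength: float, t: float = 0.0,
            rgb_weights: tuple[float, float, float] | None = None) -> None:
        v = np.asarray(getattr(image, "values", image), dtype=float)
        if v.ndim != 2:
            raise ValueError("channel image must be 2D")
        if self.channels:
            ref = next(iter(self.channels.values()))
            if v.shape != ref.shape:
                raise ValueError("all channel images must share one shape")
        w = rgb_weights or wavelength_rgb_weights(wavelength)
        total = sum(w)
        if min(w) < 0 or total <= 0:
            raise ValueError("colour weights must be non-negative, not all zero")
        self.channels[(float(z), float(wavelength), float(t))] = v
        self.colour_weights[float(wavelength)] = tuple(x / total for x in w)

    def at_depth(self, z: float, t: float = 0.0, atol: float = 1e-12):
        return {k: v for k, v in self.channels.items()
                if abs(k[0] - z) <= atol and abs(k[2] - t) <= atol}

    @property
    def z_values(self) -> list[float]:
        return sorted({k[0] for k in self.channels})

    @property
    def wavelength_values(self) -> list[float]:
        return sorted({k[1] for k in self.channels})

    @property
    def t_values(self) -> list[float]:
        return sorted({k[2] for k in self.channels})


def bayer_mosaic(channels, pattern: str = "RGGB",
                 shape: tuple[int, int] | None = None) -> np.ndarray:
    """Place up to three colour-assigned images on an RGGB mosaic of 4× area.

    ``channels`` maps 'R'/'G'/'B' to an H×W image (a mapping, or an
    iterable of (colour, image) pairs — at most one image per colour).
    Output is 2H×2W: each input pixel value appears at its colour's
    site(s) of the corresponding 2×2 cell; absent colours stay zero.  An
    empty channel set yields an all-zero mosaic (``shape`` required then).
    """
    if pattern != "RGGB":
        raise ValueError("only the RGGB pattern is supported")
    if isinstance(channels, Mapping):
        items = list(channels.items())
    else:
        items = list(channels)
    seen: dict[str, np.ndarray] = {}
    for colour, image in items:
        if colour not in _SITES:
            raise ValueError(f"unknown colour {colour!r}")
        if colour in seen:
            raise ValueError(f"two images assigned to colour {colour!r}")
        seen[colour] = np.asarray(getattr(image, "values", image), dtype=float)
    shapes = {v.shape for v in seen.values()}
    if len(shapes) > 1:
        raise ValueError("channel images must share one shape")
    if not seen:
        if shape is None:
            raise ValueError("an empty channel set needs an explicit shape")
        return np.zeros((2 * shape[0], 2 * shape[1]))
    h, w = next(iter(shapes))
    out = np.zeros((2 * h, 2 * w))
    for colour, img in seen.items():
        for dy, dx in _SITES[colour]:
            out[dy::2, dx::2] = img
    return out


def demosaic(mosaic: np.ndarray, pattern: str = "RGGB") -> dict[str, np.ndarray]:
    """Bilinear demosaicing: full-resolution R, G, B planes from the mosaic."""
    if pattern != "RGGB":
        raise ValueError("only the RGGB pattern is supported")
    mosaic = np.asarray(mosaic, dtype=float)
    kern_rb = np.array([[0.25, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 0.25]])
    kern_g = np.array([[0.0, 0.25, 0.0], [0.25, 1.0, 0.25], [0.0, 0.25, 0.0]])
    planes = {}
    for colour, kern in (("R", kern_rb), ("G", kern_g), ("B", kern_rb)):
        sites = np.zeros_like(mosaic)
        for dy, dx in _SITES[colour]:
            sites[dy::2, dx::2] = mosaic[dy::2, dx::2]
        planes[colour] = ndi.convolve(sites, kern, mode="mirror")
    return planes


def compose_colour(channels: ChannelSet, z: float, t: float = 0.0) -> np.ndarray:
    """RGB image of the channels at one depth: weighted sum, unit-max normalized."""
    at_z = channels.at_depth(z, t)
    if not at_z:
        raise ValueError(f"no channels at depth {z}")
    shape = next(iter(at_z.values())).shape
    rgb = np.zeros((*shape, 3))
    for (zz, lam, tt), img in at_z.items():
        w = channels.colour_weights[lam]
        rgb += img[..., None] * np.asarray(w)
    top = rgb.max()
    if top > 0:
        rgb /= top
    return rgb


def assemble_5d(channels: ChannelSet) -> xr.DataArray:
    """Dense (y, x, z, λ, t) datacube from a channel set.

    Every (z, λ, t) combination present in the set must be filled — one
    monochrome frame per time point suffices to populate all (z, λ)
    slices, which is the single-shot property.
    """
    if not channels.channels:
        raise ValueError("empty channel set")
    zs = channels.z_values
    ls = channels.wavelength_values
    ts = channels.t_values
    shape = next(iter(channels.channels.values())).shape
    cube = np.zeros((*shape, len(zs), len(ls), len(ts)))
    for (z, lam, t), img in channels.channels.items():
        cube[:, :, zs.index(z), ls.index(lam), ts.index(t)] = img
    return xr.DataArray(
        cube,
        dims=("y", "x", "z", "wavelength", "time"),
        coords={"z": zs, "wavelength": ls, "time": ts},
        name="reconstruction",
    )
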