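"""Scalar-Fresnel incoherent imaging simulator.

Models the lensless geometry: a quasi-monochromatic point source at
distance ``u`` in front of the pinhole mask illuminates it with a paraxial
spherical wave; the mask-modulated field propagates a distance ``v`` to a
monochrome sensor that records intensity.  Extended objects are treated as
collections of mutually incoherent point emitters, so object frames are
intensity sums of shifted chaotic PSFs — equivalently a convolution
``I_O = O ⊗ I_PSF`` for a planar object, which is the fast path.

Propagation uses the Fresnel transfer-function (angular-spectrum) kernel
when the grid supports it (distance ≤ N·pitch²/λ) and the single-transform
impulse-response form otherwise; the former preserves grid pitch and
energy exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.fft as fft

from .mask import PinholeArray, rasterize_onto
from .recon import whitened_ncc_peak

__all__ = [
    "OpticalConfig",
    "ComplexField",
    "IntensityPattern",
    "Emitter",
    "PlanarObject",
    "SceneSpec",
    "SamplingError",
    "fresnel_propagate",
    "point_source_to_mask",
    "simulate_psf",
    "simulate_object_intensity",
    "axial_response_curve",
    "spectral_response_curve",
]


class SamplingError(ValueError):
    """Grid cannot support the requested propagation distance."""


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry of one recording: source–mask ``u``, mask–sensor ``v`` (meters).

    The simulation grid is the sensor grid refined ``grid_oversample``
    times and zero-padded before transforms (see :func:`simulate_psf`).
    """

    u: float
    v: float
    wavelength: float
    sensor_shape: tuple[int, int] = (256, 256)
    pixel_pitch: float = 8e-6
    grid_oversample: int = 1

    def __post_init__(self) -> None:
        if min(self.u, self.v, self.wavelength, self.pixel_pitch) <= 0:
            raise ValueError("u, v, wavelength and pixel_pitch must be positive")
        if min(self.sensor_shape) < 16:
            raise ValueError("sensor_shape entries must be >= 16")
        if self.grid_oversample < 1 or int(self.grid_oversample) != self.grid_oversample:
            raise ValueError("grid_oversample must be a positive integer")

    @property
    def sim_pitch(self) -> float:
        return self.pixel_pitch / self.grid_oversample

    @property
    def magnification(self) -> float:
        """Geometric projection magnification v/u (image inverted)."""
        return self.v / self.u


@dataclass
class ComplexField:
    """Monochromatic scalar field sampled on a square grid."""

    amplitude: np.ndarray
    pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        if self.amplitude.ndim != 2:
            raise ValueError("field must be 2D")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("field must be finite-valued")
        if self.pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pitch and wavelength must be positive")

    @property
    def energy(self) -> float:
        return float(np.sum(np.abs(self.amplitude) ** 2) * self.pitch ** 2)


@dataclass
class IntensityPattern:
    """Non-negative sensor-plane intensity with (z, λ) metadata.

    ``role`` is ``"psf"`` for a point-source recording or ``"object"`` for
    a scene frame; ``z`` is the absolute source distance and ``du`` the
    offset from the library reference (positive = farther from the mask).
    """

    values: np.ndarray
    pitch: float
    wavelength: float | None = None
    z: float | None = None
    du: float | None = None
    role: str = "psf"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("intensity must be a 2D grid")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")


@dataclass(frozen=True)
class Emitter:
    """One incoherent point emitter of the scene (object-side coordinates)."""

    x: float
    y: float
    z: float
    wavelength: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("emitter intensity must be >= 0")
        if self.z <= 0:
            raise ValueError("emitter depth must be positive")


@dataclass(frozen=True)
class PlanarObject:
    """A planar bitmap object: non-negative 2D grid at one depth and wavelength."""

    bitmap: np.ndarray
    pitch: float
    z: float
    wavelength: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        bm = np.asarray(self.bitmap, dtype=float)
        object.__setattr__(self, "bitmap", bm)
        if bm.ndim != 2 or np.any(bm < 0):
            raise ValueError("bitmap must be a non-negative 2D grid")
        if self.pitch <= 0 or self.z <= 0:
            raise ValueError("pitch and depth must be positive")


@dataclass
class SceneSpec:
    emitters: list[Emitter] = field(default_factory=list)
    planes: list[PlanarObject] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.emitters and not self.planes:
            raise ValueError("scene must contain at least one emitter or planar object")


def _centered_coords(n: int, pitch: float) -> np.ndarray:
    return (np.arange(n) - n // 2) * pitch


def max_tf_distance(field: ComplexField) -> float:
    """Largest distance the transfer-function propagator supports on this grid."""
    n = min(field.amplitude.shape)
    return n * field.pitch ** 2 / field.wavelength


def fresnel_propagate(field: ComplexField, distance: float,
                      method: str = "auto") -> ComplexField:
    """Propagate a scalar field by ``distance`` under the Fresnel approximation.

    ``method``: ``"tf"`` (transfer function; pitch-preserving, unit-modulus
    kernel so energy is conserved), ``"ir"`` (single-transform impulse
    response; output pitch λ|z|/(N·pitch), valid for long distances), or
    ``"auto"`` to switch at the critical distance N·pitch²/λ.
    """
    if distance == 0:
        raise ValueError("distance must be nonzero")
    zmax = max_tf_distance(field)
    if method == "auto":
        method = "tf" if abs(distance) <= zmax else "ir"
    lam = field.wavelength
    k = 2 * np.pi / lam
    a = field.amplitude
    if method == "tf":
        if abs(distance) > zmax:
            raise SamplingError(
                f"transfer-function propagation aliases beyond |z| = {zmax:.4g} m "
                f"for this grid (requested {distance:.4g} m)")
        fy = fft.fftfreq(a.shape[0], d=field.pitch)
        fx = fft.fftfreq(a.shape[1], d=field.pitch)
        fsq = fy[:, None] ** 2 + fx[None, :] ** 2
        kernel = np.exp(1j * k * distance) * np.exp(-1j * np.pi * lam * distance * fsq)
        out = fft.ifft2(fft.fft2(a) * kernel)
        return ComplexField(out, field.pitch, lam)
    if method == "ir":
        if a.shape[0] != a.shape[1]:
            raise SamplingError("impulse-response propagation requires a square grid")
        if abs(distance) < zmax:
            raise SamplingError(
                f"impulse-response propagation needs |z| >= {zmax:.4g} m "
                f"for this grid (requested {distance:.4g} m)")
        n = a.shape[0]
        x1 = _centered_coords(n, field.pitch)
        q1 = np.exp(1j * k / (2 * distance) * (x1[:, None] ** 2 + x1[None, :] ** 2))
        spec = fft.fftshift(fft.fft2(fft.ifftshift(a * q1))) * field.pitch ** 2
        pitch2 = lam * abs(distance) / (n * field.pitch)
        x2 = _centered_coords(n, pitch2)
        q2 = np.exp(1j * k / (2 * distance) * (x2[:, None] ** 2 + x2[None, :] ** 2))
        out = spec * q2 * np.exp(1j * k * distance) / (1j * lam * distance)
        return ComplexField(out, pitch2, lam)
    raise ValueError(f"unknown propagation method {method!r}")


def _grid_size(config: OpticalConfig, pad_factor: int,
               mask_extent: float = 0.0) -> int:
    """Simulation grid size: the padded sensor grid, enlarged if needed.

    The grid must also hold the mask (plus a diffraction margin) and keep
    the transfer-function propagator alias-free over the mask–sensor
    distance (N ≥ λv/pitch²); the result is rounded up to an FFT-friendly
    length.
    """
    pitch = config.sim_pitch
    base = pad_factor * max(config.sensor_shape) * config.grid_oversample
    n_tf = int(np.ceil(config.v * config.wavelength / pitch ** 2))
    n_mask = int(np.ceil(mask_extent / pitch)) + 16
    return fft.next_fast_len(max(base, n_tf, n_mask))


def point_source_to_mask(config: OpticalConfig, source_xy: tuple[float, float] = (0.0, 0.0),
                         source_depth: float | None = None,
                         grid_size: int | None = None) -> ComplexField:
    """Paraxial spherical wave from a point source, sampled at the mask plane.

    Phase relative to the source axis is quadratic: k((x−xs)²+(y−ys)²)/(2u).
    The 1/u amplitude fall-off is included so emitter intensities compare
    across depths.
    """
    depth = config.u if source_depth is None else source_depth
    if depth <= 0:
        raise ValueError("source_depth must be positive")
    n = grid_size or _grid_size(config, 2)
    c = _centered_coords(n, config.sim_pitch)
    xs, ys = source_xy
    rsq = (c[None, :] - xs) ** 2 + (c[:, None] - ys) ** 2
    k = 2 * np.pi / config.wavelength
    amp = np.exp(1j * k * rsq / (2 * depth)) / depth
    return ComplexField(amp, config.sim_pitch, config.wavelength)


def _downsample(values: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return values
    r, c = values.shape
    return values.reshape(r // factor, factor, c // factor, factor).mean(axis=(1, 3))


def simulate_psf(config: OpticalConfig, mask: PinholeArray,
                 source_xy: tuple[float, float] = (0.0, 0.0),
                 source_depth: float | None = None,
                 pad_factor: int = 2) -> IntensityPattern:
    """Chaotic point-spread intensity for one source position, depth and λ.

    The source wave is modulated by the rasterized mask on a grid
    ``pad_factor`` × the (oversampled) sensor grid, propagated by ``v``
    with the pitch-preserving Fresnel kernel, squared, cropped to the
    sensor extent and box-averaged down to sensor pixels.
    """
    depth = config.u if source_depth is None else source_depth
    n = _grid_size(config, pad_factor, mask_extent=max(mask.extent))
    pitch = config.sim_pitch
    if n > 8192 or max(mask.extent) > n * pitch:
        raise ValueError("mask extent exceeds the simulation grid; "
                         "increase sensor size or pad_factor")
    raster = rasterize_onto(mask, n, pitch)
    src = point_source_to_mask(config, source_xy, depth, grid_size=n)
    modulated = ComplexField(src.amplitude * raster, pitch, config.wavelength)
    sensor_field = fresnel_propagate(modulated, config.v, method="tf")
    intensity = np.abs(sensor_field.amplitude) ** 2
    ry, rx = (s * config.grid_oversample for s in config.sensor_shape)
    y0 = n // 2 - ry // 2
    x0 = n // 2 - rx // 2
    crop = intensity[y0: y0 + ry, x0: x0 + rx]
    values = _downsample(crop, config.grid_oversample)
    return IntensityPattern(values, pitch=config.pixel_pitch,
                            wavelength=config.wavelength, z=depth,
                            du=depth - config.u, role="psf",
                            meta={"source_xy": tuple(source_xy)})


def _project_object_to_sensor(obj: PlanarObject, config: OpticalConfig,
                              sensor_shape: tuple[int, int]) -> np.ndarray:
    """Project a planar bitmap through the geometry onto a sensor-pitch grid.

    Each nonzero object pixel at coordinate δ maps to its geometric image
    point −(v/z)·δ and is splatted bilinearly onto the grid, so the
    projection agrees exactly with emitter-by-emitter placement whenever
    the image points fall on grid samples.
    """
    m = config.v / obj.z
    ry, rx = sensor_shape
    ys = _centered_coords(obj.bitmap.shape[0], obj.pitch)
    xs = _centered_coords(obj.bitmap.shape[1], obj.pitch)
    iy, ix = np.nonzero(obj.bitmap)
    w = obj.bitmap[iy, ix]
    py = -m * ys[iy] / config.pixel_pitch + ry // 2
    px = -m * xs[ix] / config.pixel_pitch + rx // 2
    if np.any(py < 0) or np.any(py > ry - 1) or np.any(px < 0) or np.any(px > rx - 1):
        raise ValueError("projected object exceeds the sensor grid")
    out = np.zeros((ry, rx))
    y0 = np.clip(np.floor(py).astype(int), 0, ry - 2)
    x0 = np.clip(np.floor(px).astype(int), 0, rx - 2)
    fy = py - y0
    fx = px - x0
    np.add.at(out, (y0, x0), w * (1 - fy) * (1 - fx))
    np.add.at(out, (y0, x0 + 1), w * (1 - fy) * fx)
    np.add.at(out, (y0 + 1, x0), w * fy * (1 - fx))
    np.add.at(out, (y0 + 1, x0 + 1), w * fy * fx)
    return out


def simulate_object_intensity(config: OpticalConfig, mask: PinholeArray,
                              scene: SceneSpec, method: str = "auto",
                              pad_factor: int = 2) -> IntensityPattern:
    """Incoherent sensor frame of a scene: intensity sum over all emitters.

    Point emitters are simulated individually.  Planar bitmaps use the
    convolution fast path (``method="auto"``/``"conv"``): one on-axis PSF
    per (depth, λ) plane circularly convolved (with 2× padding) against
    the magnification-corrected bitmap.  ``method="pointsum"`` forces
    emitter-by-emitter summation of every nonzero bitmap pixel — the slow
    oracle path.
    """
    if method not in ("auto", "conv", "pointsum"):
        raise ValueError(f"unknown method {method!r}")
    total = np.zeros(config.sensor_shape, dtype=float)
    lam = None
    for em in scene.emitters:
        cfg = replace(config, wavelength=em.wavelength)
        p = simulate_psf(cfg, mask, (em.x, em.y), em.z, pad_factor)
        total += em.intensity * p.values
        lam = em.wavelength
    for plane in scene.planes:
        cfg = replace(config, wavelength=plane.wavelength)
        lam = plane.wavelength
        if method == "pointsum":
            ys = _centered_coords(plane.bitmap.shape[0], plane.pitch)
            xs = _centered_coords(plane.bitmap.shape[1], plane.pitch)
            for iy, ix in zip(*np.nonzero(plane.bitmap)):
                w = plane.bitmap[iy, ix] * plane.intensity
                p = simulate_psf(cfg, mask, (xs[ix], ys[iy]), plane.z, pad_factor)
                total += w * p.values
        else:
            # enlarge the simulated PSF window so pattern content shifted in
            # from beyond the sensor edge by off-axis emitters is retained
            m_mag = cfg.v / plane.z
            half_y = abs(_centered_coords(plane.bitmap.shape[0], plane.pitch)).max()
            half_x = abs(_centered_coords(plane.bitmap.shape[1], plane.pitch)).max()
            margin = int(np.ceil(m_mag * max(half_y, half_x)
                                 / cfg.pixel_pitch)) + 2
            ry, rx = cfg.sensor_shape
            ext_cfg = replace(cfg, sensor_shape=(ry + 2 * margin, rx + 2 * margin))
            psf = simulate_psf(ext_cfg, mask, (0.0, 0.0), plane.z, pad_factor)
            proj = _project_object_to_sensor(plane, cfg, ext_cfg.sensor_shape)
            r, c = proj.shape
            fo = fft.fft2(np.pad(proj, ((0, r), (0, c))))
            fp = fft.fft2(np.pad(psf.values, ((0, r), (0, c))))
            conv = fft.ifft2(fo * fp).real
            # projection is centered on the extended grid: undo the offset
            conv = np.roll(conv, (-(r // 2), -(c // 2)), axis=(0, 1))[:r, :c]
            total += plane.intensity * conv[margin: margin + ry,
                                            margin: margin + rx]
    role_meta = {"n_emitters": len(scene.emitters), "n_planes": len(scene.planes)}
    return IntensityPattern(np.maximum(total, 0.0), pitch=config.pixel_pitch,
                            wavelength=lam, z=None, du=None, role="object",
                            meta=role_meta)


def axial_response_curve(config: OpticalConfig, mask: PinholeArray,
                         du_values: Sequence[float]) -> list[tuple[float, float]]:
    """Normalized correlation of I_PSF(u) against I_PSF(u + Δu).

    Correlation peaks are measured on the whitened (phase) spectra — the
    domain the reconstruction filter operates in — because the smooth
    diffraction envelope barely changes with depth and would otherwise
    mask the decay.  The curve is normalized to exactly 1 at Δu = 0
    (which must be in the sweep); its FWHM estimates the axial
    resolution, expected near the direct-imaging limit 8λ(u/D)².
    """
    du_values = [float(d) for d in du_values]
    if not any(d == 0 for d in du_values):
        raise ValueError("du_values must include 0")
    ref = simulate_psf(config, mask)
    curve = []
    for du in du_values:
        val = 1.0 if du == 0 else whitened_ncc_peak(ref, simulate_psf(
            config, mask, source_depth=config.u + du))
        curve.append((du, min(val, 1.0)))
    return curve


def spectral_response_curve(config: OpticalConfig, mask: PinholeArray,
                            wavelengths: Sequence[float]) -> list[tuple[float, float]]:
    """Normalized correlation of I_PSF(λ_ref) against I_PSF(λ), fixed geometry."""
    wavelengths = [float(w) for w in wavelengths]
    if not any(w == config.wavelength for w in wavelengths):
        raise ValueError("wavelengths must include the reference wavelength")
    ref = simulate_psf(config, mask)
    curve = []
    for lam in wavelengths:
        if lam == config.wavelength:
            curve.append((lam, 1.0))
            continue
        p = simulate_psf(replace(config, wavelength=lam), mask)
        curve.append((lam, min(whitened_ncc_peak(ref, p), 1.0)))
    return curve
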