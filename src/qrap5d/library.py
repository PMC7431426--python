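"""The (depth, wavelength) PSF library and its shortcuts.

One-time training records chaotic PSFs on a grid of q depths × p
wavelengths; a single monochrome frame of a scene is then decoded into any
(z, λ) channel by correlating it with the matching library entry.  Two
physical shortcuts shrink the training effort:

* depth–wavelength reciprocity — the paraxial pattern depends on the
  products λu and λv only, so scaling distances and wavelength inversely
  leaves it unchanged ("colour from depth and depth from colour");
* PSF synthesis — nearby library entries differ mainly by an isotropic
  magnification γ, measured at the axial/spectral boundaries and linearly
  interpolated, so four corner recordings generate the whole library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage as ndi
import tifffile

from .optics import IntensityPattern, OpticalConfig, simulate_psf
from .recon import (FilterParams, ReconImage, ncc_peak, reconstruct_pipeline,
                    whitened_ncc_peak)

__all__ = [
    "LibraryKey",
    "PSFLibrary",
    "extract_channel",
    "scale_pattern",
    "estimate_gamma",
    "interpolate_gamma",
    "synthesize_library",
    "reciprocity_transform",
    "reciprocity_scan",
]


@dataclass(frozen=True, order=True)
class LibraryKey:
    """Index of one library entry: axial coordinate (meters) and wavelength."""

    z: float
    wavelength: float


class PSFLibrary:
    """Mapping (z, λ) → chaotic PSF, with per-entry provenance.

    ``z`` may be an absolute source distance or an offset Δu — whichever
    the caller catalogues; the manifest stores it in millimetres under
    ``du_mm``.  All entries must share shape and pitch.
    """

    def __init__(self, u: float | None = None, v: float | None = None):
        self.u = u
        self.v = v
        self.entries: dict[LibraryKey, IntensityPattern] = {}
        self.provenance: dict[LibraryKey, str] = {}
        self.quality: dict[LibraryKey, float] = {}

    def add(self, z: float, wavelength: float, pattern: IntensityPattern,
            provenance: str = "measured", quality: float | None = None) -> LibraryKey:
        key = LibraryKey(float(z), float(wavelength))
        if self.entries:
            ref = next(iter(self.entries.values()))
            if pattern.values.shape != ref.values.shape or pattern.pitch != ref.pitch:
                raise ValueError("all library entries must share shape and pitch")
        self.entries[key] = pattern
        self.provenance[key] = provenance
        if quality is not None:
            self.quality[key] = quality
        return key

    @property
    def z_values(self) -> list[float]:
        return sorted({k.z for k in self.entries})

    @property
    def wavelength_values(self) -> list[float]:
        return sorted({k.wavelength for k in self.entries})

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def _axis_tolerance(axis: list[float]) -> float:
        if len(axis) < 2:
            return np.inf
        return min(np.diff(axis)) / 2

    def lookup(self, z: float, wavelength: float) -> IntensityPattern:
        """Entry at (z, λ), or the nearest within half a grid step."""
        key = LibraryKey(float(z), float(wavelength))
        if key in self.entries:
            return self.entries[key]
        zs, ls = self.z_values, self.wavelength_values
        if not zs:
            raise KeyError("library is empty")
        ztol = self._axis_tolerance(zs)
        ltol = self._axis_tolerance(ls)
        zn = min(zs, key=lambda a: abs(a - z))
        ln = min(ls, key=lambda a: abs(a - wavelength))
        if abs(zn - z) > ztol or abs(ln - wavelength) > ltol:
            raise KeyError(
                f"({z}, {wavelength}) outside library bounds/tolerance "
                f"(z axis {zs}, λ axis {ls})")
        return self.entries[LibraryKey(zn, ln)]

    # -- persistence: directory of TIFF frames + JSON manifest ------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "u_mm": None if self.u is None else self.u * 1e3,
            "v_mm": None if self.v is None else self.v * 1e3,
            "axes": {"du_mm": [z * 1e3 for z in self.z_values],
                     "lambda_nm": [w * 1e9 for w in self.wavelength_values]},
            "entries": [],
        }
        for i, (key, pat) in enumerate(sorted(self.entries.items())):
            fname = f"psf_{i:04d}.tif"
            tifffile.imwrite(directory / fname, pat.values)
            manifest["entries"].append({
                "du_mm": key.z * 1e3,
                "lambda_nm": key.wavelength * 1e9,
                "file": fname,
                "provenance": self.provenance.get(key, "measured"),
                "quality": self.quality.get(key),
                "pitch_um": pat.pitch * 1e6,
            })
        path = directory / "library.json"
        path.write_text(json.dumps(manifest, indent=2))
        return path

    @classmethod
    def load(cls, directory: str | Path) -> "PSFLibrary":
        directory = Path(directory)
        manifest = json.loads((directory / "library.json").read_text())
        u = manifest.get("u_mm")
        v = manifest.get("v_mm")
        lib = cls(u=None if u is None else u / 1e3,
                  v=None if v is None else v / 1e3)
        for ent in manifest["entries"]:
            values = tifffile.imread(directory / ent["file"])
            z = ent["du_mm"] / 1e3
            lam = ent["lambda_nm"] / 1e9
            pat = IntensityPattern(values, pitch=ent["pitch_um"] / 1e6,
                                   wavelength=lam, z=None, du=z, role="psf")
            lib.add(z, lam, pat, provenance=ent.get("provenance", "measured"),
                    quality=ent.get("quality"))
        return lib


def extract_channel(i_obj, library: PSFLibrary, key: tuple[float, float],
                    params: FilterParams | None = None) -> ReconImage:
    """Decode one (z, λ) channel from a single monochrome frame."""
    z, lam = key
    psf = library.lookup(z, lam)
    rec = reconstruct_pipeline(i_obj, psf, params)
    rec.provenance["library_key"] = (z, lam)
    return rec


def scale_pattern(pattern, gamma: float):
    """Isotropic rescale about the grid center (the optical axis) by γ.

    Bilinear interpolation; output keeps the input shape, with uncovered
    edges zero-filled (γ < 1) or content cropped (γ > 1).
    """
    if not 0.5 <= gamma <= 2.0:
        raise ValueError("gamma must lie in [0.5, 2]")
    v = np.asarray(getattr(pattern, "values", pattern), dtype=float)
    center = np.array([s // 2 for s in v.shape], dtype=float)
    out = ndi.affine_transform(v, np.array([1 / gamma, 1 / gamma]),
                               offset=center * (1 - 1 / gamma), order=1,
                               mode="constant", cval=0.0)
    if isinstance(pattern, IntensityPattern):
        return IntensityPattern(np.maximum(out, 0.0), pitch=pattern.pitch,
                                wavelength=pattern.wavelength, z=pattern.z,
                                du=pattern.du, role=pattern.role,
                                meta={**pattern.meta, "gamma": gamma})
    return out


def estimate_gamma(i_a, i_b, gamma_range: tuple[float, float] = (0.8, 1.25),
                   steps: int = 21, tol: float = 1e-4) -> float:
    """γ* maximizing the correlation peak of scale(I_a, γ) against I_b.

    Coarse grid over ``gamma_range`` followed by golden-section refinement
    of the bracketing interval down to ``tol``.
    """
    lo, hi = gamma_range
    if not (0.5 <= lo < hi <= 2.0):
        raise ValueError("gamma_range must be increasing and within [0.5, 2]")
    a = np.asarray(getattr(i_a, "values", i_a), dtype=float)
    b = np.asarray(getattr(i_b, "values", i_b), dtype=float)

    def score(g: float) -> float:
        return ncc_peak(scale_pattern(a, g), b)

    grid = np.linspace(lo, hi, steps)
    vals = np.array([score(g) for g in grid])
    if vals.max() <= 0 or (vals.max() - vals.min()) < 1e-6 * max(vals.max(), 1e-300):
        raise ValueError("flat correlation landscape; gamma is unidentifiable")
    i = int(np.argmax(vals))
    x1, x4 = grid[max(i - 1, 0)], grid[min(i + 1, steps - 1)]
    invphi = (np.sqrt(5) - 1) / 2
    x2 = x4 - invphi * (x4 - x1)
    x3 = x1 + invphi * (x4 - x1)
    f2, f3 = score(x2), score(x3)
    while x4 - x1 > tol:
        if f2 >= f3:
            x4, x3, f3 = x3, x2, f2
            x2 = x4 - invphi * (x4 - x1)
            f2 = score(x2)
        else:
            x1, x2, f2 = x2, x3, f3
            x3 = x1 + invphi * (x4 - x1)
            f3 = score(x3)
    return float((x1 + x4) / 2)


def interpolate_gamma(anchors: Sequence[tuple[float, float]], query: float) -> float:
    """Linear fit of γ versus a coordinate (Δu or λ) through two anchors."""
    (c1, g1), (c2, g2) = anchors
    if c1 == c2:
        raise ValueError("anchor coordinates must be distinct")
    t = (query - c1) / (c2 - c1)
    return float(g1 + t * (g2 - g1))


def _corner_set(z_axis: Sequence[float], lambda_axis: Sequence[float]):
    z0, z1 = min(z_axis), max(z_axis)
    l0, l1 = min(lambda_axis), max(lambda_axis)
    return z0, z1, l0, l1


def synthesize_library(corners: Mapping[tuple[float, float], IntensityPattern],
                       z_axis: Sequence[float], lambda_axis: Sequence[float],
                       gamma_range: tuple[float, float] = (0.8, 1.25),
                       u: float | None = None, v: float | None = None
                       ) -> PSFLibrary:
    """Build a full (z, λ) library from the 4 boundary recordings.

    ``corners`` maps the four (z, λ) rectangle corners to measured PSFs.
    Magnification factors γ are estimated along the two axial and two
    spectral edges; each interior entry is synthesized by rescaling the
    nearest corner with γ obtained by bilinear interpolation of the edge
    estimates (γ ≡ 1 at the corner itself).  Synthesized entries carry a
    quality score: correlation peak against their source corner.
    """
    z0, z1, l0, l1 = _corner_set(z_axis, lambda_axis)
    required = {(z0, l0), (z0, l1), (z1, l0), (z1, l1)}
    missing = required - set(corners)
    if missing:
        raise ValueError(f"missing corner recording(s): {sorted(missing)}")

    lib = PSFLibrary(u=u, v=v)
    for (z, lam) in required:
        lib.add(z, lam, corners[(z, lam)], provenance="measured")

    targets = [(float(z), float(lam)) for z in z_axis for lam in lambda_axis
               if (float(z), float(lam)) not in required]
    if not targets:
        return lib

    # edge magnifications: z0→z1 at each λ corner, l0→l1 at each z corner
    g_z = {l0: estimate_gamma(corners[(z0, l0)], corners[(z1, l0)], gamma_range),
           l1: estimate_gamma(corners[(z0, l1)], corners[(z1, l1)], gamma_range)}
    g_l = {z0: estimate_gamma(corners[(z0, l0)], corners[(z0, l1)], gamma_range),
           z1: estimate_gamma(corners[(z1, l0)], corners[(z1, l1)], gamma_range)}

    for z, lam in targets:
        tz = 0.0 if z1 == z0 else (z - z0) / (z1 - z0)
        tl = 0.0 if l1 == l0 else (lam - l0) / (l1 - l0)
        zc = z0 if tz <= 0.5 else z1
        lc = l0 if tl <= 0.5 else l1
        # γ along z at this λ, interpolated between the two edge estimates
        gz_edge = interpolate_gamma(((l0, g_z[l0]), (l1, g_z[l1])), lam)
        gl_edge = interpolate_gamma(((z0, g_l[z0]), (z1, g_l[z1])), z)
        z_far = z1 if zc == z0 else z0
        l_far = l1 if lc == l0 else l0
        gz_full = gz_edge if zc == z0 else 1.0 / gz_edge
        gl_full = gl_edge if lc == l0 else 1.0 / gl_edge
        gamma = (interpolate_gamma(((zc, 1.0), (z_far, gz_full)), z)
                 * interpolate_gamma(((lc, 1.0), (l_far, gl_full)), lam))
        src = corners[(zc, lc)]
        pat = scale_pattern(src, gamma)
        lib.add(z, lam, pat, provenance="synthesized",
                quality=ncc_peak(pat, src))
    return lib


def reciprocity_transform(u: float, v: float, lambda_from: float,
                          lambda_to: float) -> tuple[float, float]:
    """Distances reproducing at λ_to the pattern recorded at (u, v, λ_from).

    The chaotic pattern depends on λu and λv only, so
    (u', v') = (λ_from/λ_to)·(u, v) preserves both products.
    """
    if min(u, v, lambda_from, lambda_to) <= 0:
        raise ValueError("all reciprocity arguments must be positive")
    s = lambda_from / lambda_to
    return u * s, v * s


def reciprocity_scan(config: OpticalConfig, mask, uv_values: Sequence[float],
                     lambda_values: Sequence[float],
                     reference_key: tuple[float, float],
                     fixed_v: bool = False) -> np.ndarray:
    """Map of correlation peaks against a reference PSF over a (u, λ) grid.

    Joint scan (``fixed_v=False``, v = u everywhere): maxima form a comb
    along λ·u = λ_ref·u_ref.  Fixed-v scan: the only maximum is the
    reference itself — reciprocity needs u and v scaled together.  Peaks
    are measured on the whitened (phase) spectra; the returned array is
    indexed [uv, λ] with the reference grid point at 1.
    """
    if not len(uv_values) or not len(lambda_values):
        raise ValueError("scan grids must be non-empty")
    u_ref, lam_ref = reference_key
    v_ref = config.v if fixed_v else u_ref
    ref_cfg = replace(config, u=u_ref, v=v_ref, wavelength=lam_ref)
    ref = simulate_psf(ref_cfg, mask)
    out = np.zeros((len(uv_values), len(lambda_values)))
    for i, uv in enumerate(uv_values):
        for j, lam in enumerate(lambda_values):
            if uv == u_ref and lam == lam_ref:
                out[i, j] = 1.0
                continue
            cfg = replace(config, u=uv, v=config.v if fixed_v else uv,
                          wavelength=lam)
            out[i, j] = whitened_ncc_peak(simulate_psf(cfg, mask), ref)
    return out
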