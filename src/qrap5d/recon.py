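"""Correlation-based image reconstruction.

A lensless frame recorded through a random pinhole array is the object
convolved with the chaotic point-spread intensity, ``I_O = O ⊗ I_PSF``.
The object estimate is recovered by cross-correlating the frame with the
PSF, ``O' = I_O * I_PSF = O ⊗ Λ``, where Λ (the PSF autocorrelation) is
delta-like for a well-tailored chaotic wave.  This module implements the
matched, phase-only and tunable nonlinear correlation filters, the
entropy criterion used to pick the nonlinear exponents, and the
post-filter sequence (low-pass → spectrum-domain weighting → nonlinear
correlation → median).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft as fft
import scipy.ndimage as ndi

__all__ = [
    "FilterParams",
    "ReconImage",
    "cross_correlate",
    "nonlinear_correlation",
    "entropy",
    "search_filter_params",
    "lowpass_filter",
    "median_filter",
    "spectrum_domain_filter",
    "reconstruct_pipeline",
    "ncc_peak",
    "whitened_ncc_peak",
    "peak_snr",
]


@dataclass
class FilterParams:
    """Reconstruction-filter parameters.

    ``alpha`` acts on the PSF spectral magnitude, ``beta`` on the object
    spectral magnitude; (1, 1) is a matched filter and (0, 1) a
    phase-only filter.  The published operating point is (0, 0.6).
    Stages of :func:`reconstruct_pipeline` are disabled by their neutral
    values (``lowpass_cutoff=1``, ``median_kernel=1``,
    ``spectrum_filter_strength=0``).
    """

    alpha: float = 0.0
    beta: float = 0.6
    lowpass_cutoff: float = 1.0
    median_kernel: int = 1
    spectrum_filter_strength: float = 0.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.alpha <= 1.0 and -1.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [-1, 1]")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if not (0.0 < self.lowpass_cutoff <= 1.0):
            raise ValueError("lowpass_cutoff must lie in (0, 1]")


@dataclass
class ReconImage:
    """Reconstruction magnitude |C| with provenance of how it was made."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("reconstruction must be a 2D grid")
        if np.any(self.values < 0):
            raise ValueError("reconstruction magnitude must be non-negative")

    @property
    def peak(self) -> float:
        return float(self.values.max())

    @property
    def peak_index(self) -> tuple[int, int]:
        idx = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return int(idx[0]), int(idx[1])


def _values(x) -> np.ndarray:
    v = np.asarray(getattr(x, "values", x), dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a 2D intensity grid")
    return v


def _signed_power(mag: np.ndarray, expo: float) -> np.ndarray:
    """|F|^expo with zero-magnitude bins mapped to zero (they carry no phase)."""
    out = np.zeros_like(mag)
    nz = mag > 0
    out[nz] = mag[nz] ** expo
    return out


def _correlate_spectra(a: np.ndarray, b: np.ndarray, alpha: float, beta: float,
                       pad: bool) -> np.ndarray:
    """Core nonlinear correlation of mean-removed patterns a (object) and b (PSF).

    Returns |IFT{ |F_b|^alpha e^{-i arg F_b} |F_a|^beta e^{+i arg F_a} }|
    with the zero-lag term at the (n//2, m//2) pixel.  ``pad`` doubles the
    transform size (linear, wrap-free correlation) before cropping back.
    """
    r, c = a.shape
    if pad:
        a = np.pad(a, ((0, r), (0, c)))
        b = np.pad(b, ((0, r), (0, c)))
    fa = fft.fft2(a)
    fb = fft.fft2(b)
    term_o = _signed_power(np.abs(fa), beta) * np.exp(1j * np.angle(fa))
    term_p = _signed_power(np.abs(fb), alpha) * np.exp(-1j * np.angle(fb))
    corr = np.abs(fft.fftshift(fft.ifft2(term_o * term_p)))
    if pad:
        corr = corr[r - r // 2: 2 * r - r // 2, c - c // 2: 2 * c - c // 2]
    return corr


def nonlinear_correlation(i_obj, i_psf, alpha: float, beta: float,
                          pad: bool = True) -> ReconImage:
    """Nonlinear cross-correlation with tunable spectral-magnitude exponents.

    The means of both patterns are removed first, emulating correlation of
    bipolar functions, which suppresses the background pedestal.  (1, 1)
    reduces exactly to the matched filter and (0, 1) to the phase-only
    filter.
    """
    a = _values(i_obj)
    b = _values(i_psf)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    corr = _correlate_spectra(a - a.mean(), b - b.mean(), alpha, beta, pad)
    return ReconImage(corr, provenance={"alpha": alpha, "beta": beta, "pad": pad})


def cross_correlate(i_obj, i_psf, kind: str = "matched", pad: bool = True) -> ReconImage:
    """Conventional correlation filters, computed directly.

    ``matched``: |IFT{F_O · conj(F_PSF)}|;  ``phase_only``: the PSF
    spectrum is reduced to its phase, F_PSF/|F_PSF| (zero-magnitude bins
    pass zero).  Means are removed first, as everywhere in this module.
    These are the (1, 1) and (0, 1) special cases of
    :func:`nonlinear_correlation` and serve as its algebraic cross-check.
    """
    if kind not in ("matched", "phase_only"):
        raise ValueError(f"unknown correlation kind: {kind!r}")
    a = _values(i_obj)
    b = _values(i_psf)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    r, c = a.shape
    if pad:
        a = np.pad(a, ((0, r), (0, c)))
        b = np.pad(b, ((0, r), (0, c)))
    fa = fft.fft2(a)
    fb = fft.fft2(b)
    if kind == "matched":
        spec = fa * np.conj(fb)
    else:
        mag = np.abs(fb)
        filt = np.zeros_like(fb)
        nz = mag > 0
        filt[nz] = np.conj(fb[nz]) / mag[nz]
        spec = fa * filt
    corr = np.abs(fft.fftshift(fft.ifft2(spec)))
    if pad:
        corr = corr[r - r // 2: 2 * r - r // 2, c - c // 2: 2 * c - c // 2]
    return ReconImage(corr, provenance={"kind": kind, "pad": pad})


def _window_slices(shape: tuple[int, int], center: tuple[int, int],
                   size: int) -> tuple[slice, slice]:
    r0 = min(max(center[0] - size // 2, 0), shape[0] - size)
    c0 = min(max(center[1] - size // 2, 0), shape[1] - size)
    return slice(r0, r0 + size), slice(c0, c0 + size)


def entropy(image, window: int | tuple[slice, slice] | None = None) -> float:
    """Shannon entropy −Σ φ log φ of the normalized window, in nats.

    ``window`` may be None (whole image), an odd/even box size centred on
    the global peak, or an explicit pair of slices.  Bounds:
    0 ≤ S ≤ log(window pixel count).
    """
    v = _values(image)
    if window is None:
        w = v
    elif isinstance(window, int):
        if window > min(v.shape):
            raise ValueError("window does not fit inside the image")
        peak = np.unravel_index(int(np.argmax(v)), v.shape)
        sr, sc = _window_slices(v.shape, peak, window)
        w = v[sr, sc]
    else:
        w = v[window]
        if w.size == 0:
            raise ValueError("window outside image")
    total = w.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero window")
    phi = w / total
    phi = phi[phi > 0]  # 0·log 0 := 0 (also guards underflow)
    return float(-np.sum(phi * np.log(phi)))


def search_filter_params(i_obj, i_psf, alpha_grid: Sequence[float],
                         beta_grid: Sequence[float], window: int = 32) -> FilterParams:
    """Grid search for the (α, β) minimizing reconstruction entropy.

    Lower entropy in a window around the correlation peak means a more
    delta-like reconstruction (energy concentrated in the signal), which
    is the recipe used to select the nonlinear-filter operating point.
    Ties break to the smallest α, then the smallest β.
    """
    alphas = sorted(set(float(a) for a in alpha_grid))
    betas = sorted(set(float(b) for b in beta_grid))
    if not alphas or not betas:
        raise ValueError("parameter grids must be non-empty")
    best = None
    for a in alphas:
        for b in betas:
            rec = nonlinear_correlation(i_obj, i_psf, a, b)
            s = entropy(rec.values, window)
            if best is None or s < best[0]:
                best = (s, a, b)
    _, a, b = best
    return FilterParams(alpha=a, beta=b)


def lowpass_filter(image, cutoff: float) -> np.ndarray:
    """Circular low-pass at ``cutoff`` × Nyquist (cycles/sample radius).

    ``cutoff >= 1`` returns the image unchanged (a circular mask at the
    full Nyquist radius would clip the spectrum corners).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must lie in (0, 1]")
    v = _values(image)
    if cutoff >= 1.0:
        return v.copy()
    fy = fft.fftfreq(v.shape[0])
    fx = fft.fftfreq(v.shape[1])
    rho = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    keep = rho <= cutoff * 0.5
    return fft.ifft2(fft.fft2(v) * keep).real


def median_filter(image, kernel: int) -> np.ndarray:
    """Rank (median) filter with edge replication; kernel must be odd."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    v = _values(image)
    if kernel == 1:
        return v.copy()
    return ndi.median_filter(v, size=kernel, mode="nearest")


def spectrum_weights(i_obj, i_psf, smooth_bins: float = 2.0) -> np.ndarray:
    """Band-wise agreement w ∈ [0, 1] between the two spectral magnitudes.

    w is a local (Gaussian-smoothed) cosine similarity of |F_O| and
    |F_PSF|: S(|F_O||F_PSF|) / √(S(|F_O|²)·S(|F_PSF|²)).  Identical
    patterns give w = 1 everywhere; bands where the frame carries energy
    the PSF cannot explain (or vice versa) are weighted down.
    """
    a = _values(i_obj)
    b = _values(i_psf)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    ma = np.abs(fft.fft2(a - a.mean()))
    mb = np.abs(fft.fft2(b - b.mean()))
    smooth = lambda x: ndi.gaussian_filter(x, sigma=smooth_bins, mode="wrap")
    num = smooth(ma * mb)
    den = np.sqrt(smooth(ma ** 2) * smooth(mb ** 2))
    w = np.ones_like(num)
    nz = den > 0
    w[nz] = np.clip(num[nz] / den[nz], 0.0, 1.0)
    return w


def spectrum_domain_filter(i_obj, i_psf, strength: float) -> np.ndarray:
    """Re-weight the object spectrum by w^strength (w from :func:`spectrum_weights`).

    strength = 0 is the identity; larger strengths suppress spectral bands
    on which the frame and the PSF disagree, lowering correlation
    background from out-of-model content.
    """
    if strength < 0 or strength > 1:
        raise ValueError("strength must lie in [0, 1]")
    v = _values(i_obj)
    if strength == 0:
        return v.copy()
    w = spectrum_weights(i_obj, i_psf) ** strength
    return fft.ifft2(fft.fft2(v) * w).real


def reconstruct_pipeline(i_obj, i_psf, params: FilterParams | None = None) -> ReconImage:
    """Full reconstruction chain for one (depth, wavelength) channel.

    Order: low-pass filter (both patterns) → spectrum-domain weighting of
    the frame → nonlinear correlation (α, β) → median filter on |C|.
    Stages at their neutral parameter values are skipped, so defaults with
    α = β = 1 reproduce a plain matched filter.
    """
    params = params or FilterParams()
    a = _values(i_obj)
    b = _values(i_psf)
    if params.lowpass_cutoff < 1.0:
        a = lowpass_filter(a, params.lowpass_cutoff)
        b = lowpass_filter(b, params.lowpass_cutoff)
    if params.spectrum_filter_strength > 0:
        a = spectrum_domain_filter(a, b, params.spectrum_filter_strength)
    rec = nonlinear_correlation(a, b, params.alpha, params.beta)
    values = rec.values
    if params.median_kernel > 1:
        values = median_filter(values, params.median_kernel)
    prov = dict(rec.provenance)
    prov.update(lowpass_cutoff=params.lowpass_cutoff,
                median_kernel=params.median_kernel,
                spectrum_filter_strength=params.spectrum_filter_strength)
    return ReconImage(values, provenance=prov)


# ---------------------------------------------------------------------------
# correlation metrics shared across modules


def ncc_peak(a, b) -> float:
    """Peak of the mean-removed, energy-normalized linear cross-correlation.

    Bounded by 1 (Cauchy–Schwarz) and exactly 1 for identical patterns.
    """
    av = _values(a)
    bv = _values(b)
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt(np.sum(av ** 2) * np.sum(bv ** 2))
    if denom == 0:
        return 0.0
    corr = _correlate_spectra(av, bv, 1.0, 1.0, pad=True)
    return float(corr.max() / denom)


def whitened_ncc_peak(a, b) -> float:
    """Peak correlation of the two phase spectra (magnitudes whitened away).

    The smooth diffraction envelope of a chaotic pattern is nearly
    independent of depth and wavelength; channel discrimination lives in
    the speckle phase.  Correlating the pure phase spectra (both
    magnitude exponents zero) measures exactly that: 1 for identical
    patterns, near 0 for decorrelated speckle.  Bounded by 1.
    """
    av = _values(a)
    bv = _values(b)
    cab = _correlate_spectra(av - av.mean(), bv - bv.mean(), 0.0, 0.0, pad=True)
    caa = _correlate_spectra(av - av.mean(), av - av.mean(), 0.0, 0.0, pad=True)
    cbb = _correlate_spectra(bv - bv.mean(), bv - bv.mean(), 0.0, 0.0, pad=True)
    denom = np.sqrt(caa.max() * cbb.max())
    if denom == 0:
        return 0.0
    return float(cab.max() / denom)


def peak_snr(recon, exclude_radius: int = 10,
             at: tuple[int, int] | None = None) -> float:
    """Correlation-peak SNR: peak over background σ outside an exclusion disc.

    Background mean is removed from the peak; a strictly flat field scores
    0 and an ideal delta on a zero background scores +inf.  ``at`` scores
    a specific pixel instead of the global peak — e.g. to quantify
    cross-talk at a known channel location in a wrong-key reconstruction.
    """
    v = _values(recon)
    if at is None:
        pr, pc = np.unravel_index(int(np.argmax(v)), v.shape)
    else:
        pr, pc = at
    yy, xx = np.ogrid[: v.shape[0], : v.shape[1]]
    bg = v[(yy - pr) ** 2 + (xx - pc) ** 2 > exclude_radius ** 2]
    if bg.size < 2:
        raise ValueError("exclusion disc leaves no background pixels")
    sigma = bg.std()
    peak = float(v[pr, pc] - bg.mean())
    if sigma == 0:
        return np.inf if peak > 0 else 0.0
    return peak / sigma


def curve_fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a sampled curve, by linear interpolation.

    The curve is assumed single-peaked around its global maximum; the
    half-max crossings nearest the peak on each side are interpolated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = x[0]
    for j in range(i, 0, -1):
        if y[j - 1] <= half:
            t = (half - y[j - 1]) / (y[j] - y[j - 1])
            left = x[j - 1] + t * (x[j] - x[j - 1])
            break
    right = x[-1]
    for j in range(i, len(y) - 1):
        if y[j + 1] <= half:
            t = (half - y[j + 1]) / (y[j] - y[j + 1])
            right = x[j + 1] + t * (x[j] - x[j + 1])
            break
    return float(right - left)
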