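"""Quasi-random pinhole array (QRAP) generation and tailoring.

A random array of pinholes (RAP) already images — its chaotic wave encodes
the scene — but the correlation background depends strongly on where the
holes sit.  Tailoring proceeds in two layers: layer 1 draws many random
arrays and keeps the one whose simulated point reconstruction has the
highest peak-to-background SNR; layer 2 greedily nudges every pinhole by a
fixed step along x and y, accepting only strict SNR improvements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PinholeArray",
    "OptimizationReport",
    "PackingError",
    "generate_rap",
    "rasterize_mask",
    "rasterize_onto",
    "snr_objective",
    "optimize_layer1",
    "optimize_layer2",
]


class PackingError(RuntimeError):
    """Raised when the requested pinhole count cannot be packed."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could not place {requested} non-overlapping pinholes "
            f"(achieved {achieved}); reduce count or diameter")
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class PinholeArray:
    """Pinhole centers (meters, mask-centered coords), diameter and extent.

    ``diameter`` (the mask aperture D entering the resolution formulas
    1.22λu/D and 8λ(u/D)²) is the maximum chord of the extent.
    """

    centers: np.ndarray            # (n, 2) array of (x, y) in meters
    pinhole_diameter: float
    extent: tuple[float, float]    # (width, height) in meters

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "centers", centers)
        if self.pinhole_diameter <= 0:
            raise ValueError("pinhole_diameter must be positive")
        w, h = self.extent
        r = self.pinhole_diameter / 2
        if centers.size:
            if (np.any(np.abs(centers[:, 0]) > w / 2 - r + 1e-12)
                    or np.any(np.abs(centers[:, 1]) > h / 2 - r + 1e-12)):
                raise ValueError("pinhole extends outside the mask extent")
            if centers.shape[0] > 1 and self.min_separation() < self.pinhole_diameter - 1e-12:
                raise ValueError("pinholes overlap (center distance < diameter)")

    @property
    def n(self) -> int:
        return 0 if self.centers.size == 0 else self.centers.shape[0]

    @property
    def diameter(self) -> float:
        """Mask diameter D: the maximum chord of the extent."""
        return float(np.hypot(*self.extent))

    @property
    def fill_factor(self) -> float:
        area = self.extent[0] * self.extent[1]
        return self.n * np.pi * (self.pinhole_diameter / 2) ** 2 / area

    def min_separation(self) -> float:
        c = self.centers
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        d[np.diag_indices(len(c))] = np.inf
        return float(d.min())


@dataclass
class OptimizationReport:
    """Per-evaluation SNR trace and bookkeeping for one optimization stage."""

    trace: list[float] = field(default_factory=list)
    accepted_moves: int = 0
    seeds: list[int] = field(default_factory=list)
    best_snr: float = -np.inf


def _fits(xy: np.ndarray, accepted: list[np.ndarray], diameter: float) -> bool:
    if not accepted:
        return True
    d = np.linalg.norm(np.asarray(accepted) - xy, axis=1)
    return bool(d.min() >= diameter)


def generate_rap(n: int, extent: tuple[float, float], diameter: float,
                 seed: int) -> PinholeArray:
    """Draw a random array of ``n`` non-overlapping pinholes.

    Two independent random streams (derived from the master seed) supply
    the x and y coordinates; placements closer than one pinhole diameter
    to an accepted hole are rejected.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w, h = extent
    fill = n * np.pi * (diameter / 2) ** 2 / (w * h)
    if fill >= 0.5:
        raise ValueError(f"requested fill factor {fill:.2f} >= 0.5 is infeasible")
    rng_x, rng_y = np.random.SeedSequence(seed).spawn(2)
    rng_x, rng_y = np.random.default_rng(rng_x), np.random.default_rng(rng_y)
    r = diameter / 2
    accepted: list[np.ndarray] = []
    max_attempts = max(10_000, 500 * n)
    attempts = 0
    while len(accepted) < n and attempts < max_attempts:
        attempts += 1
        xy = np.array([rng_x.uniform(-w / 2 + r, w / 2 - r),
                       rng_y.uniform(-h / 2 + r, h / 2 - r)])
        if _fits(xy, accepted, diameter):
            accepted.append(xy)
    if len(accepted) < n:
        raise PackingError(n, len(accepted))
    return PinholeArray(np.array(accepted), diameter, (w, h))


def rasterize_mask(mask: PinholeArray, pitch: float) -> np.ndarray:
    """Binary raster of the mask on a grid just covering its extent.

    Requires pitch ≤ diameter/4 so each pinhole spans at least 4 samples.
    """
    if pitch > mask.pinhole_diameter / 4:
        raise ValueError(
            f"pitch {pitch:g} too coarse; need <= diameter/4 = "
            f"{mask.pinhole_diameter / 4:g}")
    n = int(np.ceil(max(mask.extent) / pitch)) + 1
    return rasterize_onto(mask, n, pitch, check_pitch=False)


def rasterize_onto(mask: PinholeArray, n: int, pitch: float,
                   check_pitch: bool = True) -> np.ndarray:
    """Binary raster of the mask centered on an n×n grid of the given pitch."""
    if check_pitch and pitch > mask.pinhole_diameter / 4:
        raise ValueError("pitch too coarse for the pinhole diameter")
    if max(mask.extent) > n * pitch:
        raise ValueError("mask extent exceeds the simulation grid")
    grid = np.zeros((n, n), dtype=float)
    coords = (np.arange(n) - n // 2) * pitch
    r = mask.pinhole_diameter / 2
    half = int(np.ceil(r / pitch)) + 1
    for cx, cy in mask.centers:
        ix = int(round(cx / pitch)) + n // 2
        iy = int(round(cy / pitch)) + n // 2
        ys = slice(max(iy - half, 0), min(iy + half + 1, n))
        xs = slice(max(ix - half, 0), min(ix + half + 1, n))
        yy = coords[ys][:, None] - cy
        xx = coords[xs][None, :] - cx
        grid[ys, xs] = np.maximum(grid[ys, xs], (yy ** 2 + xx ** 2 <= r ** 2) * 1.0)
    return grid


def snr_objective(mask: PinholeArray, config, recon_params=None,
                  exclude_radius: int = 8) -> float:
    """Reconstruction SNR of an on-axis point source through the mask.

    Simulates the chaotic PSF, reconstructs the point against the same
    PSF with the nonlinear filter, and scores peak / σ(background outside
    an exclusion disc).  Deterministic for a fixed configuration.
    """
    from . import optics, recon

    params = recon_params or recon.FilterParams()
    psf = optics.simulate_psf(config, mask)
    rec = recon.nonlinear_correlation(psf, psf, params.alpha, params.beta)
    return recon.peak_snr(rec, exclude_radius=exclude_radius)


def optimize_layer1(mask_params: dict, config, n_candidates: int = 1000,
                    seed: int = 0, recon_params=None
                    ) -> tuple[PinholeArray, OptimizationReport]:
    """Layer-1 search: best-of-``n_candidates`` random arrays by SNR.

    Candidate i always uses the seed derived from (seed, i), so the winner
    for a larger candidate budget is a prefix-max of the same stream.
    ``mask_params`` carries ``n``, ``extent`` and ``diameter`` for
    :func:`generate_rap`.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    report = OptimizationReport(seeds=[seed])
    best_mask = None
    for i in range(n_candidates):
        child = np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0]
        cand = generate_rap(mask_params["n"], mask_params["extent"],
                            mask_params["diameter"], seed=int(child) % (2 ** 31))
        snr = snr_objective(cand, config, recon_params)
        report.trace.append(snr)
        if snr > report.best_snr:
            report.best_snr = snr
            best_mask = cand
            report.accepted_moves += 1
    return best_mask, report


def _valid_position(centers: np.ndarray, idx: int, xy: np.ndarray,
                    mask: PinholeArray) -> bool:
    w, h = mask.extent
    r = mask.pinhole_diameter / 2
    if abs(xy[0]) > w / 2 - r or abs(xy[1]) > h / 2 - r:
        return False
    others = np.delete(centers, idx, axis=0)
    if others.size == 0:
        return True
    return bool(np.linalg.norm(others - xy, axis=1).min() >= mask.pinhole_diameter)


def optimize_layer2(mask: PinholeArray, config, step: float,
                    max_iters: int = 10_000, seed: int = 0, recon_params=None
                    ) -> tuple[PinholeArray, OptimizationReport]:
    """Layer-2 greedy refinement: per-pinhole ±step moves along x and y.

    Pinholes are visited in index order, trying +x, −x, +y, −y in turn;
    a move is accepted only if the SNR strictly increases and the
    non-overlap/extent constraints hold (ties keep the incumbent).  Each
    SNR evaluation counts one iteration; the search stops at ``max_iters``
    evaluations or after a full pass with no accepted move.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    centers = mask.centers.copy()
    current = replace(mask, centers=centers)
    snr = snr_objective(current, config, recon_params)
    report = OptimizationReport(trace=[snr], accepted_moves=0, seeds=[seed],
                                best_snr=snr)
    moves = np.array([[step, 0.0], [-step, 0.0], [0.0, step], [0.0, -step]])
    evals = 0
    improved = True
    while improved and evals < max_iters:
        improved = False
        for idx in range(current.n):
            for mv in moves:
                if evals >= max_iters:
                    break
                cand_xy = current.centers[idx] + mv
                if not _valid_position(current.centers, idx, cand_xy, current):
                    continue
                cand_centers = current.centers.copy()
                cand_centers[idx] = cand_xy
                cand = replace(current, centers=cand_centers)
                cand_snr = snr_objective(cand, config, recon_params)
                evals += 1
                if cand_snr > snr:
                    current, snr = cand, cand_snr
                    report.accepted_moves += 1
                    improved = True
                report.trace.append(snr)
    report.best_snr = snr
    return current, report
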