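"""Correlation filters, entropy criterion and the reconstruction pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


from qrap5d.recon import (FilterParams, cross_correlate, entropy,
                          lowpass_filter, median_filter,
                          nonlinear_correlation, peak_snr,
                          reconstruct_pipeline, search_filter_params,
                          spectrum_domain_filter, spectrum_weights)

images = hnp.arrays(np.float64, (16, 16),
                    elements=st.floats(0.0, 100.0, allow_nan=False))


def _brute_force_matched(a, b):
    """Double-loop linear correlation of mean-removed patterns.

    Independent oracle: C[dr, dc] = Σ a[i, j]·b[i−dr, j−dc] with zero
    outside, laid out with zero lag at the (n//2, m//2) pixel.
    """
    a = a - a.mean()
    b = b - b.mean()
    r, c = a.shape
    out = np.zeros((r, c))
    for dr in range(-(r // 2), r - r // 2):
        for dc in range(-(c // 2), c - c // 2):
            s = 0.0
            for i in range(r):
                for j in range(c):
                    ii, jj = i - dr, j - dc
                    if 0 <= ii < r and 0 <= jj < c:
                        s += a[i, j] * b[ii, jj]
            out[dr + r // 2, dc + c // 2] = s
    return np.abs(out)


class TestCrossCorrelate:
    def test_matched_equals_brute_force(self, rng):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        oracle = _brute_force_matched(a, b)
        got = cross_correlate(a, b, "matched").values
        assert np.max(np.abs(got - oracle)) < 1e-9

    def test_autocorrelation_peak_at_zero_lag(self, psf_fast):
        c = cross_correlate(psf_fast, psf_fast, "matched")
        assert c.peak_index == (32, 32)

    def test_shift_gives_shifted_peak(self, psf_fast):
        shifted = np.roll(psf_fast.values, (5, -7), axis=(0, 1))
        c = cross_correlate(shifted, psf_fast, "matched")
        assert c.peak_index == (32 + 5, 32 - 7)

    def test_circular_shift_equivariance(self, rng):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        base = cross_correlate(a, b, "matched", pad=False).values
        moved = cross_correlate(np.roll(a, (3, 9), axis=(0, 1)), b,
                                "matched", pad=False).values
        assert np.allclose(moved, np.roll(base, (3, 9), axis=(0, 1)),
                           rtol=1e-11, atol=1e-11 * base.max())

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            cross_correlate(rng.random((8, 8)), rng.random((8, 9)))


class TestNonlinearCorrelation:
    def test_reduces_to_matched_filter(self, rng):
        a, b = rng.random((24, 24)), rng.random((24, 24))
        nl = nonlinear_correlation(a, b, 1.0, 1.0).values
        mf = cross_correlate(a, b, "matched").values
        assert np.allclose(nl, mf, rtol=1e-10, atol=1e-10)

    def test_reduces_to_phase_only_filter(self, rng):
        a, b = rng.random((24, 24)), rng.random((24, 24))
        nl = nonlinear_correlation(a, b, 0.0, 1.0).values
        po = cross_correlate(a, b, "phase_only").values
        assert np.allclose(nl, po, rtol=1e-10, atol=1e-10)

    def test_joint_shift_leaves_peak_location(self, psf_fast):
        a = psf_fast.values
        b = np.roll(a, (4, 2), axis=(0, 1))
        c1 = nonlinear_correlation(a, a, 0.0, 0.6, pad=False)
        c2 = nonlinear_correlation(b, b, 0.0, 0.6, pad=False)
        assert c1.peak_index == c2.peak_index

    def test_scale_invariance_at_zero_exponents(self, rng):
        a, b = rng.random((24, 24)), rng.random((24, 24))
        c1 = nonlinear_correlation(a, b, 0.0, 0.0).values
        c2 = nonlinear_correlation(7.3 * a, 0.2 * b, 0.0, 0.0).values
        assert np.allclose(c1, c2, rtol=1e-9)

    def test_exponent_bounds(self):
        with pytest.raises(ValueError):
            FilterParams(alpha=1.5)


class TestEntropy:
    def test_uniform_window_is_log_n(self):
        img = np.ones((20, 20))
        assert entropy(img) == pytest.approx(np.log(400), rel=1e-12)

    def test_single_pixel_is_zero(self):
        img = np.zeros((16, 16))
        img[3, 5] = 2.0
        assert entropy(img) == 0.0

    def test_two_pixel_hand_value(self):
        img = np.zeros((2, 2))
        img[0, 0], img[0, 1] = 0.75, 0.25
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert entropy(img) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5623, abs=1e-4)

    def test_all_zero_window_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.zeros((8, 8)))

    @given(images)
    def test_bounds(self, img):
        if img.sum() == 0:
            return
        s = entropy(img)
        assert -1e-12 <= s <= np.log(img.size) + 1e-12


class TestSearchFilterParams:
    def test_single_point_grid(self, psf_fast):
        p = search_filter_params(psf_fast, psf_fast, [0.0], [0.6], window=16)
        assert (p.alpha, p.beta) == (0.0, 0.6)

    def test_argmin_property(self, psf_fast, rng):
        frame = psf_fast.values + 0.05 * rng.random(psf_fast.values.shape) \
            * psf_fast.values.mean()
        alphas, betas = [0.0, 1.0], [0.4, 0.7, 1.0]
        best = search_filter_params(frame, psf_fast, alphas, betas, window=16)
        s_best = entropy(nonlinear_correlation(frame, psf_fast, best.alpha,
                                               best.beta).values, 16)
        for a in alphas:
            for b in betas:
                s = entropy(nonlinear_correlation(frame, psf_fast, a, b).values, 16)
                assert s_best <= s + 1e-12

    def test_entropy_choice_beats_matched_filter_snr(self, cfg_fast, mask_fast,
                                                     psf_fast):
        from qrap5d.optics import simulate_psf
        frame = simulate_psf(cfg_fast, mask_fast,
                             source_xy=(5 * cfg_fast.pixel_pitch, 0.0))
        best = search_filter_params(frame, psf_fast, [0.0],
                                    np.arange(0.2, 1.01, 0.1), window=32)
        snr_nl = peak_snr(nonlinear_correlation(frame, psf_fast, best.alpha,
                                                best.beta))
        snr_mf = peak_snr(cross_correlate(frame, psf_fast, "matched"))
        assert snr_nl >= snr_mf

    def test_empty_grid_rejected(self, psf_fast):
        with pytest.raises(ValueError):
            search_filter_params(psf_fast, psf_fast, [], [0.6])


class TestPostFilters:
    def test_lowpass_unit_cutoff_identity(self, rng):
        img = rng.random((32, 32))
        assert np.max(np.abs(lowpass_filter(img, 1.0) - img)) < 1e-9

    def test_lowpass_removes_high_frequency(self):
        n = 64
        x = np.arange(n)
        # on-bin tone at 28/64 = 0.4375 cyc/sample, above 0.5×Nyquist
        img = np.cos(2 * np.pi * 28 / n * x)[None, :] * np.ones((n, 1))
        out = lowpass_filter(img, 0.5)
        assert np.abs(out).max() < 1e-9
        # an on-bin tone below the cutoff passes untouched
        low = np.cos(2 * np.pi * 4 / n * x)[None, :] * np.ones((n, 1))
        assert np.allclose(lowpass_filter(low, 0.5), low, atol=1e-12)

    def test_median_kernel_one_identity(self, rng):
        img = rng.random((16, 16))
        assert np.array_equal(median_filter(img, 1), img)

    def test_median_removes_impulse(self):
        img = np.ones((16, 16))
        img[8, 8] = 100.0
        assert np.allclose(median_filter(img, 3), 1.0)

    def test_median_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            median_filter(rng.random((8, 8)), 2)

    def test_spectrum_filter_zero_strength_identity(self, psf_fast, rng):
        frame = rng.random(psf_fast.values.shape)
        out = spectrum_domain_filter(frame, psf_fast, 0.0)
        assert np.array_equal(out, frame)

    def test_spectrum_weights_identity_patterns(self, psf_fast):
        w = spectrum_weights(psf_fast, psf_fast)
        assert np.all(w >= 1 - 1e-9)

    def test_spectrum_filter_raises_snr_on_noisy_frame(self, cfg_fast,
                                                       mask_fast, psf_fast, rng):
        from qrap5d.optics import simulate_psf
        frame = simulate_psf(cfg_fast, mask_fast,
                             source_xy=(6 * cfg_fast.pixel_pitch, 0.0))
        noisy = frame.values + 3 * frame.values.mean() \
            * rng.random(frame.values.shape)
        s0 = peak_snr(reconstruct_pipeline(noisy, psf_fast,
                                           FilterParams(0.0, 0.6)))
        s1 = peak_snr(reconstruct_pipeline(
            noisy, psf_fast,
            FilterParams(0.0, 0.6, spectrum_filter_strength=1.0)))
        assert s1 > s0


class TestPipeline:
    def test_neutral_stages_give_matched_filter(self, rng):
        a, b = rng.random((24, 24)), rng.random((24, 24))
        out = reconstruct_pipeline(a, b, FilterParams(alpha=1.0, beta=1.0))
        mf = cross_correlate(a, b, "matched")
        assert np.allclose(out.values, mf.values, rtol=1e-10, atol=1e-10)

    def test_delta_like_autocorrelation_of_chaotic_psf(self, psf_full):
        """Λ of an optimized-scale chaotic PSF is sharply peaked."""
        lam = nonlinear_correlation(psf_full, psf_full, 0.0, 0.6)
        assert peak_snr(lam) >= 20

    def test_correct_depth_psf_wins(self, cfg_fast, mask_fast, psf_fast):
        from qrap5d.optics import simulate_psf
        frame = simulate_psf(cfg_fast, mask_fast)  # object at u
        wrong = simulate_psf(cfg_fast, mask_fast,
                             source_depth=cfg_fast.u + 4e-3)
        params = FilterParams(0.0, 0.6)
        snr_right = peak_snr(reconstruct_pipeline(frame, psf_fast, params))
        snr_wrong = peak_snr(reconstruct_pipeline(frame, wrong, params))
        assert snr_right > snr_wrong
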