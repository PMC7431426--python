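"""Fresnel propagator and incoherent imaging simulator."""

import numpy as np
import pytest

from qrap5d import optics, recon
from qrap5d.mask import PinholeArray
from qrap5d.optics import (ComplexField, Emitter, OpticalConfig, SamplingError,
                           SceneSpec, fresnel_propagate, max_tf_distance,
                           point_source_to_mask, simulate_object_intensity,
                           simulate_psf)


def _gaussian_field(n=128, pitch=4e-6, lam=530e-9, w=60e-6):
    c = (np.arange(n) - n // 2) * pitch
    r2 = c[:, None] ** 2 + c[None, :] ** 2
    return ComplexField(np.exp(-r2 / w ** 2).astype(complex), pitch, lam)


class TestFresnelPropagate:
    def test_forward_backward_identity(self):
        f = _gaussian_field()
        z = 0.5 * max_tf_distance(f)
        back = fresnel_propagate(fresnel_propagate(f, z), -z)
        rms = np.sqrt(np.mean(np.abs(back.amplitude - f.amplitude) ** 2))
        assert rms < 1e-9

    def test_plane_wave_magnitude_preserved(self):
        n, pitch, lam = 64, 4e-6, 530e-9
        f = ComplexField(np.ones((n, n), dtype=complex), pitch, lam)
        out = fresnel_propagate(f, 0.2 * max_tf_distance(f))
        assert np.allclose(np.abs(out.amplitude), 1.0, atol=1e-10)
        # phase advanced uniformly
        assert np.ptp(np.angle(out.amplitude)) < 1e-9

    def test_energy_conservation(self):
        f = _gaussian_field()
        out = fresnel_propagate(f, 0.8 * max_tf_distance(f))
        assert abs(out.energy - f.energy) / f.energy < 1e-6

    def test_sampling_violation_names_limit(self):
        f = _gaussian_field(n=64)
        zmax = max_tf_distance(f)
        with pytest.raises(SamplingError, match=f"{zmax:.4g}"):
            fresnel_propagate(f, 2 * zmax, method="tf")

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            fresnel_propagate(_gaussian_field(n=32), 0.0)

    @pytest.mark.parametrize("z", [5e-3, 8e-3])
    def test_circular_aperture_on_axis_oracle(self, z):
        """On-axis intensity of a plane-wave-lit disc: 4 sin²(πa²/(2λz))."""
        n, pitch, lam, a = 512, 4e-6, 530e-9, 0.15e-3
        c = (np.arange(n) - n // 2) * pitch
        rr = np.hypot(c[:, None], c[None, :])
        f = ComplexField((rr <= a).astype(complex), pitch, lam)
        out = fresnel_propagate(f, z, method="tf")
        sim = np.abs(out.amplitude[n // 2, n // 2]) ** 2
        pred = 4 * np.sin(np.pi * a ** 2 / (2 * lam * z)) ** 2
        assert sim == pytest.approx(pred, rel=0.10)

    def test_impulse_response_form_long_distance(self):
        f = _gaussian_field(n=128)
        z = 3 * max_tf_distance(f)
        out = fresnel_propagate(f, z, method="auto")
        assert out.pitch == pytest.approx(f.wavelength * z / (128 * f.pitch))
        assert np.all(np.isfinite(out.amplitude))


class TestPointSource:
    def test_on_axis_symmetry(self, cfg_fast):
        f = point_source_to_mask(cfg_fast, (0.0, 0.0), grid_size=64)
        ph = np.angle(f.amplitude)
        # symmetric about the grid-center pixel
        assert np.allclose(ph[32, 32 + 5], ph[32, 32 - 5], atol=1e-12)
        assert np.allclose(ph[32 + 7, 32], ph[32 - 7, 32], atol=1e-12)

    def test_quadratic_phase_value(self, cfg_fast):
        depth = 0.08
        f = point_source_to_mask(cfg_fast, (0.0, 0.0), depth, grid_size=64)
        r = 10 * cfg_fast.sim_pitch
        expected = np.pi * r ** 2 / (cfg_fast.wavelength * depth)
        got = np.angle(f.amplitude[32, 42] / f.amplitude[32, 32])
        assert got == pytest.approx(expected % (2 * np.pi), abs=1e-6)

    def test_doubling_depth_halves_curvature(self, cfg_fast):
        f1 = point_source_to_mask(cfg_fast, (0.0, 0.0), 0.05, grid_size=64)
        f2 = point_source_to_mask(cfg_fast, (0.0, 0.0), 0.10, grid_size=64)
        p1 = np.angle(f1.amplitude[32, 35] / f1.amplitude[32, 32])
        p2 = np.angle(f2.amplitude[32, 35] / f2.amplitude[32, 32])
        assert p1 == pytest.approx(2 * p2, rel=1e-9)

    def test_invalid_depth(self, cfg_fast):
        with pytest.raises(ValueError):
            point_source_to_mask(cfg_fast, (0.0, 0.0), -0.1)


class TestSimulatePsf:
    def test_single_pinhole_single_lobe(self, cfg_fast):
        m = PinholeArray(np.array([[0.0, 0.0]]), 160e-6, (1e-3, 1e-3))
        psf = simulate_psf(cfg_fast, m)
        r0, c0 = np.unravel_index(psf.values.argmax(), psf.values.shape)
        assert (r0, c0) == (32, 32)
        # energy concentrated in one central lobe
        yy, xx = np.ogrid[:64, :64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 12 ** 2
        assert psf.values[disc].sum() / psf.values.sum() > 0.5

    def test_two_pinhole_fringes(self, cfg_fast):
        d = 0.4e-3
        m = PinholeArray(np.array([[-d / 2, 0.0], [d / 2, 0.0]]), 80e-6,
                         (1e-3, 1e-3))
        psf = simulate_psf(cfg_fast, m)
        row = psf.values[32, :] - psf.values[32, :].mean()
        spec = np.abs(np.fft.rfft(row * np.hanning(len(row))))
        k = spec[1:].argmax() + 1
        freq = k / (len(row) * cfg_fast.pixel_pitch)
        pred = d / (cfg_fast.wavelength * cfg_fast.v)
        assert freq == pytest.approx(pred, rel=0.07)  # within one FFT bin

    def test_lateral_shift_covariance(self, cfg_fast, mask_fast, psf_fast):
        """Source shift δ moves the pattern by −(v/u)δ."""
        shift_px = 6
        delta = shift_px * cfg_fast.pixel_pitch * cfg_fast.u / cfg_fast.v
        shifted = simulate_psf(cfg_fast, mask_fast, source_xy=(delta, 0.0))
        c = recon.cross_correlate(shifted, psf_fast, "phase_only")
        assert c.peak_index == (32, 32 - shift_px)

    def test_mask_too_large(self, cfg_fast):
        big = PinholeArray(np.array([[0.0, 0.0]]), 80e-6, (0.5, 0.5))
        with pytest.raises(ValueError, match="grid"):
            simulate_psf(cfg_fast, big)

    def test_metadata(self, cfg_fast, mask_fast):
        psf = simulate_psf(cfg_fast, mask_fast, source_depth=cfg_fast.u + 2e-3)
        assert psf.role == "psf"
        assert psf.du == pytest.approx(2e-3)
        assert psf.wavelength == cfg_fast.wavelength
        assert psf.values.shape == cfg_fast.sensor_shape
        assert np.all(psf.values >= 0)


class TestObjectIntensity:
    def test_single_emitter_equals_psf(self, cfg_fast, mask_fast, psf_fast):
        scene = SceneSpec(emitters=[
            Emitter(0.0, 0.0, cfg_fast.u, cfg_fast.wavelength, 1.0)])
        frame = simulate_object_intensity(cfg_fast, mask_fast, scene)
        assert np.allclose(frame.values, psf_fast.values)

    def test_incoherent_linearity(self, cfg_fast, mask_fast):
        px = cfg_fast.pixel_pitch
        e1 = Emitter(4 * px, 0.0, cfg_fast.u, cfg_fast.wavelength, 1.0)
        e2 = Emitter(-3 * px, 2 * px, cfg_fast.u, cfg_fast.wavelength, 0.5)
        f1 = simulate_object_intensity(cfg_fast, mask_fast, SceneSpec(emitters=[e1]))
        f2 = simulate_object_intensity(cfg_fast, mask_fast, SceneSpec(emitters=[e2]))
        f12 = simulate_object_intensity(cfg_fast, mask_fast,
                                        SceneSpec(emitters=[e1, e2]))
        assert np.allclose(f12.values, f1.values + f2.values, rtol=1e-12)

    def test_convolution_fast_path_matches_point_sum(self, cfg_fast, mask_fast):
        """O ⊗ I_PSF via FFT equals emitter-by-emitter summation."""
        obj_pitch = 2 * cfg_fast.pixel_pitch
        bitmap = np.zeros((9, 9))
        bitmap[2:7:2, 2:7:2] = 1.0
        bitmap[4, 3] = 0.5
        from qrap5d.optics import PlanarObject
        plane = PlanarObject(bitmap, obj_pitch, cfg_fast.u, cfg_fast.wavelength)
        scene = SceneSpec(planes=[plane])
        fast = simulate_object_intensity(cfg_fast, mask_fast, scene, method="conv")
        slow = simulate_object_intensity(cfg_fast, mask_fast, scene,
                                         method="pointsum")
        rel = np.linalg.norm(fast.values - slow.values) / np.linalg.norm(slow.values)
        assert rel < 0.02

    def test_empty_scene_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec()


class TestResponseCurves:
    def test_axial_curve_properties(self, cfg_fast, mask_fast):
        dus = np.linspace(-6e-3, 6e-3, 9)
        curve = optics.axial_response_curve(cfg_fast, mask_fast, list(dus))
        x = np.array([p[0] for p in curve])
        y = np.array([p[1] for p in curve])
        assert y[x == 0][0] == 1.0
        assert np.all((y >= 0) & (y <= 1))
        # decays away from the peak on the smoothed curve
        sm = np.convolve(y, np.ones(3) / 3, mode="valid")
        i = sm.argmax()
        assert sm[0] < sm[i] and sm[-1] < sm[i]

    def test_axial_requires_zero(self, cfg_fast, mask_fast):
        with pytest.raises(ValueError):
            optics.axial_response_curve(cfg_fast, mask_fast, [1e-3, 2e-3])

    def test_spectral_peak_and_symmetry(self, cfg_full, mask_full):
        lams = 530e-9 + np.array([-6, -3, 0, 3, 6]) * 1e-9
        curve = optics.spectral_response_curve(cfg_full, mask_full, list(lams))
        vals = dict((round(l * 1e9 - 530), v) for l, v in curve)
        assert vals[0] == 1.0
        assert max(vals.values()) == 1.0
        for d in (3, 6):
            lo, hi = vals[-d], vals[d]
            assert abs(lo - hi) / ((lo + hi) / 2) < 0.20

    def test_lambda_width_grows_with_pinhole_diameter(self, cfg_fast):
        """Λ cannot be sharper than the smallest speckle, set by pinhole size."""
        from qrap5d.mask import generate_rap
        widths = {}
        for d, n in [(80e-6, 40), (320e-6, 12)]:
            m = generate_rap(n, (2e-3, 2e-3), d, seed=5)
            psf = simulate_psf(cfg_fast, m)
            auto = recon.cross_correlate(psf, psf, "matched").values
            r0 = np.unravel_index(auto.argmax(), auto.shape)[0]
            row = auto[r0, :] - np.median(auto[r0, :])
            widths[d] = recon.curve_fwhm(
                np.arange(len(row)) * cfg_fast.pixel_pitch, row)
        assert widths[80e-6] < widths[320e-6]


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"u": -1.0}, {"v": 0.0}, {"wavelength": 0.0},
        {"sensor_shape": (8, 64)}, {"grid_oversample": 0},
        {"pixel_pitch": -1e-6},
    ])
    def test_invalid_config(self, kwargs):
        base = dict(u=0.1, v=0.1, wavelength=530e-9, sensor_shape=(64, 64),
                    pixel_pitch=8e-6, grid_oversample=1)
        base.update(kwargs)
        with pytest.raises(ValueError):
            OpticalConfig(**base)

    def test_oversampling_refines_grid(self, mask_fast):
        cfg = OpticalConfig(u=0.1, v=0.1, wavelength=530e-9,
                            sensor_shape=(32, 32), pixel_pitch=32e-6,
                            grid_oversample=2)
        psf = simulate_psf(cfg, mask_fast)
        assert psf.values.shape == (32, 32)
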