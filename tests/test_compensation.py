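"""Tilt/spherical compensation, center estimation, unwrapping, pipeline."""

import math

import numpy as np
import pytest

import holophase as hp
from holophase.compensation import ReconstructOptions
from holophase.simulate import _spherical_phase, carrier_roi

from conftest import (
    APODIZE, C_TRUE, ROI, SIZE, STAR_HEIGHT, VERTEX, tilt_for,
)


class TestDigitalReferenceWave:
    def test_zero_tilt_is_unit_constant(self, params512):
        r = hp.digital_reference_wave(hp.TiltAngles(0.0, 0.0), params512)
        np.testing.assert_allclose(r.values, 1.0)

    def test_unit_modulus(self, params512):
        r = hp.digital_reference_wave(tilt_for((93, -41)), params512)
        np.testing.assert_allclose(np.abs(r.values), 1.0, atol=1e-12)

    def test_flattens_simulated_carrier(self, sphere_only_truth, sphere_only_hologram):
        # after tilt compensation the residual mean phase gradient is tiny
        spec = hp.compute_spectrum(sphere_only_hologram)
        h_f = hp.filter_plus_one(spec, ROI, apodize=APODIZE)
        flat = hp.compensate_tilt(h_f, sphere_only_truth.tilt)
        # remove the known spherical phase, leaving carrier residual only
        residual = flat.values * np.exp(
            -1j * _spherical_phase(sphere_only_truth.sphere, sphere_only_truth.params)
        )
        interior = residual[128:-128, 128:-128]
        grad = np.angle(interior[:, 1:] * np.conj(interior[:, :-1]))
        assert abs(np.mean(grad)) <= 2 * np.pi / (10 * SIZE)


class TestCompensateTilt:
    def test_exact_cancellation(self, params512):
        tilt = tilt_for((70, 55))
        r = hp.digital_reference_wave(tilt, params512)
        out = hp.compensate_tilt(hp.ComplexField(np.conj(r.values), params512), tilt)
        np.testing.assert_allclose(np.angle(out.values), 0.0, atol=1e-9)

    def test_involution(self, params512, sphere_only_field):
        tilt = tilt_for((70, 55))
        neg = hp.TiltAngles(-tilt.theta_x, -tilt.theta_y)
        back = hp.compensate_tilt(hp.compensate_tilt(sphere_only_field, tilt), neg)
        np.testing.assert_allclose(back.values, sphere_only_field.values, atol=1e-9)

    def test_residual_ring_pattern(self, sphere_only_field):
        # non-telecentric residual shows >= 3 concentric wraps along a radius
        phase = np.angle(sphere_only_field.values)
        row = phase[int(VERTEX[1]), int(VERTEX[0]) :]
        wraps = np.count_nonzero(np.abs(np.diff(row)) > np.pi)
        assert wraps >= 3


class TestEstimateSphereCenter:
    @pytest.mark.parametrize("center", [(256.0, 256.0), (293.0, 235.0)])
    def test_synthetic_sphere_recovered(self, params512, center):
        sphere = hp.SphericalWavefront(3e5, 3e5, h=center[0], g=center[1], sign=1)
        pm = hp.PhaseMap(hp.wrap_phase(_spherical_phase(sphere, params512)), wrapped=True)
        h, g = hp.estimate_sphere_center(pm)
        assert abs(h - center[0]) <= 2 and abs(g - center[1]) <= 2

    def test_constant_map_fails(self):
        with pytest.raises(hp.CenterNotFoundError):
            hp.estimate_sphere_center(hp.PhaseMap(np.zeros((128, 128)), wrapped=True))


class TestConjugateSphericalWave:
    def test_telecentric_unit_field(self, params512):
        tele = hp.SphericalWavefront(None, None, telecentric=True)
        np.testing.assert_allclose(
            hp.conjugate_spherical_wave(tele, params512).values, 1.0
        )

    def test_vertex_phase_zero_and_known_value(self, params512):
        sphere = hp.SphericalWavefront(2.644e5, 2.644e5, h=200.0, g=300.0, sign=1)
        w = hp.conjugate_spherical_wave(sphere, params512)
        assert np.angle(w.values[300, 200]) == pytest.approx(0.0, abs=1e-12)
        # 100 columns from the vertex: -pi*(100*5.86)^2/(0.532*2.644e5)
        expected = -np.pi * (100 * 5.86) ** 2 / (0.532 * 2.644e5)
        assert np.angle(w.values[300, 300]) == pytest.approx(
            hp.wrap_phase(np.array(expected)), abs=1e-9
        )
        np.testing.assert_allclose(np.abs(w.values), 1.0, atol=1e-12)


class TestCompensateSphere:
    def test_exact_cancellation(self, params512):
        sphere = hp.SphericalWavefront(2e5, 3e5, h=250.0, g=260.0, sign=1)
        w = hp.conjugate_spherical_wave(sphere, params512)
        pm = hp.compensate_sphere(
            hp.ComplexField(np.conj(w.values), params512), sphere
        )
        np.testing.assert_allclose(pm.values, 0.0, atol=1e-9)

    def test_true_parameters_flatten_background(
        self, sphere_only_field, sphere_only_truth
    ):
        pm = hp.compensate_sphere(sphere_only_field, sphere_only_truth.sphere)
        assert np.std(pm.values) <= 0.1

    def test_wrong_sign_doubles_rings(self, sphere_only_field, sphere_only_truth):
        good = hp.compensate_sphere(sphere_only_field, sphere_only_truth.sphere)
        bad = hp.compensate_sphere(
            sphere_only_field, sphere_only_truth.sphere.flipped()
        )
        count_wraps = lambda pm: np.count_nonzero(
            np.abs(np.diff(pm.values[int(VERTEX[1])])) > np.pi
        )
        assert count_wraps(bad) > count_wraps(good)


class TestUnwrap:
    def test_linear_ramp(self):
        ramp = np.tile(np.linspace(0.0, 6 * np.pi, 256), (64, 1))
        unw = hp.unwrap_phase(hp.PhaseMap(hp.wrap_phase(ramp), wrapped=True)).values
        # fit a plane; residual must vanish
        x = np.arange(256)
        coeffs = np.polyfit(x, unw.mean(axis=0), 1)
        fitted = np.polyval(coeffs, x)
        assert np.max(np.abs(unw - fitted)) <= 1e-6

    def test_congruent_mod_2pi(self, sphere_only_field):
        pm = hp.ComplexField(sphere_only_field.values, sphere_only_field.params).phase_map()
        unw = hp.unwrap_phase(pm).values
        np.testing.assert_allclose(
            hp.wrap_phase(unw - pm.values), 0.0, atol=1e-9
        )

    def test_paraboloid_five_wraps(self, params512):
        sphere = hp.SphericalWavefront(8.0e5, 8.0e5, h=256.0, g=256.0, sign=1)
        s = _spherical_phase(sphere, params512)
        assert s.max() >= 5 * 2 * np.pi  # at least 5 wraps
        unw = hp.unwrap_phase(hp.PhaseMap(hp.wrap_phase(s), wrapped=True)).values
        unw -= unw[256, 256] - s[256, 256]
        assert np.sqrt(np.mean((unw - s) ** 2)) <= 0.01


def test_subtract_blank_identity(star_pattern):
    pm = hp.PhaseMap(hp.wrap_phase(star_pattern.values), wrapped=True)
    np.testing.assert_allclose(hp.subtract_blank(pm, pm).values, 0.0, atol=1e-12)
    with pytest.raises(hp.InvalidInputError):
        hp.subtract_blank(pm, hp.PhaseMap(np.zeros((8, 8)), wrapped=True))


class TestReconstruct:
    def test_provenance_records_all_parameters(self, star_hologram):
        res = hp.reconstruct(star_hologram, ROI, ReconstructOptions(apodize=APODIZE))
        for key in ("P", "Q", "M", "N", "theta_x", "theta_y", "C_x", "C_y", "h", "g"):
            assert key in res.provenance

    def test_amplitude_equals_filtered_modulus(self, star_hologram):
        res = hp.reconstruct(star_hologram, ROI, ReconstructOptions(apodize=APODIZE))
        spec = hp.compute_spectrum(star_hologram)
        expected = np.abs(hp.filter_plus_one(spec, ROI, apodize=APODIZE).values)
        np.testing.assert_array_equal(res.amplitude, expected)

    def test_telecentric_flag_equals_skipped_stage(self, params512, star_pattern):
        truth = hp.SimulationTruth.from_optics(
            params512, tilt_for((150, 120)), f_TL=2e5, z=2e5, object_phase=star_pattern
        )
        holo = hp.simulate_hologram(truth)
        roi = hp.SpectrumROI(P=106, Q=136, M=121, N=121)
        skipped = hp.reconstruct(holo, roi, ReconstructOptions(telecentric=True))
        spec = hp.compute_spectrum(holo)
        flat = hp.compensate_tilt(hp.filter_plus_one(spec, roi), truth.tilt)
        tele = hp.SphericalWavefront(None, None, telecentric=True)
        manual = hp.compensate_sphere(flat, tele)
        assert np.max(np.abs(skipped.phase.values - manual.values)) <= 1e-9

    def test_spectral_curvature_estimate_within_10pc(
        self, params512, sphere_only_truth
    ):
        # tight ROI around the true support: pre-optimization C within 10%
        truth = hp.SimulationTruth(
            params=params512, tilt=sphere_only_truth.tilt,
            sphere=hp.SphericalWavefront(5.77e5, 5.77e5, h=VERTEX[0], g=VERTEX[1], sign=1),
            object_phase=hp.PhaseMap(np.zeros(params512.shape), wrapped=True),
        )
        holo = hp.simulate_hologram(truth)
        res = hp.reconstruct(holo, carrier_roi(truth, pad=1))
        assert hp.percent_error(res.sphere.C_x, 5.77e5) <= 10.0
        assert res.sphere.sign == 1

    def test_shift_invariance(self, params512, star_truth, star_hologram):
        # translating the object by 30 px leaves the recovered height within 2%
        def mean_height(truth, holo):
            res = hp.reconstruct(
                holo, ROI,
                ReconstructOptions(apodize=APODIZE, sphere_seed=truth.sphere, unwrap=True),
            )
            pat = truth.object_phase.values
            obj = pat > 0.5 * STAR_HEIGHT
            u = res.unwrapped.values
            return np.mean(u[obj]) - np.median(u[pat == 0])

        shifted_pat = hp.make_pattern(
            "star", SIZE, STAR_HEIGHT, radius_frac=0.17,
            center=(421 - 30, 395 - 30), edge_sigma=2.0,
        )
        shifted = hp.SimulationTruth(
            params=params512, tilt=star_truth.tilt, sphere=star_truth.sphere,
            object_phase=shifted_pat,
        )
        h0 = mean_height(star_truth, star_hologram)
        h1 = mean_height(shifted, hp.simulate_hologram(shifted))
        assert abs(h1 - h0) / abs(h0) <= 0.02

    def test_missing_roi_requires_auto(self, star_hologram):
        with pytest.raises(hp.InvalidInputError):
            hp.reconstruct(star_hologram, None, ReconstructOptions(auto_roi=False))

    @pytest.mark.parametrize("kind", ["star", "wedding_cake", "disc", "blobs", "bars"])
    @pytest.mark.parametrize("curvature", [1e5, 1e6])
    def test_recovery_across_patterns_and_curvatures(
        self, params512, kind, curvature
    ):
        # true-parameter compensation recovers every target kind with
        # SSIM >= 0.95 over the full curvature decade
        pat = hp.make_pattern(
            kind, SIZE, 0.9 if kind == "wedding_cake" else STAR_HEIGHT,
            radius_frac=0.17 if kind in ("star", "disc") else None,
            center=(421, 395) if kind in ("star", "disc") else None,
            edge_sigma=2.0,
        )
        sphere = hp.SphericalWavefront(
            curvature, curvature, h=VERTEX[0], g=VERTEX[1], sign=1
        )
        truth = hp.SimulationTruth(
            params=params512, tilt=tilt_for((170, 170)), sphere=sphere,
            object_phase=pat,
        )
        res = hp.reconstruct(
            hp.simulate_hologram(truth), ROI,
            ReconstructOptions(apodize=APODIZE, sphere_seed=sphere, unwrap=True),
        )
        bg = pat.values == 0
        unw = res.unwrapped.values - np.median(res.unwrapped.values[bg])
        ssim = hp.ssim_metric(
            hp.PhaseMap(unw, wrapped=False), hp.PhaseMap(pat.values, wrapped=False)
        )
        assert ssim >= 0.95

    def test_noise_robustness_snr_20db(self):
        # additive noise at SNR 20 dB: GA+PS curvature PE stays <= 5%
        n = 256
        p = hp.AcquisitionParams(n, n, 5.86, 0.532)
        tilt = tilt_for((85, 85), n=n)
        C = 1.48e5
        sphere = hp.SphericalWavefront(C, C, h=136.0, g=120.0, sign=1)
        star = hp.make_pattern(
            "star", n, STAR_HEIGHT, radius_frac=0.17, center=(205, 195), edge_sigma=1.5
        )
        clean = hp.simulate_hologram(
            hp.SimulationTruth(params=p, tilt=tilt, sphere=sphere, object_phase=star)
        )
        truth = hp.SimulationTruth(
            params=p, tilt=tilt, sphere=sphere, object_phase=star,
            noise_sd=float(np.std(clean.values)) / 10, rng_seed=1,
        )
        res = hp.reconstruct(
            hp.simulate_hologram(truth), hp.SpectrumROI(43, 43, 83, 83),
            ReconstructOptions(
                optimize="GA_PS", cost="J2", rng_seed=1, apodize=APODIZE,
                sphere_seed=hp.SphericalWavefront(C * 1.25, C * 1.25),
            ),
        )
        assert hp.percent_error(res.sphere.C_x, C) <= 5.0
        assert hp.percent_error(res.sphere.C_y, C) <= 5.0
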