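import dataclasses

import numpy as np
import pytest

import cacflow as cf
from cacflow.core import InvalidArgumentError
from cacflow.coherence import normalized_lag_correlations
from cacflow.synthetic import (ComponentSpec, correlated_channel_draw,
                               decaying_coherence, delta_coherence,
                               expected_measured_coherence, scene_presets,
                               triangle_coherence)


class TestCorrelatedChannelDraw:
    def test_rank_one_profile_gives_identical_channels(self, rng):
        g = correlated_channel_draw(np.ones(8), 8, 5, rng)
        assert np.allclose(g, g[0][None, :], atol=1e-10)

    def test_delta_profile_gives_iid_channels(self, rng):
        m = 16
        draws = np.stack([correlated_channel_draw(delta_coherence(m), m, 1, rng)[:, 0]
                          for _ in range(4000)])
        cov = draws.T.conj() @ draws / draws.shape[0]
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 0.1
        assert np.allclose(np.diag(cov).real, 1.0, atol=0.1)

    def test_toeplitz_covariance_recovery(self, rng):
        """Sample covariance over 1e4 draws matches the prescribed triangle
        Toeplitz matrix entrywise within 0.03."""
        m = 64
        profile = triangle_coherence(m)
        g = correlated_channel_draw(profile, m, 10_000, rng)
        cov = (g @ g.conj().T / g.shape[1]).real
        idx = np.abs(np.arange(m)[:, None] - np.arange(m)[None, :])
        assert np.max(np.abs(cov - profile[idx])) < 0.03

    def test_unrepresentable_profile_rejected(self, rng):
        bad = np.zeros(4)  # rho[0] = 0: no nonnegative eigenvalue mass
        with pytest.raises(InvalidArgumentError):
            correlated_channel_draw(bad, 4, 1, rng)


class TestSimulatePixel:
    def test_coherent_blood_is_pure_phasor(self, small_acq, rng):
        comp = ComponentSpec(kind="blood", amplitude=1.0, doppler_fraction=0.1,
                             coherence_profile=np.ones(small_acq.n_channels))
        u = cf.simulate_pixel([comp], small_acq, rng)
        k = np.arange(small_acq.ensemble)
        expected = u[0, 0] * np.exp(2j * np.pi * 0.1 * k)
        assert np.allclose(u, expected[None, :], atol=1e-9)
        assert np.allclose(np.abs(u), np.abs(u[0, 0]), atol=1e-9)

    def test_noise_component_uncorrelated_across_channels_and_slow_time(self, rng):
        acq = cf.AcquisitionParams(f0=3.5e6, prf=3e3, n_channels=8, ensemble=8)
        comp = ComponentSpec(kind="noise", amplitude=1.0)
        flat = np.stack([cf.simulate_pixel([comp], acq, rng).ravel()
                         for _ in range(3000)])
        cov = flat.T.conj() @ flat / flat.shape[0]
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 0.12

    def test_strong_clutter_dominates_beamsum_spectrum(self, ref_acq, rng):
        blood = ComponentSpec(kind="blood", amplitude=1.0, doppler_fraction=0.1,
                              coherence_profile=triangle_coherence(ref_acq.n_channels))
        clutter = ComponentSpec(kind="clutter", amplitude=10.0, doppler_fraction=0.005,
                                coherence_profile=triangle_coherence(ref_acq.n_channels))
        u = cf.simulate_pixel([blood, clutter], ref_acq, rng)
        beam = u.sum(axis=0)
        freqs = np.fft.fftfreq(ref_acq.ensemble)
        spectrum = np.abs(np.fft.fft(beam)) ** 2
        peak = freqs[np.argmax(spectrum)]
        assert abs(peak - 0.005) < abs(peak - 0.1)

    def test_empty_component_list_rejected(self, small_acq, rng):
        with pytest.raises(InvalidArgumentError):
            cf.simulate_pixel([], small_acq, rng)


class TestSimulateScene:
    def test_determinism_bit_identical(self, ref_acq):
        scene = scene_presets("water_path", shape=(12, 12), seed=42)
        a = cf.simulate_scene(scene, ref_acq, n_frames=2)
        b = cf.simulate_scene(scene, ref_acq, n_frames=2)
        assert np.array_equal(a.data, b.data)

    def test_energy_scales_with_component_amplitude(self, ref_acq):
        base = scene_presets("water_path", shape=(12, 12), seed=7)
        base = dataclasses.replace(base, vessel=None, blood=None, noise=None)
        doubled = dataclasses.replace(
            base, speckle=dataclasses.replace(base.speckle, amplitude=2.0))
        p1 = np.mean(np.abs(cf.beamsum(cf.simulate_scene(base, ref_acq, 1)).data) ** 2)
        p2 = np.mean(np.abs(cf.beamsum(cf.simulate_scene(doubled, ref_acq, 1)).data) ** 2)
        assert p2 / p1 == pytest.approx(4.0, rel=0.15)

    def test_speckle_only_scene_is_stationary(self, ref_acq):
        scene = dataclasses.replace(
            scene_presets("water_path", shape=(14, 14), seed=8),
            vessel=None, blood=None, noise=None, clutter=None)
        ens = cf.simulate_scene(scene, ref_acq, n_frames=1)
        vmap = cf.velocity_map(cf.beamsum(ens))
        assert np.max(np.abs(vmap.v_hat)) < 1e-6

    def test_vessel_velocity_recovered_without_filtering(self, ref_acq):
        """Plug flow at 5 cm/s axial: the unfiltered in-vessel mean Kasai
        velocity lands within 5% of the prescribed value."""
        scene = scene_presets("water_path", shape=(32, 32), seed=9)
        ens = cf.simulate_scene(scene, ref_acq, n_frames=1)
        vroi = cf.vessel_roi(scene, shrink_mm=0.4)
        vmap = cf.velocity_map(cf.beamsum(ens))
        mean_v = cf.roi_stats(vmap, vroi)[0].mean
        assert mean_v == pytest.approx(5.0, rel=0.05)

    def test_prescribed_coherence_expectation_recovered(self, ref_acq):
        """Mean measured R[m] over >=1e3 speckle pixels matches the analytic
        expectation of the normalized estimator within 3 standard errors for
        m <= 10."""
        scene = dataclasses.replace(
            scene_presets("water_path", seed=10), vessel=None, blood=None, noise=None)
        ens = cf.simulate_scene(scene, ref_acq, n_frames=1)
        d = ens.data[..., 0].reshape(-1, ref_acq.n_channels, ref_acq.ensemble)
        assert d.shape[0] >= 1000
        r = normalized_lag_correlations(np.asarray(d, complex), 10).real
        rho = triangle_coherence(ref_acq.n_channels)[1:11]
        expected = expected_measured_coherence(rho)
        se = r.std(axis=0) / np.sqrt(r.shape[0])
        assert np.all(np.abs(r.mean(axis=0) - expected) < 3 * se)


class TestScenePresets:
    @pytest.mark.parametrize("name, target", [
        ("water_path", 0.75), ("tissue1", 0.45), ("tissue2", 0.36)])
    def test_loc_calibration(self, ref_acq, name, target):
        """Measured speckle-ROI LOC lands within +/-0.05 of the imaging
        condition's calibration value over >=1000 pixels."""
        scene = scene_presets(name, seed=21)
        ens = cf.simulate_scene(scene, ref_acq, n_frames=1)
        roi = cf.speckle_roi(scene)
        assert roi.mask_for(scene.grid()).sum() >= 1000
        loc = cf.lag_one_coherence_roi(ens, roi)
        assert loc == pytest.approx(target, abs=0.05)

    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidArgumentError):
            scene_presets("jelly")

    def test_yaml_round_trip(self):
        scene = scene_presets("tissue1", shape=(10, 10), seed=3)
        again = cf.SceneSpec.from_yaml(scene.to_yaml())
        assert again.shape == scene.shape
        assert again.seed == scene.seed
        assert again.vessel == scene.vessel
        assert np.allclose(again.clutter.coherence_profile,
                           scene.clutter.coherence_profile)
        assert again.clutter.slow_time_modulation == scene.clutter.slow_time_modulation


class TestCoherenceProfiles:
    def test_triangle_endpoints(self):
        rho = triangle_coherence(64)
        assert rho[0] == 1.0 and rho[-1] == pytest.approx(1 / 64)

    def test_decaying_profile_below_triangle(self):
        fast = decaying_coherence(64, 2.0)
        assert np.all(fast[1:] < triangle_coherence(64)[1:])

    def test_measured_coherence_bias_is_monotone_and_bounded(self):
        rho = np.linspace(0, 0.99, 50)
        g = expected_measured_coherence(rho)
        assert np.all(np.diff(g) > 0)
        assert np.all(g <= rho + 1e-12)
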