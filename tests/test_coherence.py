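import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cacflow as cf
from cacflow.coherence import normalized_lag_correlations
from cacflow.core import InvalidArgumentError


def eq6_reference(u):
    """Literal triple-loop transcription of the normalized channel
    correlation, the independent oracle for the vectorized path."""
    m_tot, k_tot = u.shape
    out = np.zeros(m_tot - 1, complex)
    for m in range(1, m_tot):
        acc = 0.0
        for k in range(k_tot):
            for i in range(m_tot - m):
                acc += (u[i, k] * np.conj(u[i + m, k])
                        / (abs(u[i, k]) * abs(u[i + m, k])))
        out[m - 1] = acc / (k_tot * (m_tot - m))
    return out


class TestCorrelationProfile:
    def test_identical_channels_fully_coherent(self):
        u = np.tile(np.exp(1j * np.linspace(0, 1, 5)), (8, 1))
        prof = cf.correlation_profile(u)
        assert np.allclose(prof.r_hat, 1.0)

    def test_alternating_sign_pattern(self):
        u = np.array([(-1.0 + 0j) ** i * np.ones(3) for i in range(6)])
        prof = cf.correlation_profile(u)
        assert prof.r_hat[0] == pytest.approx(-1.0)
        assert prof.r_hat[1] == pytest.approx(+1.0)

    def test_iid_channels_average_to_zero(self, rng):
        """Null distribution: |mean R[m]| over pixels stays within the
        Monte-Carlo bound 3/sqrt(N*K*(M-m))."""
        n_px, m_tot, k_tot = 500, 64, 14
        u = (rng.standard_normal((n_px, m_tot, k_tot))
             + 1j * rng.standard_normal((n_px, m_tot, k_tot)))
        r = normalized_lag_correlations(u, 10)
        mean_r = np.abs(r.mean(axis=0))
        for m in range(1, 11):
            assert mean_r[m - 1] < 3 / np.sqrt(n_px * k_tot * (m_tot - m))

    def test_matches_literal_transcription(self, rng):
        u = (rng.standard_normal((6, 3)) + 1j * rng.standard_normal((6, 3)))
        prof = cf.correlation_profile(u)
        assert np.allclose(prof.r_hat, eq6_reference(u), atol=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(scale=st.complex_numbers(min_magnitude=1e-3, max_magnitude=1e3,
                                    allow_nan=False, allow_infinity=False))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        u = rng.standard_normal((8, 4)) + 1j * rng.standard_normal((8, 4))
        base = cf.correlation_profile(u).r_hat
        scaled = cf.correlation_profile(scale * u).r_hat
        assert np.allclose(scaled, base, atol=1e-9)

    def test_all_zero_pixel_flagged(self):
        prof = cf.correlation_profile(np.zeros((4, 3), complex))
        assert prof.all_zero
        assert np.allclose(prof.r_hat, 0.0)


class TestSlscValue:
    def test_perfect_coherence_upper_bound(self):
        prof = cf.CoherenceProfile(r_hat=np.ones(63))
        assert cf.slsc_value(prof, 10) == pytest.approx(10.0)

    def test_zero_profile(self):
        prof = cf.CoherenceProfile(r_hat=np.zeros(63))
        assert cf.slsc_value(prof, 10) == 0.0

    def test_triangle_profile_closed_form(self):
        m_tot = 64
        prof = cf.CoherenceProfile(r_hat=1 - np.arange(1, m_tot) / m_tot)
        assert cf.slsc_value(prof, 10) == pytest.approx(9.1406, abs=5e-5)

    def test_out_of_range_lag_rejected(self):
        prof = cf.CoherenceProfile(r_hat=np.ones(5))
        with pytest.raises(InvalidArgumentError):
            cf.slsc_value(prof, 6)

    def test_bounded_by_q(self, rng):
        u = rng.standard_normal((16, 6)) + 1j * rng.standard_normal((16, 6))
        val = cf.slsc_value(cf.correlation_profile(u), 8)
        assert -8 <= val <= 8


class TestTheoreticalMaxSlsc:
    def test_reference_value(self):
        assert cf.theoretical_max_slsc(64, 10) == pytest.approx(9.140625)

    def test_single_lag(self):
        assert cf.theoretical_max_slsc(32, 1) == pytest.approx(1 - 1 / 32)

    def test_large_aperture_limit(self):
        assert cf.theoretical_max_slsc(10 ** 9, 10) == pytest.approx(10.0, abs=1e-6)


class TestSlscStack:
    def _ens(self, rng, acq, n_px=3):
        data = (rng.standard_normal((n_px, 1, acq.n_channels, acq.ensemble))
                + 1j * rng.standard_normal((n_px, 1, acq.n_channels, acq.ensemble)))
        grid = cf.PixelGrid.regular((n_px, 1), 0.4)
        return cf.ChannelEnsemble(data=data, grid=grid, acq=acq)

    def test_single_layer_equals_per_pixel_values(self, rng, small_acq):
        ens = self._ens(rng, small_acq)
        stack = cf.slsc_stack([ens], q=3)
        for i in range(3):
            expected = cf.slsc_value(cf.correlation_profile(ens.data[i, 0, :, :, 0]), 3)
            assert stack.values[0, i, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_dataset_gives_identical_layers(self, rng, small_acq):
        ens = self._ens(rng, small_acq)
        stack = cf.slsc_stack([ens, ens], q=3)
        assert np.array_equal(stack.values[0], stack.values[1])

    def test_coherent_scene_separates_from_noise(self, rng, ref_acq):
        n_px = 40
        tone = np.exp(1j * 0.3 * np.arange(ref_acq.ensemble))
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, (n_px, 1, 1, 1)))
        coherent = np.broadcast_to(
            tone, (n_px, 1, ref_acq.n_channels, ref_acq.ensemble)) * phases
        noise = (rng.standard_normal(coherent.shape)
                 + 1j * rng.standard_normal(coherent.shape))
        grid = cf.PixelGrid.regular((n_px, 1), 0.4)
        st_coh = cf.slsc_stack([cf.ChannelEnsemble(coherent.copy(), grid, ref_acq)], q=10)
        st_noise = cf.slsc_stack([cf.ChannelEnsemble(noise, grid, ref_acq)], q=10)
        assert st_coh.values.mean() - st_noise.values.mean() >= 5


class TestLagOneCoherenceRoi:
    def test_identical_channels_give_unity(self, small_acq):
        data = np.ones((2, 2, small_acq.n_channels, small_acq.ensemble), complex)
        ens = cf.ChannelEnsemble(data, cf.PixelGrid.regular((2, 2), 0.4), small_acq)
        roi = cf.ROI(mask=np.ones((2, 2), bool))
        assert cf.lag_one_coherence_roi(ens, roi) == pytest.approx(1.0)

    def test_iid_noise_averages_to_zero(self, rng, ref_acq):
        n = 24  # 576 pixels
        data = (rng.standard_normal((n, n, ref_acq.n_channels, ref_acq.ensemble))
                + 1j * rng.standard_normal((n, n, ref_acq.n_channels, ref_acq.ensemble)))
        ens = cf.ChannelEnsemble(data, cf.PixelGrid.regular((n, n), 0.4), ref_acq)
        loc = cf.lag_one_coherence_roi(ens, cf.ROI(mask=np.ones((n, n), bool)))
        se = 1 / np.sqrt(n * n * ref_acq.ensemble * (ref_acq.n_channels - 1))
        assert abs(loc) < 3 * se
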