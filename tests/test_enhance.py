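"""Band-pass, trajectory-matrix SVD, template extraction, matched filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import signal as sps
from scipy.signal import periodogram

import radarbeat as rb
from radarbeat.demod import arctangent_demodulate
from radarbeat.enhance import select_template


def _sine(freq, fs=100.0, duration=20.0, amp=1.0):
    t = np.arange(round(duration * fs)) / fs
    return rb.SampledSignal(amp * np.sin(2 * np.pi * freq * t), fs=fs, unit="m")


class TestBandpass:
    def test_cardiac_tone_passes_within_3db(self):
        out = rb.bandpass(_sine(1.0))
        # steady-state section, past the causal filter's warm-up
        seg = slice(1000, 2000)
        in_rms = np.sqrt(np.mean(_sine(1.0).values[seg] ** 2))
        out_rms = np.sqrt(np.mean(out.values[seg] ** 2))
        assert abs(20 * np.log10(out_rms / in_rms)) < 3.0

    def test_respiration_fundamental_attenuated_40db(self):
        spec = rb.BandpassSpec()
        sos = spec.design(100.0)
        w, h = sps.sosfreqz(sos, worN=[0.25], fs=100.0)
        assert 20 * np.log10(np.abs(h[0])) < -40.0

    def test_constant_input_decays_to_zero(self):
        # zero gain at DC; the narrow-band IIR transient rings for tens of
        # seconds, so judge the tail of a long window
        x = rb.SampledSignal(np.full(6000, 5.0), fs=100, unit="m")
        out = rb.bandpass(x)
        assert np.max(np.abs(out.values[-500:])) < 1e-5 * 5.0

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            rb.BandpassSpec(low_cut=2.5, high_cut=0.6)
        with pytest.raises(ValueError):
            rb.BandpassSpec(order=7)
        with pytest.raises(ValueError):
            rb.bandpass(rb.SampledSignal(np.zeros(10), fs=4.0), rb.BandpassSpec())

    def test_output_length_equals_input_length(self):
        out = rb.bandpass(_sine(1.0))
        assert out.n == 2000


class TestTrajectoryMatrix:
    def test_tiny_example_rows_are_lagged_vectors(self):
        tm = rb.build_trajectory_matrix(np.array([1.0, 2.0, 3.0, 4.0]), L=2)
        np.testing.assert_array_equal(tm.matrix, [[1, 2], [2, 3], [3, 4]])
        assert (tm.M, tm.L) == (3, 2)

    def test_default_window_dimensions(self):
        x = _sine(1.0)  # N = 2000
        tm = rb.build_trajectory_matrix(x, L=200)
        assert (tm.M, tm.L) == (1801, 200)

    @given(
        hnp.arrays(
            np.float64,
            st.integers(10, 60),
            elements=st.floats(-1e3, 1e3, allow_nan=False),
        ),
        st.integers(2, 9),
    )
    @settings(max_examples=50, deadline=None)
    def test_hankel_structure_and_svd_reconstruction(self, values, L):
        if values.size < L or np.ptp(values) == 0:
            return
        tm = rb.build_trajectory_matrix(values, L)
        i, j = np.indices(tm.matrix.shape)
        np.testing.assert_array_equal(tm.matrix, values[i + j])
        if np.linalg.norm(tm.matrix) < 1e-6:  # subnormal inputs: ratios meaningless
            return
        # non-increasing spectrum, orthonormal factors, exact recomposition
        assert np.all(np.diff(tm.singular_values) <= 1e-9 * tm.singular_values[0])
        np.testing.assert_allclose(
            tm.right_vectors @ tm.right_vectors.T, np.eye(tm.right_vectors.shape[0]), atol=1e-10
        )
        rel = np.linalg.norm(tm.reconstruct() - tm.matrix) / np.linalg.norm(tm.matrix)
        assert rel < 1e-8

    def test_pure_sinusoid_has_effective_rank_two(self):
        tm = rb.build_trajectory_matrix(_sine(1.0), L=200)
        assert tm.singular_values[2] / tm.singular_values[0] < 1e-6
        assert tm.signal_rank == 2

    def test_window_shorter_than_lag_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            rb.build_trajectory_matrix(np.arange(5.0), L=10)


class TestExtractTemplate:
    def test_templates_are_orthonormal(self, scene_minus20):
        x = arctangent_demodulate(scene_minus20.iq, scene_minus20.radar.wavelength).displacement
        tm = rb.build_trajectory_matrix(x, 200)
        t = [rb.extract_template(tm, k).values for k in (1, 2, 3, 4)]
        for k in range(4):
            assert np.linalg.norm(t[k]) == pytest.approx(1.0, abs=1e-12)
            for j in range(k + 1, 4):
                assert abs(np.dot(t[k], t[j])) < 1e-8

    def test_sign_convention_survives_global_inversion(self):
        x = _sine(1.0).values + 0.1 * np.sin(2 * np.pi * 0.3 * np.arange(2000) / 100)
        a = rb.extract_template(rb.build_trajectory_matrix(x, 50), 1)
        b = rb.extract_template(rb.build_trajectory_matrix(-x, 50), 1)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)
        assert a.values[np.argmax(np.abs(a.values))] > 0

    def test_cardiac_component_sits_at_index_three_under_interference(self, scene_minus20):
        # with strong respiration the leading pair is respiratory and the
        # third right singular vector oscillates at the heart rate
        x = arctangent_demodulate(scene_minus20.iq, scene_minus20.radar.wavelength).displacement
        tm = rb.build_trajectory_matrix(x, 200)

        def dom(k):
            f, p = periodogram(rb.extract_template(tm, k).values, fs=100, nfft=4096)
            return f[np.argmax(p)]

        assert abs(dom(3) - 1.0) <= 0.2
        assert dom(1) < 0.6  # respiratory band

    def test_index_beyond_rank_reports_rank(self):
        tm = rb.build_trajectory_matrix(np.full(100, 3.14), L=10)
        with pytest.raises(ValueError, match="rank"):
            rb.extract_template(tm, 3)

    def test_select_template_clamps_to_signal_rank(self, scene_heartbeat_only, scene_minus20):
        x = arctangent_demodulate(
            scene_heartbeat_only.iq, scene_heartbeat_only.radar.wavelength
        ).displacement
        tm = rb.build_trajectory_matrix(x, 200)
        assert select_template(tm, 3).source_index == 2  # heart pair only
        x2 = arctangent_demodulate(scene_minus20.iq, scene_minus20.radar.wavelength).displacement
        tm2 = rb.build_trajectory_matrix(x2, 200)
        assert select_template(tm2, 3).source_index == 3  # interference present


def _brute_force_same_correlation(x, h):
    """Independent oracle: direct-sum cross-correlation, 'same' alignment."""
    L = len(h)
    off = (L - 1) - (L - 1) // 2
    out = np.zeros_like(x)
    for n in range(len(x)):
        acc = 0.0
        for k in range(L):
            j = n + k - off
            if 0 <= j < len(x):
                acc += x[j] * h[k]
        out[n] = acc
    return out


class TestMatchedFilter:
    def test_unit_impulse_template_is_identity(self):
        x = _sine(1.0, duration=2.0)
        out = rb.matched_filter(x, np.array([1.0]))
        np.testing.assert_array_equal(out.values, x.values)

    def test_embedded_copy_peaks_at_centre_sample(self):
        rng = np.random.default_rng(3)
        L, p = 31, 40
        h = rng.normal(size=L)
        h /= np.linalg.norm(h)
        x = np.zeros(120)
        x[p : p + L] = h
        out = rb.matched_filter(rb.SampledSignal(x, fs=100), h)
        assert np.argmax(out.values) == p + (L - 1) // 2

    def test_matches_brute_force_oracle_on_random_signals(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(8, 64))
            L = int(rng.integers(1, n + 1))
            x = rng.normal(size=n)
            h = rng.normal(size=L)
            got = rb.matched_filter(rb.SampledSignal(x, fs=1.0), h).values
            np.testing.assert_allclose(got, _brute_force_same_correlation(x, h), atol=1e-10)

    def test_linearity(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        h = rng.normal(size=17)
        mk = lambda v: rb.SampledSignal(v, fs=100)
        left = rb.matched_filter(mk(2.5 * x - 1.5 * y), h).values
        right = 2.5 * rb.matched_filter(mk(x), h).values - 1.5 * rb.matched_filter(mk(y), h).values
        np.testing.assert_allclose(left, right, atol=1e-9)

    def test_template_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            rb.matched_filter(rb.SampledSignal(np.zeros(5), fs=1), np.ones(6))


class TestHeartbeatEnhancer:
    def test_enhanced_waveform_oscillates_at_heart_rate(self, scene_minus20):
        x = arctangent_demodulate(scene_minus20.iq, scene_minus20.radar.wavelength).displacement
        y = rb.enhance(x)
        f, p = periodogram(y.values, fs=100)
        assert f[np.argmax(p)] == pytest.approx(1.0, abs=0.05)

    def test_output_is_normalized_and_deterministic(self, scene_minus20):
        x = arctangent_demodulate(scene_minus20.iq, scene_minus20.radar.wavelength).displacement
        a = rb.enhance(x)
        b = rb.enhance(x)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert a.values.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_raises_not_nans(self):
        x = rb.SampledSignal(np.full(2000, 1.0), fs=100)
        with pytest.raises(ValueError, match="constant"):
            rb.enhance(x)

    def test_fitted_attributes_and_params(self, scene_minus20):
        x = arctangent_demodulate(scene_minus20.iq, scene_minus20.radar.wavelength).displacement
        est = rb.HeartbeatEnhancer().fit(x)
        assert est.template_.values.shape == (200,)
        assert est.used_index_ == 3
        assert est.get_params()["sv_index"] == 3
        cloned = rb.HeartbeatEnhancer(**est.get_params())
        assert cloned.get_params() == est.get_params()

    def test_transform_before_fit_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            rb.HeartbeatEnhancer().transform(_sine(1.0))
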