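"""Hemodynamic signal processing against closed forms and planted truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astroca import physio as ph
from astroca import synthetic as syn


class TestCPP:
    def test_direct_subtraction(self):
        assert ph.compute_cpp(np.array([100.0]), np.array([10.0]))[0] == 90.0
        np.testing.assert_allclose(
            ph.compute_cpp(np.full(5, 100.0), np.zeros(5)), 100.0)

    def test_icp_step_maps_to_cpp_step(self):
        icp = np.r_[np.zeros(50), np.full(50, 12.0)]
        cpp = ph.compute_cpp(np.full(100, 100.0), icp)
        assert cpp[0] - cpp[-1] == pytest.approx(12.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ph.compute_cpp(np.zeros(3), np.zeros(4))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-5, 5, allow_nan=False))
    def test_linearity(self, a):
        m = np.array([100.0, 90.0, 80.0])
        i = np.array([5.0, 10.0, 15.0])
        np.testing.assert_allclose(ph.compute_cpp(a * m, a * i),
                                   a * ph.compute_cpp(m, i))

    def test_optional_cvp_floor(self):
        cpp = ph.compute_cpp(np.full(3, 100.0), np.array([2.0, 5.0, 8.0]),
                             cvp=5.0)
        np.testing.assert_allclose(cpp, [95.0, 95.0, 92.0])


class TestMapAndHR:
    def test_synthetic_six_hz_wave(self):
        fs = 200.0
        t = np.arange(0, 60, 1 / fs)
        abp = 100 + 20 * np.sin(2 * np.pi * 6 * t)
        m, hr = ph.map_and_hr(abp, fs)
        assert abs(m[2000:-2000].mean() - 100) < 0.5
        assert abs(np.nanmedian(hr) - 360.0) / 360.0 < 0.02

    def test_flat_wave_has_missing_hr(self):
        with pytest.warns(UserWarning):
            m, hr = ph.map_and_hr(np.full(2000, 100.0), 100.0)
        np.testing.assert_allclose(m, 100.0)
        assert np.isnan(hr).all()

    def test_planted_hr_plateaus_recovered(self):
        fs = 200.0
        n = int(120 * fs)
        hr_bpm = np.full(n, 300.0)
        hr_bpm[n // 2:] = 420.0
        abp = syn.synthesize_abp(np.full(n, 100.0), hr_bpm, 30.0, fs)
        _, hr = ph.map_and_hr(abp, fs)
        early = np.nanmedian(hr[int(20 * fs):int(50 * fs)])
        late = np.nanmedian(hr[int(80 * fs):int(110 * fs)])
        assert abs(early - 300) / 300 < 0.02
        assert abs(late - 420) / 420 < 0.02


class TestRSNA:
    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(
            ph.rectify_smooth_rsna(np.zeros(100), 100.0), 0.0)

    def test_step_reaches_one_minus_inv_e_at_tau(self):
        fs = 1000.0
        x = np.zeros(int(2 * fs))
        t0 = int(0.5 * fs)
        x[t0:] = 2.0
        y = ph.rectify_smooth_rsna(x, fs, tau=0.1)
        assert y[t0 + int(0.1 * fs)] == pytest.approx(
            2.0 * (1 - np.exp(-1)), rel=0.02)

    def test_transfer_function_attenuation(self):
        fs = 2000.0
        tau = 0.1
        t = np.arange(0, 20, 1 / fs)
        for f in (0.5, 2.0):
            env = 1.0 + 0.5 * np.sin(2 * np.pi * f * t)
            y = ph.rectify_smooth_rsna(env, fs, tau=tau)
            ripple = y[len(y) // 2:]
            gain = (ripple.max() - ripple.min()) / 1.0
            expect = 1.0 / np.sqrt(1 + (2 * np.pi * f * tau) ** 2)
            assert abs(gain - expect) / expect < 0.05

    def test_smoothing_is_a_contraction(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 5000)
        y = ph.rectify_smooth_rsna(x, 500.0)
        assert np.abs(y).max() <= np.abs(x).max() + 1e-12

    def test_normalization_endpoints_and_midpoint(self):
        x = np.array([0.2, 1.0, 0.6])
        out = ph.normalize_rsna(x, resting_level=1.0, blockade_floor=0.2)
        np.testing.assert_allclose(out, [0.0, 100.0, 50.0])
        with pytest.raises(ValueError):
            ph.normalize_rsna(x, resting_level=0.1, blockade_floor=0.2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.floats(-5, 5))
    def test_normalization_is_affine_order_preserving(self, scale, shift):
        x = np.array([0.3, 0.5, 0.9])
        out = ph.normalize_rsna(x, 1.0, 0.0)
        assert np.all(np.diff(out) > 0) == np.all(np.diff(x) > 0)
        out2 = ph.normalize_rsna(scale * x + shift, scale * 1.0 + shift,
                                 shift)
        np.testing.assert_allclose(out2, out, atol=1e-9)


class TestResponseDelay:
    def test_noiseless_planted_delay(self):
        p = syn.SyntheticPhysioParams(icp_noise_sd=0.0, abp_noise_sd=0.0,
                                      pulse_pressure=0.0, seed=0)
        rec, _ = syn.generate_physio(p)
        proto = ph.StimulusProtocol(p.step_onset,
                                    p.step_onset + p.step_duration)
        d = ph.response_delay(rec.icp, rec.abp, rec.sample_rate, proto,
                              baseline_window=120.0)
        assert d == pytest.approx(30.0, abs=0.5)

    def test_null_response_yields_missing(self):
        rng = np.random.default_rng(11)
        fs = 50.0
        n = int(600 * fs)
        flat = 100.0 + rng.normal(0, 1.0, n)
        proto = ph.StimulusProtocol(200.0, 400.0)
        import warnings
        misses = 0
        for s in range(40):
            resp = 100.0 + np.random.default_rng(s).normal(0, 1.0, n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = ph.response_delay(flat, resp, fs, proto,
                                      baseline_window=120.0)
            misses += d is None
        assert misses / 40 >= 0.95

    def test_monte_carlo_delay_recovery(self):
        delays = []
        for s in range(15):
            p = syn.SyntheticPhysioParams(seed=s, duration=600.0,
                                          step_onset=150.0,
                                          step_duration=300.0)
            rec, _ = syn.generate_physio(p)
            proto = ph.StimulusProtocol(150.0, 450.0)
            r = ph.response_summary(rec, proto)
            delays.append(r.response_delay)
        assert abs(np.mean(delays) - 30.0) < 2.0


class TestResponseSummary:
    def test_null_recording_has_small_deltas(self):
        p = syn.SyntheticPhysioParams(pressor_amplitude=0.0, hr_delta=0.0,
                                      icp_step=0.0, seed=1)
        rec, _ = syn.generate_physio(p)
        proto = ph.StimulusProtocol(p.step_onset,
                                    p.step_onset + p.step_duration)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = ph.response_summary(rec, proto)
        assert abs(r.delta_map) < 0.5
        assert abs(r.delta_hr) < 2.0

    def test_planted_pressor_amplitude_recovered(self):
        amps = []
        for s in range(8):
            p = syn.SyntheticPhysioParams(seed=s)
            rec, _ = syn.generate_physio(p)
            proto = ph.StimulusProtocol(p.step_onset,
                                        p.step_onset + p.step_duration)
            amps.append(ph.response_summary(rec, proto).peak_delta_map)
        assert abs(np.mean(amps) - 20.0) < 2.0

    def test_planted_persistence_recovered(self):
        pers = []
        for s in range(5):
            p = syn.SyntheticPhysioParams(seed=s)
            rec, _ = syn.generate_physio(p)
            proto = ph.StimulusProtocol(p.step_onset,
                                        p.step_onset + p.step_duration)
            pers.append(ph.response_summary(rec, proto).persistence)
        assert abs(np.mean(pers) - 120.0) < 15.0
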