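"""Baseline F₀(t) estimation: IRLS smoothing, low-rank trend, ΔF/F₀."""

import numpy as np
import pytest

from astroca import baseline as bl
from astroca import synthetic as syn


def _rmse(a, b):
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


class TestIRLSSmooth:
    def test_constant_trace_unchanged(self):
        z = bl.irls_smooth(np.full(100, 3.0))
        assert np.abs(z - 3.0).max() < 1e-9

    def test_linear_ramp_preserved(self):
        t = np.linspace(0, 1, 200)
        ramp = 2.0 * t + 1.0
        z = bl.irls_smooth(ramp)
        assert np.abs(z - ramp).max() / np.abs(ramp).max() < 0.01

    def test_boxcar_upswing_rejected_on_slow_sinusoid(self):
        n = 300
        t = np.linspace(0, 1, n)
        sine = np.sin(2 * np.pi * t)
        amp = 1.0
        y = sine.copy()
        y[100:115] += amp        # upswing 5% of trace length
        z = bl.irls_smooth(y)
        assert np.abs(z - sine).max() < 0.2 * amp

    @pytest.mark.parametrize("bad", [np.ones(3), np.r_[np.ones(9), np.nan]])
    def test_short_or_nonfinite_traces_rejected(self, bad):
        with pytest.raises(ValueError):
            bl.irls_smooth(bad)


class TestLowrankTrend:
    def test_rank_one_smooth_matrix_reproduced(self):
        t = np.linspace(0, 1, 100)
        F = np.outer(1 + 0.2 * np.sin(2 * np.pi * t), np.ones(50)) * 37.0
        trend = bl.lowrank_trend(F, r=1, n_outer=1)
        assert np.abs(trend - F).max() / np.abs(F).max() < 0.02

    def test_output_numerical_rank_bounded_by_r(self, still_movie):
        _, movie, _ = still_movie
        F = movie.functional.reshape(movie.n_frames, -1)
        trend = bl.lowrank_trend(bl.FluorescenceMatrix(F=F), r=20)
        sv = np.linalg.svd(trend, compute_uv=False)
        assert np.sum(sv > 1e-8 * sv[0]) <= 20

    def test_trend_recovers_planted_drift_under_noise(self, still_movie):
        params, movie, truth = still_movie
        trend = bl.lowrank_trend(
            bl.FluorescenceMatrix.from_stack(movie.functional), r=20)
        err = _rmse(trend.reshape(movie.functional.shape),
                    truth.baseline_movie)
        assert err < 0.5 * params.noise_sd

    def test_zero_rank_rejected_and_constant_returned(self):
        with pytest.raises(ValueError):
            bl.lowrank_trend(np.ones((10, 4)), r=0)
        const = np.full((10, 4), 5.0)
        np.testing.assert_allclose(bl.lowrank_trend(const, r=2), const)


class TestLocalCorrection:
    def test_zero_residual_returns_trend_exactly(self):
        trend = np.random.default_rng(0).random((40, 24, 24)) + 10
        est = bl.local_correction(np.zeros_like(trend), trend)
        np.testing.assert_allclose(est.F0, trend)

    def test_constant_negative_residual_blends_to_unity(self):
        # partition-of-unity: a constant offset must be reproduced exactly
        # everywhere once the overlapping-window weights are normalized
        trend = np.full((40, 24, 24), 50.0)
        resid = np.full_like(trend, -3.0)
        est = bl.local_correction(resid, trend)
        np.testing.assert_allclose(est.F0, trend - 3.0, atol=1e-9)

    def test_local_offset_missed_by_trend_is_corrected(self, still_movie):
        params, movie, truth = still_movie
        trend = bl.lowrank_trend(
            bl.FluorescenceMatrix.from_stack(movie.functional), r=20
        ).reshape(movie.functional.shape)
        # plant a smooth localized *negative* dip the global trend missed
        dip = np.zeros_like(trend)
        t = np.arange(movie.n_frames)
        bump = -8.0 * np.exp(-0.5 * ((t - 75) / 20.0) ** 2)
        dip[:, 16:48, 16:48] = bump[:, None, None]
        stack = movie.functional + dip
        target = truth.baseline_movie + dip
        est = bl.local_correction(stack - trend, trend)
        assert _rmse(est.F0, target) < _rmse(trend, target)
        reg = np.s_[:, 16:48, 16:48]
        assert _rmse(est.F0[reg], target[reg]) < 0.8 * _rmse(trend[reg],
                                                             target[reg])

    def test_window_larger_than_movie_rejected(self):
        with pytest.raises(ValueError):
            bl.local_correction(np.zeros((10, 8, 8)), np.zeros((10, 8, 8)),
                                window=(30, 16))


class TestComputeDff:
    def test_identity_and_scalar_cases(self):
        f0 = np.full((5, 4, 4), 50.0)
        out = bl.compute_dff(f0.copy(), f0)
        np.testing.assert_allclose(out.dff, 0.0)
        out2 = bl.compute_dff(1.2 * f0, f0)
        np.testing.assert_allclose(out2.dff, 0.2)

    def test_noiseless_movie_peaks_match_planted_amplitude(self):
        p = syn.SyntheticMovieParams(height=48, width=48, n_frames=150,
                                     noise_sd=0.0, rigid_shift_amplitude=0.0,
                                     nonrigid_amplitude=0.0, seed=2)
        movie, truth = syn.generate_movie(p)
        dff = bl.compute_dff(movie.functional, truth.baseline_movie)
        peaks = []
        for i in range(truth.n_rois):
            sig = truth.roi_signals[i]
            if sig.max() < 0.9 * p.transient_amplitude:
                continue
            mask = truth.label_image == i + 1
            roi_dff = dff.dff[:, mask].mean(axis=1)
            peaks.append(roi_dff[np.argmax(sig)] / sig.max())
        assert peaks, "expected at least one full-amplitude event"
        assert np.abs(np.array(peaks) - 1.0).max() < 0.02

    def test_dff_bounded_below_where_f_nonneg(self, still_movie):
        _, movie, _ = still_movie
        est = bl.estimate_baseline(movie.functional, r=10)
        dff = bl.compute_dff(movie.functional, est)
        assert dff.dff.min() >= -1.0 - 1e-12


class TestBaselineProperties:
    def test_full_estimate_tracks_planted_baseline(self, still_movie):
        params, movie, truth = still_movie
        est = bl.estimate_baseline(movie.functional, r=20)
        assert _rmse(est.F0, truth.baseline_movie) < 0.5 * params.noise_sd

    def test_f0_stays_below_running_median_band(self, still_movie):
        # upswing rejection: F0 should not ride on top of transients
        params, movie, truth = still_movie
        est = bl.estimate_baseline(movie.functional, r=20)
        lab = truth.label_image
        ok = total = 0
        for i in range(1, truth.n_rois + 1):
            m = lab == i
            raw = movie.functional[:, m].mean(axis=1)
            f0 = est.F0[:, m].mean(axis=1)
            med = np.array([np.median(raw[max(0, t - 15):t + 15])
                            for t in range(len(raw))])
            ok += np.sum(f0 <= med + 2 * params.noise_sd)
            total += len(raw)
        assert ok / total >= 0.95

    def test_f0_inside_percentile_band_of_raw_traces(self, still_movie):
        # automated surrogate for by-eye validation of the baseline:
        # per-ROI F0 must track the lower-middle of the raw distribution
        # in sliding windows (tolerance of half the trace noise SD)
        from astroca import detection as det
        _, movie, truth = still_movie
        est = bl.estimate_baseline(movie.functional, r=20)
        inside = total = 0
        for i in range(1, truth.n_rois + 1):
            m = truth.label_image == i
            raw = movie.functional[:, m].mean(axis=1)
            f0 = est.F0[:, m].mean(axis=1)
            tol = 0.5 * det.estimate_noise_sd(raw)
            for t in range(len(raw)):
                lo, hi = np.percentile(raw[max(0, t - 20):t + 20], [5, 60])
                inside += lo - tol <= f0[t] <= hi + tol
                total += 1
        assert inside / total >= 0.9

    def test_f0_temporal_variation_is_slow(self, still_movie):
        _, movie, _ = still_movie
        est = bl.estimate_baseline(movie.functional, r=20)
        step = np.abs(np.diff(est.F0, axis=0)).max(axis=0)
        span = est.F0.max(axis=0) - est.F0.min(axis=0) + 1e-9
        assert np.median(step / span) < 0.35
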