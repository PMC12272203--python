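"""Preprocessing chain: QC, Delta OD, motion handling, block averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.interpolate import make_smoothing_spline

from hddot.preprocess import (
    BLOCK_GRID,
    ODTimeSeries,
    RawRecording,
    TrialLog,
    block_average,
    correct_spline,
    correct_wavelet,
    detect_motion,
    find_clean_segment,
    intensity_to_od,
    qc_channels,
    smoothing_spline,
    validate_trials,
)

FS = 25.0 / 3.0


def channel_table(n, separation=30.0):
    return pd.DataFrame(
        {
            "source": np.zeros(n, int),
            "detector": np.arange(n),
            "wavelength": np.full(n, 735.0),
            "separation": np.full(n, float(separation)),
        }
    )


def od_series(x, fs=FS, separation=30.0):
    x = np.atleast_2d(np.asarray(x, float))
    return ODTimeSeries(
        od=x, fs=fs, channels=channel_table(len(x), separation),
        mean_intensity=np.ones(len(x)),
    )


class TestQC:
    def test_constant_bright_channel_passes(self):
        rec = RawRecording(np.full((1, 200), 1e-3), FS, channel_table(1))
        rep = qc_channels(rec)
        assert rep["good"].all() and rep["cov_percent"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_dim_channel_fails_on_intensity(self):
        rec = RawRecording(np.full((1, 200), 1e-5), FS, channel_table(1))
        rep = qc_channels(rec)
        assert not rep["good"].iloc[0]
        assert rep["reasons"].iloc[0] == "intensity"

    def test_long_channel_fails_on_separation(self):
        rec = RawRecording(np.full((1, 200), 1e-3), FS, channel_table(1, separation=65.0))
        rep = qc_channels(rec)
        assert rep["reasons"].iloc[0] == "separation"

    def test_noisy_channel_fails_on_cov(self):
        rng = np.random.default_rng(0)
        x = 1e-3 * (1 + 0.2 * rng.standard_normal(500))
        rep = qc_channels(RawRecording(np.abs(x)[None, :], FS, channel_table(1)))
        assert "cov" in rep["reasons"].iloc[0]

    def test_zero_mean_channel_fails_cov(self):
        rec = RawRecording(np.zeros((1, 100)), FS, channel_table(1))
        rep = qc_channels(rec)
        assert "cov" in rep["reasons"].iloc[0]

    def test_cov_computed_on_clean_segment(self):
        x = np.full(400, 1e-3)
        x[300:] *= 5.0  # artifact at the end
        rec = RawRecording(x[None, :], FS, channel_table(1))
        assert not qc_channels(rec)["good"].iloc[0]
        assert qc_channels(rec, clean_segment=(0.0, 300 / FS))["good"].iloc[0]


class TestIntensityToOD:
    def test_constant_gives_zero(self):
        od = intensity_to_od(RawRecording(np.full((1, 50), 2e-3), FS, channel_table(1)))
        np.testing.assert_allclose(od.od, 0.0, atol=1e-15)

    def test_sample_at_mean_over_e(self):
        x = np.full(100, 1.0)
        # choose one sample so that mean stays 1 and that sample is 1/e
        x[0] = np.exp(-1.0)
        x[1] = 2.0 - np.exp(-1.0)
        od = intensity_to_od(RawRecording(x[None, :], FS, channel_table(1)))
        assert od.od[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(-6, 0.3, (4, 300)))
        rec = RawRecording(x, FS, channel_table(4))
        od = intensity_to_od(rec)
        np.testing.assert_allclose(od.to_intensity(), x, rtol=1e-12)

    def test_nonpositive_rejected(self):
        x = np.full((1, 50), 1e-3)
        x[0, 7] = 0.0
        with pytest.raises(ValueError, match="sample 7"):
            intensity_to_od(RawRecording(x, FS, channel_table(1)))


class TestDetectMotion:
    def test_flat_signal_unflagged(self):
        assert not detect_motion(od_series(np.zeros(300))).any()

    def test_step_flagged_with_mask_extent(self):
        x = np.zeros(400)
        x[200:] = 0.6
        mask = detect_motion(od_series(x))
        assert mask.any()
        flagged = np.flatnonzero(mask[0]) / FS
        t_step = 200 / FS
        # extends about t_mask + window around the step, not much further
        assert flagged.min() >= t_step - 2.2
        assert flagged.max() <= t_step + 2.2

    def test_subthreshold_step_with_large_channel_std_unflagged(self):
        # slow oscillation gives robust std ~0.042 (15*std ~ 0.63) without
        # adding in-window variability; a 0.4 step stays below both limits
        t = np.arange(600) / FS
        x = 0.04 * np.sin(2 * np.pi * 0.05 * t)
        x[300:] += 0.4
        assert not detect_motion(od_series(x)).any()

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            detect_motion(od_series(np.zeros(100)), t_motion=0.05)

    def test_clean_segment_finder(self):
        mask = np.zeros((3, 500), dtype=bool)
        mask[:, 100:140] = True
        seg = find_clean_segment(mask, FS, min_s=10.0)
        lo, hi = seg
        assert lo == pytest.approx(140 / FS)
        assert hi == pytest.approx(500 / FS)


class TestSmoothingSpline:
    @pytest.mark.parametrize("p", [0.99, 0.9, 0.5])
    def test_matches_scipy_oracle(self, p):
        rng = np.random.default_rng(0)
        t = np.linspace(0.0, 5.0, 120)
        y = np.sin(2 * t) + rng.normal(0, 0.2, len(t))
        ref = make_smoothing_spline(t, y, lam=(1 - p) / p)(t)
        np.testing.assert_allclose(smoothing_spline(t, y, p), ref, atol=1e-10)

    def test_p_one_interpolates(self):
        t = np.linspace(0, 1, 40)
        y = np.cos(t * 7)
        np.testing.assert_allclose(smoothing_spline(t, y, 1.0), y, atol=1e-12)

    def test_batched_rows_match_individual(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 3, 80)
        Y = rng.standard_normal((5, 80))
        batch = smoothing_spline(t, Y, 0.95)
        for k in range(5):
            np.testing.assert_allclose(batch[k], smoothing_spline(t, Y[k], 0.95),
                                       atol=1e-10)


class TestCorrectSpline:
    def test_empty_mask_identity(self):
        x = np.sin(np.arange(300) / 20.0)[None, :]
        od = od_series(x)
        out = correct_spline(od, np.zeros_like(x, dtype=bool))
        np.testing.assert_array_equal(out.od, x)

    def test_transient_jump_rmse_reduced(self):
        t = np.arange(600) / FS
        clean = 0.05 * np.sin(2 * np.pi * 0.1 * t)
        dirty = clean.copy()
        dirty[300:330] += 0.8  # transient artifact inside a flagged segment
        od = od_series(dirty)
        mask = detect_motion(od)
        assert mask[0, 310]
        out = correct_spline(od, mask)
        rmse_pre = np.sqrt(np.mean((dirty - clean) ** 2))
        rmse_post = np.sqrt(np.mean((out.od[0] - clean) ** 2))
        assert rmse_post < rmse_pre

    def test_interpolating_limit_flattens_segment(self):
        t = np.arange(200) / FS
        x = np.sin(t)[None, :].copy()
        mask = np.zeros_like(x, dtype=bool)
        mask[0, 80:120] = True
        out = correct_spline(od_series(x), mask, p=1.0)
        seg = out.od[0, 80:120]
        # interpolating spline removes all structure; only the continuity
        # level remains
        assert np.ptp(seg) < 1e-8

    def test_unflagged_structure_preserved(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 250)) * 0.01
        mask = np.zeros_like(x, dtype=bool)
        mask[:, 100:130] = True
        out = correct_spline(od_series(x), mask)
        # data before the artifact untouched; data after only level-shifted
        np.testing.assert_array_equal(out.od[:, :100], x[:, :100])
        np.testing.assert_allclose(
            np.diff(out.od[:, 130:]), np.diff(x[:, 130:]), atol=1e-12
        )

    def test_step_artifact_removed_with_continuity(self):
        t = np.arange(600) / FS
        clean = 0.02 * np.sin(2 * np.pi * 0.1 * t)
        dirty = clean.copy()
        dirty[300:] += 0.6  # persistent baseline shift
        od = od_series(dirty)
        mask = detect_motion(od)
        out = correct_spline(od, mask)
        # the step is gone: late samples sit near the early baseline again
        late = out.od[0, 500:]
        assert np.abs(late - clean[500:]).mean() < 0.1
        # the spline leaves at most a sample-wide transient at the step;
        # the wavelet stage then suppresses it
        both = correct_wavelet(out)
        rmse_pre = np.sqrt(np.mean((dirty - clean) ** 2))
        rmse_post = np.sqrt(np.mean((both.od[0] - clean) ** 2))
        assert rmse_post < 0.2 * rmse_pre


class TestCorrectWavelet:
    def test_huge_fence_is_identity(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2, 512)) * 0.01
        out = correct_wavelet(od_series(x), a=1e9)
        np.testing.assert_allclose(out.od, x, atol=1e-10)

    def test_spike_suppressed_clean_preserved(self):
        t = np.arange(1024) / FS
        clean = 0.02 * np.sin(2 * np.pi * 0.08 * t)
        spiky = clean.copy()
        spike_amp = 10 * clean.std()
        spiky[500] += spike_amp
        out = correct_wavelet(od_series(np.vstack([spiky, clean])))
        residual_spike = abs(out.od[0, 500] - clean[500])
        assert residual_spike < 0.2 * spike_amp  # >= 80% suppression
        # non-spike samples barely change
        others = np.abs(out.od[0] - clean)
        others[490:510] = 0
        assert np.sqrt(np.mean(others**2)) < 0.1 * clean.std()

    def test_gaussian_zeroing_fraction_matches_normal_mass(self):
        """For white noise, the zeroed-coefficient fraction approximates the
        Gaussian mass outside the a=0.8 quartile fence."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal((64, 2048))
        out = correct_wavelet(od_series(x), a=0.8)
        # expected two-sided mass outside [Q1 - 0.8 IQR, Q3 + 0.8 IQR]
        q1, q3 = sps.norm.ppf([0.25, 0.75])
        fence = q3 + 0.8 * (q3 - q1)
        expected = 2 * sps.norm.sf(fence)
        # measure the fraction actually zeroed by reusing the rule directly
        import pywt

        coeffs = pywt.wavedec(x, "db2", level=7, axis=1)
        zeroed, total = 0, 0
        for d in coeffs[1:]:
            qq1, qq3 = np.percentile(d, [25, 75], axis=1)
            iqr = qq3 - qq1
            out_mask = (d < (qq1 - 0.8 * iqr)[:, None]) | (d > (qq3 + 0.8 * iqr)[:, None])
            zeroed += out_mask.sum()
            total += d.size
        assert zeroed / total == pytest.approx(expected, abs=0.02)

    def test_short_signal_passthrough_with_warning(self):
        x = np.zeros((1, 8))
        with pytest.warns(UserWarning, match="short"):
            out = correct_wavelet(od_series(x))
        np.testing.assert_array_equal(out.od, x)


class TestValidateTrials:
    def make_log(self, looks, conditions=None, alerts=None):
        n = len(looks)
        conditions = conditions or ["social"] * n
        alerts = alerts if alerts is not None else [False] * n
        return TrialLog(
            pd.DataFrame(
                {
                    "condition": conditions,
                    "onset": np.arange(n) * 20.0,
                    "duration": np.full(n, 10.0),
                    "looking_fraction": looks,
                    "alert_flag": alerts,
                }
            )
        )

    def test_59_percent_looking_invalid(self):
        t, _ = validate_trials(self.make_log([0.59, 0.60]))
        assert list(t["valid"]) == [False, True]

    def test_three_plus_three_included(self):
        log = self.make_log(
            [0.9] * 6, conditions=["social"] * 3 + ["non-social"] * 3
        )
        _, included = validate_trials(log)
        assert included

    def test_nine_plus_two_excluded(self):
        log = self.make_log(
            [0.9] * 11, conditions=["social"] * 9 + ["non-social"] * 2
        )
        _, included = validate_trials(log)
        assert not included

    def test_alerted_trial_removed(self):
        log = self.make_log([0.9, 0.9], alerts=[True, False])
        t, _ = validate_trials(log)
        assert list(t["valid"]) == [False, True]

    def test_overlapping_trials_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TrialLog(
                pd.DataFrame(
                    {
                        "condition": ["social", "social"],
                        "onset": [0.0, 5.0],
                        "duration": [10.0, 10.0],
                        "looking_fraction": [1.0, 1.0],
                        "alert_flag": [False, False],
                    }
                )
            )


class TestBlockAverage:
    FS_EXACT = 25.0 / 6.0  # sample clock commensurate with 0.24 s steps

    def trials(self, onsets):
        return pd.DataFrame(
            {
                "condition": ["social"] * len(onsets),
                "onset": onsets,
                "duration": [10.0] * len(onsets),
                "looking_fraction": [1.0] * len(onsets),
                "alert_flag": [False] * len(onsets),
                "valid": [True] * len(onsets),
            }
        )

    def test_grid_is_89_samples(self):
        assert len(BLOCK_GRID) == 89
        assert BLOCK_GRID[0] == -2.0 and BLOCK_GRID[-1] == 20.0

    def test_piecewise_linear_waveform_exact(self):
        fs = self.FS_EXACT
        t = np.arange(int(80 * fs)) / fs
        onset = 24.0  # on the sample clock (0.24 s steps)
        knots = [onset, onset + 4.8, onset + 9.6, onset + 14.4]  # sample-aligned
        x = np.interp(t, knots, [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)
        od = od_series(x[None, :], fs=fs)
        ba = block_average(od, self.trials([onset]))["social"]
        expected = np.interp(ba.grid, [0.0, 4.8, 9.6, 14.4], [0, 1, 1, 0],
                             left=0.0, right=0.0)
        expected -= expected[ba.grid <= 0].mean()
        np.testing.assert_allclose(ba.data[0], expected, atol=1e-12)

    def test_two_identical_epochs_average_to_one(self):
        fs = self.FS_EXACT
        t = np.arange(int(150 * fs)) / fs
        onsets = [24.0, 96.0]
        x = np.zeros_like(t)
        for on in onsets:
            x += np.interp(t, [on, on + 4.8, on + 14.4], [0, 1, 0], left=0, right=0) * (
                (t >= on) & (t <= on + 14.4)
            )
        od = od_series(x[None, :], fs=fs)
        one = block_average(od, self.trials(onsets[:1]))["social"]
        both = block_average(od, self.trials(onsets))["social"]
        np.testing.assert_allclose(both.data, one.data, atol=1e-12)

    def test_baseline_interval_mean_is_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 2000)) * 0.01
        od = od_series(x, fs=FS)
        ba = block_average(od, self.trials([50.0, 100.0, 150.0]))["social"]
        base = ba.data[:, ba.grid <= 0]
        np.testing.assert_allclose(base.mean(axis=1), 0.0, atol=1e-14)

    def test_noise_averaging_shrinks_rmse_like_sqrt_n(self):
        """Monte-Carlo: averaging 9 noisy epochs shrinks waveform RMSE ~3x."""
        rng = np.random.default_rng(7)
        fs = self.FS_EXACT
        hrf_grid = np.clip(BLOCK_GRID, 0, None)
        true_wave = hrf_grid * np.exp(-hrf_grid / 5.0)  # arbitrary smooth shape
        true_wave -= true_wave[BLOCK_GRID <= 0].mean()
        ratios = []
        for rep in range(12):
            onsets = 30.0 + 30.0 * np.arange(9)
            t = np.arange(int((onsets[-1] + 40) * fs)) / fs
            x = np.zeros_like(t)
            for on in onsets:
                x += np.interp(t - on, BLOCK_GRID, true_wave, left=0, right=0)
            noise = 0.5 * rng.standard_normal(len(t))
            od = od_series((x + noise)[None, :], fs=fs)
            nine = block_average(od, self.trials(onsets))["social"]
            one = block_average(od, self.trials(onsets[:1]))["social"]
            e9 = np.sqrt(np.mean((nine.data[0] - true_wave) ** 2))
            e1 = np.sqrt(np.mean((one.data[0] - true_wave) ** 2))
            ratios.append(e1 / e9)
        # expect ~sqrt(9) = 3 improvement on average
        assert 2.0 < np.mean(ratios) < 4.5

    def test_epoch_beyond_recording_dropped(self):
        od = od_series(np.zeros((1, 200)), fs=FS)
        with pytest.warns(UserWarning, match="bounds"):
            ba = block_average(od, self.trials([200 / FS - 5.0]))["social"]
        assert ba.n_trials == 0
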