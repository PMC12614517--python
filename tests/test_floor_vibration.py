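"""Floor-vibration pipeline: filtering, sync, detection, localization, speed."""

import numpy as np
import pytest
from scipy import signal as sps

from ambientgait import (
    StepSeries,
    VibeParams,
    VibrationError,
    VibrationRecord,
    WalkerParams,
    cadence_from_steps,
    detect_steps,
    instantaneous_cadence_z,
    kalman_speed,
    localize_steps,
    preprocess,
    simulate_trial,
    snr_max,
    synchronize,
)
from ambientgait.floor_vibration import floor_metrics
from ambientgait.synthetic_walker import default_sensor_layout


def _record(data, fs=4096.0, sync=True):
    layout, groups, pair = default_sensor_layout()
    return VibrationRecord(fs, data, layout, groups, pair if sync else None)


def _noise_record(rng, fs=4096.0, duration=10.0, sd=0.01, n_chan=7):
    return _record(rng.normal(0, sd, (n_chan, int(fs * duration))), fs)


class TestPreprocess:
    def test_constant_offset_removed(self):
        rec = _record(np.full((7, 8192), 3.7))
        out = preprocess(rec)
        assert np.max(np.abs(out.data)) <= 1e-8 * 3.7

    @pytest.mark.parametrize("freq,check", [(100.0, "pass"), (1.0, "stop")])
    def test_band_edges_match_cascaded_response_oracle(self, freq, check):
        fs = 4096.0
        t = np.arange(int(fs * 10)) / fs
        data = np.tile(np.sin(2 * np.pi * freq * t), (7, 1))
        out = preprocess(_record(data, fs))
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        amp = np.max(np.abs(out.data[0, mid]))
        # oracle: |H_hp|^2 * |H_lp|^2 at this frequency (forward-backward
        # squares each magnitude response)
        w, h_hp = sps.freqz(*sps.butter(2, 5, "highpass", fs=fs),
                            worN=[freq], fs=fs)
        _, h_lp = sps.freqz(*sps.butter(2, 250, "lowpass", fs=fs),
                            worN=[freq], fs=fs)
        expected = float((np.abs(h_hp) ** 2 * np.abs(h_lp) ** 2)[0])
        if check == "pass":
            assert amp == pytest.approx(expected, rel=0.01)
            # the 250 Hz corner already shaves ~2% off a 100 Hz tone after
            # the forward-backward (magnitude-squared) pass
            assert amp == pytest.approx(1.0, abs=0.03)
        else:
            assert amp <= max(0.01, 2 * expected)

    def test_zero_phase_impulse_window_preserved(self):
        fs = 4096.0
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1e-4, (7, int(fs * 4)))
        t = np.arange(int(fs * 4)) / fs
        burst = np.exp(-0.5 * ((t - 2.0) / 0.01) ** 2) * np.sin(
            2 * np.pi * 80 * (t - 2.0))
        data[2] += burst
        rec = _record(data, fs)
        win = int(0.02 * fs)

        def peak_window(r):
            n_win = r.n_samples // win
            p = (r.data[2, : n_win * win] ** 2).reshape(n_win, win).mean(axis=1)
            return int(np.argmax(p))

        assert peak_window(preprocess(rec)) == peak_window(rec)

    def test_too_short_channel(self):
        with pytest.raises(VibrationError):
            preprocess(_record(np.zeros((7, 10))))


class TestSynchronize:
    @pytest.mark.parametrize("lag", [0.25, -0.125, 0.0])
    def test_injected_lag_recovered(self, lag):
        fs = 4096.0
        _, rec, truth = simulate_trial(
            WalkerParams(), VibeParams(sample_rate=fs, daq_lag=lag), seed=4)
        out, est = synchronize(preprocess(rec))
        assert est == pytest.approx(lag, abs=1.0 / fs)
        assert out.n_channels == rec.n_channels - 1

    def test_gain_invariance_of_lag(self):
        fs = 4096.0
        _, rec, _ = simulate_trial(
            WalkerParams(), VibeParams(sample_rate=fs, daq_lag=0.2), seed=6)
        pre = preprocess(rec)
        _, lag0 = synchronize(pre)
        boosted = pre.data.copy()
        boosted[pre.sync_pair[0]] *= 10.0
        rec10 = VibrationRecord(fs, boosted, pre.layout, pre.daq_group,
                                pre.sync_pair)
        _, lag10 = synchronize(rec10)
        assert lag10 == lag0

    def test_silent_channels_rejected(self):
        rec = _record(np.zeros((7, 8192)))
        with pytest.raises(VibrationError):
            synchronize(rec)


class TestSnrMax:
    def test_median_normalization_is_exact(self):
        rng = np.random.default_rng(2)
        snr = snr_max(_noise_record(rng))
        med = np.median(snr.per_sensor_snr, axis=0)
        np.testing.assert_allclose(med, 1.0, atol=1e-15)
        np.testing.assert_allclose(
            snr.snr_max, snr.per_sensor_snr.max(axis=1))

    def test_per_channel_gain_invariance(self):
        rng = np.random.default_rng(3)
        rec = _noise_record(rng)
        gains = rng.uniform(0.1, 10.0, rec.n_channels)
        rec_g = _record(rec.data * gains[:, None])
        np.testing.assert_allclose(snr_max(rec_g).per_sensor_snr,
                                   snr_max(rec).per_sensor_snr, rtol=1e-12)

    def test_single_impulse_dominates_its_window(self):
        rng = np.random.default_rng(4)
        rec = _noise_record(rng, duration=5.0)
        i = int(2.513 * rec.sample_rate)
        rec.data[3, i] += 5.0
        snr = snr_max(rec)
        assert snr.window_times[np.argmax(snr.snr_max)] == pytest.approx(
            2.513, abs=0.02)

    def test_record_shorter_than_window(self):
        with pytest.raises(VibrationError):
            snr_max(_record(np.ones((7, 10))))


class TestDetectSteps:
    def test_simulated_trial_all_steps_within_two_hundredths(
            self, nominal_trial):
        _, rec, truth = nominal_trial
        sync, _ = synchronize(preprocess(rec))
        steps = detect_steps(snr_max(sync))
        assert steps.n_steps == len(truth.step_times)
        np.testing.assert_allclose(steps.step_times, truth.step_times,
                                   atol=0.02)

    def test_min_distance_suppresses_close_impulses(self):
        rng = np.random.default_rng(5)
        rec = _noise_record(rng, duration=5.0)
        fs = rec.sample_rate
        rec.data[:, int(2.0 * fs)] += 4.0
        rec.data[:, int(2.2 * fs)] += 3.0  # 0.2 s apart: suppressed
        steps = detect_steps(snr_max(rec))
        assert steps.n_steps == 1
        assert steps.step_times[0] == pytest.approx(2.0, abs=0.02)

    def test_pure_noise_yields_no_steps(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            rec = preprocess(_noise_record(rng))
            if detect_steps(snr_max(rec)).n_steps > 0:
                hits += 1
        assert hits == 0

    def test_constant_signal_degenerate(self):
        with pytest.raises(VibrationError):
            detect_steps(snr_max(_record(np.ones((7, 8192)))))


class TestCadenceFromSteps:
    def test_uniform_half_second_gaps(self):
        steps = StepSeries(np.arange(10) * 0.5)
        assert cadence_from_steps(steps).cadence == pytest.approx(120.0)

    def test_missed_step_removed_by_outlier_rule(self):
        # nineteen 0.5 s gaps plus one doubled gap: MAD = 0, fallback
        # removes the 1.0 s gap, leaving exactly 120 steps/min
        times = np.concatenate([np.arange(10) * 0.5,
                                4.5 + 1.0 + np.arange(10) * 0.5])
        res = cadence_from_steps(StepSeries(times))
        assert res.cadence == pytest.approx(120.0)
        assert res.n_outliers == 1
        assert res.n_missed == 1

    def test_faster_gait(self):
        steps = StepSeries(np.arange(8) * 0.4)
        assert cadence_from_steps(steps).cadence == pytest.approx(150.0)

    def test_too_few_steps(self):
        with pytest.raises(VibrationError):
            cadence_from_steps(StepSeries([0.0, 0.5, 1.0]))


class TestInstantaneousCadenceZ:
    def test_periodic_degenerate(self):
        with pytest.raises(VibrationError):
            instantaneous_cadence_z(StepSeries(np.arange(10) * 0.5))

    def test_doubled_gap_is_unique_minimum(self):
        rng = np.random.default_rng(6)
        intervals = np.concatenate(
            [0.5 + rng.normal(0, 0.01, 8), [1.0], 0.5 + rng.normal(0, 0.01, 8)])
        z = instantaneous_cadence_z(StepSeries(np.cumsum(intervals)))
        # the doubled interval is gap index 7 of the step-time differences
        assert np.argmin(z) == 7
        assert sorted(z)[1] - z[7] > 1.0

    def test_normalization_identity(self):
        rng = np.random.default_rng(7)
        times = np.cumsum(0.5 + rng.normal(0, 0.03, 20))
        z = instantaneous_cadence_z(StepSeries(times))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)


def _impulse_record(us, times, alpha=0.35, fs=4096.0, duration=12.0,
                    noise_sd=0.0, seed=0, gains=None):
    """Impulses with exact exponential energy decay at given positions."""
    rng = np.random.default_rng(seed)
    layout, groups, pair = default_sensor_layout()
    layout = np.delete(layout, 3, axis=0)          # already synchronized
    groups = tuple(g for i, g in enumerate(groups) if i != 3)
    n = int(fs * duration)
    data = rng.normal(0, noise_sd, (6, n)) if noise_sd > 0 else np.zeros((6, n))
    t = np.arange(n) / fs
    for u, tau in zip(us, times):
        for c in range(6):
            a = np.exp(-alpha * abs(u - layout[c, 0]) / 2.0)
            data[c] += a * np.exp(-0.5 * ((t - tau) / 0.01) ** 2) * np.sin(
                2 * np.pi * 80 * (t - tau))
    if gains is not None:
        data *= np.asarray(gains)[:, None]
    return VibrationRecord(fs, data, layout, groups, None)


class TestLocalizeSteps:
    def test_noiseless_exponential_decay_inverted(self):
        rec = _impulse_record([4.0], [2.0])
        steps = localize_steps(rec, StepSeries([2.0]))
        assert steps.step_positions[0] == pytest.approx(4.0, abs=0.1)

    def test_equidistant_impulse_lands_at_midpoint(self):
        # halfway between the sensor columns at u=2 and u=7
        rec = _impulse_record([4.5], [2.0])
        steps = localize_steps(rec, StepSeries([2.0]))
        assert steps.step_positions[0] == pytest.approx(4.5, abs=0.1)

    def test_global_gain_invariance(self):
        rec = _impulse_record([5.5, 8.0], [2.0, 2.6], noise_sd=1e-3, seed=1)
        rec_g = VibrationRecord(rec.sample_rate, rec.data * 7.3, rec.layout,
                                rec.daq_group, None)
        p0 = localize_steps(rec, StepSeries([2.0, 2.6])).step_positions
        p1 = localize_steps(rec_g, StepSeries([2.0, 2.6])).step_positions
        np.testing.assert_allclose(p1, p0, atol=1e-9)

    def test_per_channel_gain_invariance(self):
        rec = _impulse_record([5.5, 8.0], [2.0, 2.6], noise_sd=1e-3, seed=2)
        gains = np.array([0.5, 2.0, 1.3, 0.7, 4.0, 1.1])
        rec_g = VibrationRecord(rec.sample_rate, rec.data * gains[:, None],
                                rec.layout, rec.daq_group, None)
        p0 = localize_steps(rec, StepSeries([2.0, 2.6])).step_positions
        p1 = localize_steps(rec_g, StepSeries([2.0, 2.6])).step_positions
        np.testing.assert_allclose(p1, p0, atol=1e-9)

    def test_recovers_decay_rate(self, clean_floor_trial):
        _, rec, truth = clean_floor_trial
        sync, _ = synchronize(preprocess(rec))
        steps = detect_steps(snr_max(sync))
        steps = localize_steps(sync, steps)
        assert steps.decay_alpha == pytest.approx(0.35, abs=0.05)
        np.testing.assert_allclose(steps.step_positions,
                                   truth.step_positions, atol=0.15)


class TestKalmanSpeed:
    def test_noiseless_line_exact(self):
        t = np.arange(14) * 0.5
        steps = StepSeries(t, 3.5 + 1.2 * t)
        res = kalman_speed(steps)
        assert res.speed == pytest.approx(1.2, abs=1e-6)

    def test_gross_outlier_gated(self):
        t = np.arange(14) * 0.5
        pos = 3.5 + 1.2 * t
        pos[7] += 3.0
        res = kalman_speed(StepSeries(t, pos))
        assert res.n_gated >= 1
        assert res.speed == pytest.approx(1.2, rel=0.10)
        # oracle: OLS on the inliers
        keep = np.ones(14, bool)
        keep[7] = False
        oracle = np.polyfit(t[keep], pos[keep], 1)[0]
        assert res.speed == pytest.approx(oracle, rel=0.10)

    def test_noisy_positions_monte_carlo(self):
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.arange(14) * 0.5
            pos = 3.5 + 1.2 * t + rng.normal(0, 0.3, 14)
            if abs(kalman_speed(StepSeries(t, pos)).speed - 1.2) / 1.2 < 0.15:
                ok += 1
        assert ok >= 95

    def test_requires_positions(self):
        with pytest.raises(VibrationError):
            kalman_speed(StepSeries(np.arange(5) * 0.5))


def test_floor_metrics_end_to_end(nominal_trial):
    _, rec, truth = nominal_trial
    m = floor_metrics(rec)
    assert m.quality_flag == "ok"
    assert m.n_steps_detected == len(truth.step_times)
    assert m.cadence == pytest.approx(truth.cadence, abs=2.0)
    assert m.speed == pytest.approx(truth.speed, rel=0.15)
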