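"""Analysis pipeline: filters, spikes, band power, paradigm statistics."""

import numpy as np
import pytest

from durakit.ephys import (
    DEFAULT_BANDS,
    BandSet,
    Event,
    RecordingSession,
    SpikeSet,
    artifact_reject,
    band_power,
    detect_spikes,
    evoked_window_test,
    extract_lfp,
    impedance_normalized_response,
    load_session,
    mt_spectrogram_z,
    power_change_map,
    save_session,
    sort_spikes,
    spike_snr,
    stim_block_analysis,
)
from durakit.synth_ephys import (
    EvokedSpec,
    SessionConfig,
    generate_lfp_session,
    generate_spiking,
    regular_trials,
    spike_template,
)


def sine_session(freq, fs=4000.0, duration=4.0, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return RecordingSession(signals=amplitude * np.sin(2 * np.pi * freq * t),
                            sample_rate=fs, channel_ids=[0])


def noise_session(fs=500.0, duration=60.0, n_channels=4, seed=0,
                  events=()):
    rng = np.random.default_rng(seed)
    return RecordingSession(
        signals=rng.standard_normal((n_channels, int(duration * fs))),
        sample_rate=fs, channel_ids=list(range(n_channels)),
        events=list(events))


class TestExtractLfp:
    def test_above_band_tone_attenuated(self):
        out = extract_lfp(sine_session(300.0))
        atten = np.abs(out.signals[0][500:-500]).max()
        assert 20 * np.log10(1.0 / atten) >= 20.0

    def test_line_notch_attenuates_60hz(self):
        out = extract_lfp(sine_session(60.0))
        atten = np.abs(out.signals[0][500:-500]).max()
        assert 20 * np.log10(1.0 / atten) >= 20.0

    def test_passband_tone_preserved(self):
        out = extract_lfp(sine_session(10.0))
        assert np.abs(out.signals[0][500:-500]).max() == pytest.approx(1.0,
                                                                       rel=0.01)

    def test_output_rate_is_1khz(self):
        out = extract_lfp(sine_session(10.0, fs=30000.0, duration=1.0))
        assert out.sample_rate == 1000.0
        assert out.signals.shape[1] == 1000

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="2 kHz"):
            extract_lfp(sine_session(10.0, fs=1000.0))


class TestDetectSpikes:
    def test_pure_noise_yields_no_detections(self):
        cfg = SessionConfig(n_channels=1, sample_rate=30e3, duration_s=10.0,
                            seed=0)
        session, _ = generate_spiking(cfg, 0.0)
        spikes = detect_spikes(session)
        # -6 sigma threshold: Gaussian tail makes false positives negligible
        assert len(spikes.times) <= 1

    def test_planted_spikes_recovered_at_20db(self):
        cfg = SessionConfig(n_channels=1, sample_rate=30e3, duration_s=30.0,
                            seed=1)
        session, truth = generate_spiking(cfg, 5.0, target_snr_db=20.0)
        spikes = detect_spikes(session)
        matched = _match(truth.spike_times[0], spikes.times, tol=1e-3)
        recall = matched / max(len(truth.spike_times[0]), 1)
        precision = matched / max(len(spikes.times), 1)
        assert recall >= 0.95 and precision >= 0.95

    def test_no_refractory_doubles(self):
        cfg = SessionConfig(n_channels=1, sample_rate=30e3, duration_s=20.0,
                            seed=2)
        session, truth = generate_spiking(cfg, 5.0, target_snr_db=26.0)
        spikes = detect_spikes(session)
        assert len(spikes.times) <= len(truth.spike_times[0]) + 1
        assert np.all(np.diff(spikes.times) >= 1e-3)

    def test_flat_signal_rejected(self):
        session = RecordingSession(signals=np.zeros((1, 30000)),
                                   sample_rate=30e3, channel_ids=[0])
        with pytest.raises(ValueError, match="degenerate"):
            detect_spikes(session)


def _match(truth_times, found_times, tol):
    used = np.zeros(len(found_times), bool)
    n = 0
    for t in truth_times:
        d = np.abs(found_times - t)
        d[used] = np.inf
        if len(d) and d.min() <= tol:
            used[np.argmin(d)] = True
            n += 1
    return n


class TestSortSpikes:
    def two_template_session(self, seed=3):
        fs = 30e3
        rng = np.random.default_rng(seed)
        n = int(30.0 * fs)
        x = rng.normal(0, 10e-6, n)
        t1 = spike_template(fs) * 120e-6
        t2 = np.roll(spike_template(fs, trough_fraction=0.45), 6) * 200e-6
        labels, times = [], []
        pos = int(0.1 * fs)
        while pos < n - len(t1) - int(0.1 * fs):
            which = rng.integers(2)
            tpl = (t1, t2)[which]
            x[pos:pos + len(tpl)] += tpl
            times.append(pos / fs)
            labels.append(which)
            pos += int(rng.uniform(0.05, 0.2) * fs)
        session = RecordingSession(signals=x, sample_rate=fs, channel_ids=[0])
        return session, np.array(times), np.array(labels)

    def test_two_planted_templates_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        session, times, labels = self.two_template_session()
        spikes = sort_spikes(detect_spikes(session), k=2, seed=0)
        truth = []
        for t in spikes.times:
            truth.append(labels[np.argmin(np.abs(times - t))])
        assert adjusted_rand_score(truth, spikes.labels) >= 0.9

    def test_k1_is_a_single_cluster(self):
        session, _, _ = self.two_template_session(4)
        spikes = sort_spikes(detect_spikes(session), k=1)
        assert np.all(spikes.labels == 0)

    def test_same_seed_is_deterministic(self):
        session, _, _ = self.two_template_session(5)
        detected = detect_spikes(session)
        a = sort_spikes(detected, k=2, seed=7)
        b = sort_spikes(detected, k=2, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_k_exceeding_spike_count_rejected(self):
        spikes = SpikeSet(times=np.array([0.1]), waveforms=np.ones((1, 10)),
                          background_sd=1e-6, sample_rate=30e3)
        with pytest.raises(ValueError):
            sort_spikes(spikes, k=3)


class TestSpikeSnr:
    def test_arithmetic(self):
        wf = np.zeros((3, 20))
        wf[:, 5] = -70e-6
        wf[:, 12] = 30e-6
        spikes = SpikeSet(times=np.zeros(3), waveforms=wf,
                          background_sd=10e-6, sample_rate=30e3)
        out = spike_snr(spikes)
        assert out["ratio"] == pytest.approx(10.0)
        assert out["db"] == pytest.approx(20.0)

    @pytest.mark.parametrize("target_db", [20.0, 32.0])
    def test_generator_roundtrip_within_1db(self, target_db):
        cfg = SessionConfig(n_channels=1, sample_rate=30e3, duration_s=30.0,
                            seed=6)
        session, _ = generate_spiking(cfg, 5.0, target_snr_db=target_db)
        spikes = detect_spikes(session)
        assert spike_snr(spikes)["db"] == pytest.approx(target_db, abs=1.0)

    def test_scale_invariance(self):
        wf = np.random.default_rng(0).normal(size=(5, 20))
        a = SpikeSet(np.zeros(5), wf, 1e-6, 30e3)
        b = SpikeSet(np.zeros(5), 2 * wf, 2e-6, 30e3)
        assert spike_snr(a)["db"] == pytest.approx(spike_snr(b)["db"])

    def test_empty_set_rejected(self):
        spikes = SpikeSet(np.array([]), np.empty((0, 10)), 1e-6, 30e3)
        with pytest.raises(ValueError):
            spike_snr(spikes)


class TestBandPower:
    def test_zero_signal_has_zero_power(self):
        assert band_power(np.zeros(5000), (4.0, 8.0), 500.0) == 0.0

    def test_in_band_sine_is_half_sample_rate(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        p = band_power(np.sin(2 * np.pi * 10.0 * t), (5.0, 20.0), fs)
        assert p == pytest.approx(fs / 2, rel=0.02)

    def test_out_of_band_sine_suppressed(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        p_in = band_power(np.sin(2 * np.pi * 10.0 * t), (5.0, 20.0), fs)
        p_out = band_power(np.sin(2 * np.pi * 80.0 * t), (5.0, 20.0), fs)
        assert p_out <= 0.01 * p_in

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="3 cycles"):
            band_power(np.zeros(100), (4.0, 8.0), 500.0)


class TestPowerChangeMap:
    def planted_session(self, seed=0, n_trials=60):
        schedule = regular_trials(n_trials, 2.2, 1.0)
        positions = {i: (float(i % 4), float(i // 4)) for i in range(8)}
        cfg = SessionConfig(n_channels=8, sample_rate=500.0,
                            duration_s=1.0 + n_trials * 2.2 + 1.0, seed=seed,
                            trial_schedule=schedule,
                            channel_positions=positions)
        spec = EvokedSpec(target_channels=(0, 1, 2), band=(4.0, 8.0),
                          power_multiplier=2.0)
        session, truth = generate_lfp_session(cfg, [spec])
        return session

    def test_identical_windows_give_zero_change(self):
        session = self.planted_session()
        out = power_change_map(session, session.event_times("stim_onset"),
                               (0.0, 1.0), (0.0, 1.0), (4.0, 8.0))
        assert np.allclose(out["change"], 0.0)
        assert not out["significant"].any()

    def test_planted_channels_flagged(self):
        session = self.planted_session(seed=1, n_trials=100)
        out = power_change_map(session, session.event_times("stim_onset"),
                               (0.0, 1.0), (-1.0, 0.0), (4.0, 8.0))
        assert set(np.nonzero(out["significant"])[0]) == {0, 1, 2}

    def test_interpolated_map_present_with_positions(self):
        session = self.planted_session()
        out = power_change_map(session, session.event_times("stim_onset"),
                               (0.0, 1.0), (-1.0, 0.0), (4.0, 8.0))
        assert out["map"] is not None
        assert out["map"]["values"].shape == (64, 64)

    def test_single_trial_rejected(self):
        session = self.planted_session()
        with pytest.raises(ValueError, match="2 trials"):
            power_change_map(session, [1.0], (0.0, 1.0), (-1.0, 0.0),
                             (4.0, 8.0))


class TestMtSpectrogramZ:
    fs = 500.0

    def trials_from(self, x, n_trials, seg_len):
        n = int(seg_len * self.fs)
        return np.stack([x[i * n:(i + 1) * n] for i in range(n_trials)])

    def test_stationary_noise_has_zero_mean_z(self):
        rng = np.random.default_rng(0)
        trials = rng.standard_normal((30, int(1.5 * self.fs)))
        out = mt_spectrogram_z(trials, self.fs, 0.15, 0.01, (0.0, 0.5))
        assert abs(out["z"].mean()) < 0.2

    def test_planted_gamma_gain_appears_after_event(self):
        rng = np.random.default_rng(1)
        n = int(1.5 * self.fs)
        trials = rng.standard_normal((40, n))
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, (30, 70), btype="bandpass", fs=self.fs, output="sos")
        burst = sosfiltfilt(sos, rng.standard_normal((40, n)), axis=1)
        trials[:, int(0.75 * self.fs):] += 2.0 * burst[:, int(0.75 * self.fs):]
        out = mt_spectrogram_z(trials, self.fs, 0.15, 0.01, (0.0, 0.5))
        gamma_rows = (out["frequency"] >= 30) & (out["frequency"] <= 70)
        pre = out["z"][gamma_rows][:, out["time"] < 0.6].mean()
        post = out["z"][gamma_rows][:, out["time"] > 0.9].mean()
        assert post > pre + 1.0

    def test_baseline_covering_whole_segment_self_normalizes(self):
        rng = np.random.default_rng(2)
        trials = rng.standard_normal((20, int(1.0 * self.fs)))
        out = mt_spectrogram_z(trials, self.fs, 0.1, 0.02, (0.0, 1.0))
        assert abs(out["z"].mean()) < 1e-6

    def test_window_longer_than_segment_rejected(self):
        with pytest.raises(ValueError, match="window"):
            mt_spectrogram_z(np.zeros((2, 100)), self.fs, 1.0, 0.01,
                             (0.0, 0.1))


class TestArtifactReject:
    def test_clean_noise_barely_masked(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        mask = artifact_reject(x, 10.0)
        assert mask.mean() < 1e-4
        assert len(mask) == len(x)

    def test_planted_artifact_masked(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        x[5000] = 50.0
        assert artifact_reject(x, 10.0)[5000]

    def test_guard_dilates_mask(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        x[5000] = 50.0
        mask = artifact_reject(x, 10.0, guard_samples=5)
        assert mask[4996] and mask[5004]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            artifact_reject(np.ones(100))


def _blocks(n_blocks, period_s):
    blocks = []
    for b in range(n_blocks):
        t0 = b * 4 * period_s
        blocks.append({
            "baseline1": (t0, t0 + period_s),
            "baseline2": (t0 + period_s, t0 + 2 * period_s),
            "stim": (t0 + 2 * period_s, t0 + 3 * period_s),
            "post": (t0 + 3 * period_s, t0 + 4 * period_s),
        })
    return blocks


class TestStimBlockAnalysis:
    fs = 500.0

    def stationary(self, n_blocks=12, period_s=10.0, seed=0):
        dur = n_blocks * 4 * period_s
        return noise_session(self.fs, dur, 4, seed), _blocks(n_blocks, period_s)

    def test_stationary_blocks_show_no_change(self):
        session, blocks = self.stationary()
        out = stim_block_analysis(session, blocks, DEFAULT_BANDS["high_gamma"])
        assert abs(out["network_induced"].mean()) < 5.0
        assert out["p_induced_vs_spontaneous"] > 0.01

    def test_planted_post_gamma_gain_detected(self):
        session, blocks = self.stationary(seed=1)
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, (60, 150), btype="bandpass", fs=self.fs, output="sos")
        rng = np.random.default_rng(2)
        gain = sosfiltfilt(sos, rng.standard_normal(session.signals.shape),
                           axis=1)
        for blk in blocks:
            i0 = int(blk["post"][0] * self.fs)
            i1 = int(blk["post"][1] * self.fs)
            session.signals[:, i0:i1] += 1.0 * gain[:, i0:i1]
        out = stim_block_analysis(session, blocks, DEFAULT_BANDS["high_gamma"])
        assert out["network_induced"].mean() > out["network_spontaneous"].mean()
        assert out["p_induced_vs_spontaneous"] < 0.05
        # sign convention: a gain is a positive delta
        assert np.all(out["network_induced"] > 0)

    def test_missing_period_rejected(self):
        session, blocks = self.stationary(n_blocks=2)
        del blocks[0]["post"]
        with pytest.raises(ValueError, match="post"):
            stim_block_analysis(session, blocks, DEFAULT_BANDS["low_gamma"])


class TestEvokedWindowTest:
    def test_planted_tactile_response_flagged(self):
        n_trials = 30
        schedule = regular_trials(n_trials, 3.0, 1.0)
        cfg = SessionConfig(n_channels=8, sample_rate=500.0,
                            duration_s=1.0 + n_trials * 3.0 + 1.0, seed=3,
                            trial_schedule=schedule)
        spec = EvokedSpec(target_channels=(2, 5), band=(4.0, 15.0),
                          power_multiplier=6.0, duration_s=1.0)
        session, _ = generate_lfp_session(cfg, [spec])
        out = evoked_window_test(session, session.event_times("stim_onset"),
                                 band=(4.0, 15.0))
        flagged = set(np.nonzero(out["significant"])[0])
        assert {2, 5} <= flagged
        assert len(flagged - {2, 5}) == 0

    def test_null_session_rarely_flags(self):
        events = [Event("stim_onset", t) for t in np.arange(1.0, 59.0, 2.0)]
        session = noise_session(500.0, 60.0, 8, seed=4, events=events)
        out = evoked_window_test(session, session.event_times("stim_onset"),
                                 band=(4.0, 15.0))
        assert out["significant"].sum() <= 1

    def test_overlapping_windows_rejected(self):
        session = noise_session(500.0, 10.0, 2, seed=5)
        with pytest.raises(ValueError, match="overlap"):
            evoked_window_test(session, [1.0, 1.1], band=(4.0, 15.0))


class TestImpedanceNormalization:
    def test_equal_impedances_preserve_ordering(self):
        zmap = {0: 1.0, 1: 3.0, 2: 2.0}
        out = impedance_normalized_response(zmap, {0: 5e4, 1: 5e4, 2: 5e4})
        assert sorted(out, key=out.get) == sorted(zmap, key=zmap.get)

    def test_doubling_impedance_halves_response(self):
        out1 = impedance_normalized_response({0: 1.0}, {0: 1e4})
        out2 = impedance_normalized_response({0: 1.0}, {0: 2e4})
        assert out2[0] == pytest.approx(out1[0] / 2)

    def test_missing_impedance_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            out = impedance_normalized_response({0: 1.0, 1: 2.0}, {0: 1e4})
        assert 1 not in out

    def test_planted_response_peaks_at_nearest_channel(self):
        # spatially specific effect: only the channel nearest the planted
        # stimulation zone carries an elevated band response
        n_trials = 40
        schedule = regular_trials(n_trials, 3.0, 1.0)
        cfg = SessionConfig(n_channels=6, sample_rate=500.0,
                            duration_s=1.0 + n_trials * 3.0 + 1.0, seed=6,
                            trial_schedule=schedule)
        spec = EvokedSpec(target_channels=(3,), band=(4.0, 40.0),
                          power_multiplier=4.0, duration_s=0.9)
        session, _ = generate_lfp_session(cfg, [spec])
        onsets = session.event_times("stim_onset")
        zmap = {}
        fs = session.sample_rate
        for ch in range(6):
            seg_len = int(1.5 * fs)
            trials = np.stack([
                session.signals[ch][int((t - 0.35) * fs):
                                    int((t - 0.35) * fs) + seg_len]
                for t in onsets])
            out = mt_spectrogram_z(trials, fs, 0.15, 0.01, (0.0, 0.35))
            rows = (out["frequency"] >= 4) & (out["frequency"] <= 40)
            cols = (out["time"] >= 0.35) & (out["time"] <= 1.25)
            zmap[ch] = out["z"][rows][:, cols].mean()
        norm = impedance_normalized_response(zmap, {ch: 3e4 for ch in range(6)})
        assert max(norm, key=norm.get) == 3


class TestSessionContainer:
    def test_roundtrip_preserves_samples_and_events(self, tmp_path):
        session = noise_session(500.0, 2.0, 3, seed=7,
                                events=[Event("go_tone", 1.0)])
        session.impedances = {0: 3e4, 1: 3.1e4, 2: 2.9e4}
        path = tmp_path / "session.h5"
        save_session(session, path)
        back = load_session(path)
        scale = np.abs(session.signals).max() / 32000.0
        assert np.allclose(back.signals, session.signals, atol=scale)
        assert back.events == [Event("go_tone", 1.0)]
        assert back.sample_rate == 500.0

    def test_double_roundtrip_is_exact(self, tmp_path):
        session = noise_session(500.0, 1.0, 2, seed=8)
        save_session(session, tmp_path / "a.h5")
        a = load_session(tmp_path / "a.h5")
        save_session(a, tmp_path / "b.h5")
        b = load_session(tmp_path / "b.h5")
        assert np.array_equal(a.signals, b.signals)


def test_bandset_defaults_are_valid_at_1khz():
    bs = BandSet()
    bs.validate(1000.0)
    assert bs["theta"] == (4.0, 8.0)
    assert bs["low_gamma"] == (30.0, 59.0)
    with pytest.raises(ValueError):
        BandSet({"bad": (10.0, 5.0)}).validate(1000.0)
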