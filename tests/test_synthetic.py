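"""Synthetic generator: determinism, validation, injected structure."""

import numpy as np
import pytest

from ieegpac import (SLOW_OSC_1HZ, SyntheticConfig, generate_acoustic_triggers,
                     generate_sleep_recording, inject_outlier_epochs,
                     inject_tacs_artifact, morlet_bandpass)


class TestConfigValidation:
    def test_bad_band_edges_name_the_field(self):
        with pytest.raises(ValueError, match="so_band"):
            SyntheticConfig(so_band=(4.0, 0.5))

    def test_bad_coupling_depth_rejected(self):
        with pytest.raises(ValueError, match="coupling_depth"):
            SyntheticConfig(coupling_depth=1.5)

    def test_bad_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            SyntheticConfig(duration=0.0)

    def test_fs_below_twice_band_edge_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            SyntheticConfig(fs=128.0)   # gamma band reaches 110 Hz


class TestGeneration:
    def test_same_seed_bit_identical(self):
        cfg = SyntheticConfig(n_channels=2, duration=30.0, seed=9)
        rec1, _ = generate_sleep_recording(cfg)
        rec2, _ = generate_sleep_recording(cfg)
        np.testing.assert_array_equal(rec1.data, rec2.data)

    def test_different_seeds_differ(self):
        rec1, _ = generate_sleep_recording(
            SyntheticConfig(n_channels=1, duration=30.0, seed=1))
        rec2, _ = generate_sleep_recording(
            SyntheticConfig(n_channels=1, duration=30.0, seed=2))
        assert not np.array_equal(rec1.data, rec2.data)

    def test_events_inside_recording_and_bursts_non_overlapping(self, sleep_recording):
        rec, truth = sleep_recording
        for ch_events in truth.so_events:
            for ev in ch_events:
                assert 0.0 <= ev.onset
                assert ev.onset + ev.duration <= truth.duration + 1e-9
                assert 1 <= ev.n_cycles <= 2
        for intervals in truth.burst_intervals["spindle"]:
            arr = np.asarray(intervals)
            if len(arr) > 1:
                assert (arr[1:, 0] >= arr[:-1, 1] - 1e-9).all()

    def test_slow_wave_spectrum_is_broadband(self, sleep_recording):
        # unitary 1-2 cycle events drawn across 0.5-4 Hz: no narrow peak
        # (no bin more than 3x the mean of its neighboring octave)
        from scipy.signal import welch

        rec, _ = sleep_recording
        freqs, psd = welch(rec.data[0], fs=rec.fs, nperseg=int(64 * rec.fs))
        sel = (freqs >= 0.5) & (freqs <= 4.0)
        for i in np.flatnonzero(sel):
            f = freqs[i]
            octave = (freqs >= f / np.sqrt(2)) & (freqs <= f * np.sqrt(2)) \
                & (freqs != f) & (freqs >= 0.25) & (freqs <= 8.0)
            assert psd[i] < 3.0 * psd[octave].mean()

    def test_ground_truth_serializes_to_json(self, sleep_recording, tmp_path):
        import json

        _, truth = sleep_recording
        path = tmp_path / "truth.json"
        truth.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["coupling_depth"] == [0.8, 0.0]
        assert len(payload["so_events"]) == 2

    def test_trigger_locked_events_land_on_onsets(self):
        onsets = tuple(np.arange(5.0, 55.0, 3.0))
        cfg = SyntheticConfig(n_channels=1, duration=60.0,
                              so_event_onsets=onsets, seed=3)
        _, truth = generate_sleep_recording(cfg)
        got = [ev.onset for ev in truth.so_events[0]]
        assert set(got) <= set(onsets)
        assert len(got) >= len(onsets) - 3   # overlaps/end-of-record skipped


class TestTacsInjection:
    def test_rms_ratio_matches_construction(self, sleep_recording):
        rec, _ = sleep_recording
        neural_rms = rec.data.std()
        out = inject_tacs_artifact(rec, 1.0, 10.0 * np.sqrt(2) * neural_rms)
        artifact = out.data - rec.data
        assert np.sqrt((artifact ** 2).mean()) / neural_rms >= 10.0 - 1e-6

    def test_exact_period_count_in_five_minutes(self):
        # 1 Hz for 300 s: exactly 300 artifact periods
        cfg = SyntheticConfig(n_channels=1, duration=300.0, seed=4)
        rec, _ = generate_sleep_recording(cfg)
        out = inject_tacs_artifact(rec, 1.0, 1000.0)
        artifact = out.data[0] - rec.data[0]
        # positive-going zero crossings of the pure cosine artifact
        pos = artifact > 0
        crossings = np.count_nonzero(~pos[:-1] & pos[1:])
        assert crossings == 300

    def test_nyquist_violating_harmonic_rejected(self, sleep_recording):
        rec, _ = sleep_recording
        with pytest.raises(ValueError, match="Nyquist"):
            inject_tacs_artifact(rec, 1.0, 100.0,
                                 harmonic_coeffs={300: (1.0, 0.0)})

    def test_non_positive_amplitude_rejected(self, sleep_recording):
        rec, _ = sleep_recording
        with pytest.raises(ValueError, match="amplitude"):
            inject_tacs_artifact(rec, 1.0, 0.0)


class TestAcousticTriggers:
    @pytest.mark.parametrize("rate,duration,expected",
                             [(1.0, 300.0, 300), (0.75, 300.0, 225),
                              (1.0, 0.0, 0)])
    def test_trigger_counts(self, rate, duration, expected):
        times = generate_acoustic_triggers(rate, duration)
        assert len(times) == expected
        if expected > 1:
            np.testing.assert_allclose(np.diff(times), 1.0 / rate)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            generate_acoustic_triggers(0.0, 10.0)

    def test_jitter_perturbs_but_keeps_count(self):
        times = generate_acoustic_triggers(1.0, 100.0, jitter=0.05, rng=0)
        assert len(times) == 100
        assert np.std(np.diff(times)) > 0


class TestOutlierEpochs:
    def test_unit_gain_is_identity(self, sleep_recording):
        rec, _ = sleep_recording
        out = inject_outlier_epochs(rec, [(10.0, 12.0)], gain=1.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_power_scaled_by_gain(self, sleep_recording):
        rec, _ = sleep_recording
        out = inject_outlier_epochs(rec, [(10.0, 12.0)], gain=10.0)
        s, e = int(10 * rec.fs), int(12 * rec.fs)
        ratio = (out.data[0, s:e] ** 2).mean() / (rec.data[0, s:e] ** 2).mean()
        assert ratio == pytest.approx(10.0)

    def test_overlapping_intervals_merged_with_warning(self, sleep_recording):
        rec, _ = sleep_recording
        with pytest.warns(UserWarning, match="merged"):
            out = inject_outlier_epochs(rec, [(10.0, 12.0), (11.0, 13.0)],
                                        gain=4.0)
        s, e = int(10 * rec.fs), int(13 * rec.fs)
        np.testing.assert_allclose(out.data[:, s:e], 2.0 * rec.data[:, s:e])

    def test_interval_outside_recording_rejected(self, sleep_recording):
        rec, _ = sleep_recording
        with pytest.raises(ValueError, match="outside"):
            inject_outlier_epochs(rec, [(290.0, 310.0)], gain=2.0)

    def test_boosted_cycle_flagged_downstream(self):
        # round trip with the cycle-wise outlier screen
        from ieegpac import (FAST_SPINDLE, reject_outlier_cycles,
                             segment_cycles, wrap_degrees)

        cfg = SyntheticConfig(n_channels=1, duration=120.0, seed=6)
        rec, _ = generate_sleep_recording(cfg)
        boosted = inject_outlier_epochs(rec, [(60.0, 61.0)], gain=10.0)
        t = np.arange(rec.n_samples) / rec.fs
        phase = wrap_degrees(360.0 * 1.0 * t)
        table = segment_cycles(rec.fs, phase=phase)
        amp = morlet_bandpass(boosted.data[0], rec.fs, FAST_SPINDLE).amplitude
        out = reject_outlier_cycles(table, amp)
        rejected = np.flatnonzero(~out.df["retained"].to_numpy())
        assert 60 in rejected
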