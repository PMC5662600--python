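"""Harmonic artifact model: fit, subtraction, phase reference."""

import numpy as np
import pytest
from scipy.signal import periodogram

from ieegpac import (HarmonicFitModel, SLOW_OSC_1HZ, SyntheticConfig,
                     TrapezoidalWaveformError, fit_harmonic_artifact,
                     generate_sleep_recording, inject_tacs_artifact,
                     morlet_bandpass, stimulation_phase, subtract_artifact,
                     wrap_degrees)

FS = 512.0


def _times(duration=60.0):
    return np.arange(int(duration * FS)) / FS


class TestFit:
    def test_pure_sine_recovered_exactly(self):
        # the model class contains the input: near-machine-precision fit
        t = _times()
        model = fit_harmonic_artifact(2.0 * np.sin(2 * np.pi * t), FS, 1.0)
        assert abs(model.b[0] - 2.0) < 1e-6
        others = np.r_[model.a, model.b[1:], model.dc]
        assert np.max(np.abs(others)) < 1e-6
        resid = subtract_artifact(2.0 * np.sin(2 * np.pi * t), model)
        assert np.sqrt((resid ** 2).mean()) < 1e-6 * np.sqrt(2.0)

    def test_base_frequency_refined_off_grid(self):
        # oracle: dense grid search over f0 on the residual variance
        t = _times(120.0)
        x = np.sin(2 * np.pi * 1.001 * t)
        model = fit_harmonic_artifact(x, FS, 1.0)
        grid = np.linspace(0.99, 1.01, 2001)
        design = lambda f0: np.column_stack(
            [np.cos(2 * np.pi * f0 * t), np.sin(2 * np.pi * f0 * t)])
        rss = [np.linalg.lstsq(design(f0), x, rcond=None)[1][0]
               for f0 in grid]
        f0_grid = grid[int(np.argmin(rss))]
        assert abs(model.f0 - 1.001) < 1e-4
        assert abs(model.f0 - f0_grid) < 1e-4

    def test_harmonic_count_capped_at_40_hz(self):
        t = _times()
        m1 = fit_harmonic_artifact(np.sin(2 * np.pi * t), FS, 1.0)
        m075 = fit_harmonic_artifact(np.sin(2 * np.pi * 0.75 * t), FS, 0.75)
        assert m1.n_harmonics == 40
        assert m075.n_harmonics == 53  # floor(40 / 0.75)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="10 periods"):
            fit_harmonic_artifact(np.zeros(int(5 * FS)), FS, 1.0)

    def test_trapezoidal_waveform_refused(self):
        with pytest.raises(TrapezoidalWaveformError):
            fit_harmonic_artifact(np.zeros(int(60 * FS)), FS, 0.75,
                                  stim_waveform="trapezoid")

    def test_json_round_trip(self, tmp_path):
        t = _times()
        model = fit_harmonic_artifact(
            np.sin(2 * np.pi * t) + 0.2 * np.cos(4 * np.pi * t), FS, 1.0)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = HarmonicFitModel.from_json(path)
        assert back.f0 == model.f0
        np.testing.assert_array_equal(back.a, model.a)
        np.testing.assert_array_equal(back.b, model.b)


class TestSubtraction:
    def _coupled_recording(self, seed=7):
        cfg = SyntheticConfig(n_channels=1, duration=300.0,
                              coupling_depth=0.5, seed=seed)
        rec, _ = generate_sleep_recording(cfg)
        return rec

    def test_residual_recovers_neural_signal(self):
        # artifact 10x the neural RMS; the residual should be the neural
        # trace nearly unchanged
        rec = self._coupled_recording()
        neural = rec.data[0].copy()
        amp = 10.0 * np.sqrt(2.0) * neural.std()
        noisy = inject_tacs_artifact(
            rec, 1.0, amp,
            harmonic_coeffs={2: (0.08 * amp, 0.02 * amp),
                             3: (0.02 * amp, -0.01 * amp)})
        model = fit_harmonic_artifact(noisy.data[0], FS, 1.0)
        resid = subtract_artifact(noisy.data[0], model)
        assert np.corrcoef(resid, neural)[0, 1] > 0.99

    def test_stationary_artifact_suppressed_40_db(self):
        rec = self._coupled_recording(seed=8)
        amp = 10.0 * np.sqrt(2.0) * rec.data[0].std()
        noisy = inject_tacs_artifact(rec, 1.0, amp,
                                     harmonic_coeffs={2: (0.1 * amp, 0.0)})
        model = fit_harmonic_artifact(noisy.data[0], FS, 1.0)
        resid = subtract_artifact(noisy.data[0], model)
        freqs, p_before = periodogram(noisy.data[0], FS)
        _, p_after = periodogram(resid, FS)
        for f_target in (1.0, 2.0):
            i = np.argmin(np.abs(freqs - f_target))
            assert 10 * np.log10(p_before[i] / p_after[i]) >= 40.0

    def test_exact_reconstruction_leaves_zero_residual(self):
        t = _times()
        model = fit_harmonic_artifact(np.sin(2 * np.pi * t), FS, 1.0)
        wave = model.reconstruct(t.size)
        np.testing.assert_allclose(subtract_artifact(wave, model), 0.0,
                                   atol=1e-12)

    def test_drifting_artifact_degrades_fit_and_flags_poor_removal(self):
        rec = self._coupled_recording(seed=9)
        amp = 10.0 * np.sqrt(2.0) * rec.data[0].std()
        stationary = inject_tacs_artifact(rec, 1.0, amp)
        drifting = inject_tacs_artifact(rec, 1.0, amp, drift=3.0)
        m_stat = fit_harmonic_artifact(stationary.data[0], FS, 1.0)
        m_drift = fit_harmonic_artifact(drifting.data[0], FS, 1.0)
        assert m_drift.residual_ratio > m_stat.residual_ratio
        assert m_drift.poor_removal and not m_stat.poor_removal

    def test_subtraction_is_linear(self):
        t = _times()
        artifact = 100.0 * np.sin(2 * np.pi * t)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(t.size)
        model = fit_harmonic_artifact(artifact, FS, 1.0)
        lhs = subtract_artifact(artifact + y, model)
        rhs = y + (artifact - model.reconstruct(t.size))
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestStimulationPhase:
    def _model(self):
        t = _times()
        return fit_harmonic_artifact(
            3.0 * np.cos(2 * np.pi * (t - 0.2)), FS, 1.0)

    def test_zero_at_positive_peak_and_180_at_trough(self):
        model = self._model()
        assert abs(stimulation_phase(model, 0.2)) < 0.5
        assert abs(abs(stimulation_phase(model, 0.7)) - 180.0) < 0.5

    def test_periodicity(self):
        model = self._model()
        t = np.array([0.33, 1.1, 2.8])
        np.testing.assert_allclose(stimulation_phase(model, t),
                                   stimulation_phase(model, t + 1.0 / model.f0),
                                   atol=1e-6)

    def test_zero_fundamental_has_no_phase_reference(self):
        t = _times()
        model = fit_harmonic_artifact(np.cos(4 * np.pi * t), FS, 1.0)
        model.a[0] = model.b[0] = 0.0
        with pytest.raises(ValueError, match="phase reference"):
            stimulation_phase(model, 0.0)

    def test_agrees_with_morlet_phase_of_pure_fundamental(self):
        # cross-module consistency: same 0-degrees-at-peak convention
        t = _times(120.0)
        x = 50.0 * np.cos(2 * np.pi * (t - 0.4))
        model = fit_harmonic_artifact(x, FS, 1.0)
        analytic = morlet_bandpass(x, FS, SLOW_OSC_1HZ)
        interior = slice(int(20 * FS), int(100 * FS))
        diff = wrap_degrees(stimulation_phase(model, t[interior])
                            - analytic.phase_deg[interior])
        assert np.max(np.abs(diff)) < 2.0
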