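"""Synthetic intracranial sleep recordings with known coupling structure.

The generator emulates the features of NREM iEEG that the analysis pipeline
depends on, with every draw recorded as ground truth:

* **Slow oscillations** are *unitary events*: Hann-windowed sinusoid
  snippets of 1-2 cycles whose frequency is drawn fresh per event from the
  0.5-4 Hz band, separated by random gaps.  A regular rhythm therefore never
  persists beyond two cycles and the slow-wave spectrum is broadband with no
  narrow peak -- matching real human sleep, where slow waves are isolated
  events rather than a sustained oscillator.
* **Spindle and gamma activity** are narrowband Gaussian noise whose
  envelope is gated to slow-oscillation events and multiplicatively
  modulated as ``1 + depth * cos(phi_SO - preferred_phase)``.  For a
  noise-free channel the normalised modulation index then equals ``depth/2``
  exactly -- a closed-form recovery oracle.
* **1/f background noise**, a **sinusoidal tACS artifact** with harmonic
  distortion and optional amplitude drift, **acoustic trigger trains**, and
  **movement/outlier epochs** complete the model.

Reproducibility: one seed per generation call; per-channel sub-streams are
spawned deterministically, so identical configs give bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .recording import TimeSeriesRecording
from .spectral import (BandDefinition, FAST_SPINDLE, GAMMA, morlet_bandpass,
                       wrap_degrees)

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "SOEvent",
    "generate_sleep_recording",
    "inject_tacs_artifact",
    "generate_acoustic_triggers",
    "inject_outlier_epochs",
]


@dataclass(frozen=True)
class SOEvent:
    """One unitary slow-oscillation event."""

    onset: float          # s
    duration: float       # s
    frequency: float      # Hz
    n_cycles: int
    amplitude: float      # uV, peak


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic recording.

    Defaults reflect deep NREM sleep as recorded subdurally at 512 Hz:
    5-minute blocks, ~15 unitary slow-oscillation events per minute of 1-2
    cycles each drawn from the broadband 0.5-4 Hz range, 200 uV peak slow
    oscillations over a ~15 uV-RMS 1/f background (so the 50 uV endogenous
    amplitude floor can be exercised both ways), and spindle/gamma bursts
    nested in the events over a continuous narrowband background at half
    the burst envelope -- sigma and gamma activity never vanish in real
    sleep EEG, which is also why median-based spindle power thresholds are
    meaningful.
    """

    n_channels: int = 4
    fs: float = 512.0
    duration: float = 300.0              # s
    so_event_rate: float = 15.0          # events / min
    so_band: tuple[float, float] = (0.5, 4.0)
    max_consecutive_so_cycles: int = 2
    coupling_depth: float | tuple = 0.0  # scalar or per channel, in [0, 1]
    preferred_phase_deg: float | tuple = 0.0
    spindle_band: BandDefinition = FAST_SPINDLE
    gamma_band: BandDefinition = GAMMA
    spindle_scale: float = 25.0          # uV, burst envelope scale
    gamma_scale: float = 8.0             # uV
    baseline_burst_level: float = 0.5    # envelope fraction between events
    noise_exponent: float = 1.0          # 1/f^exponent power slope
    noise_scale: float = 15.0            # uV RMS of the background
    signal_scale: float = 200.0          # uV, peak slow-oscillation amplitude
    so_event_onsets: tuple | None = None # fixed onsets (s), e.g. trigger-locked
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.so_band
        if not 0 < lo < hi:
            raise ValueError(f"invalid so_band={self.so_band}: need 0 < low < high")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        top = max(hi, self.spindle_band.edges[1], self.gamma_band.edges[1])
        if self.fs <= 2.0 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge ({top} Hz)"
            )
        for d in np.atleast_1d(self.coupling_depth):
            if not 0.0 <= d <= 1.0:
                raise ValueError(
                    f"coupling_depth must lie in [0, 1], got {d}"
                )
        if self.max_consecutive_so_cycles < 1:
            raise ValueError("max_consecutive_so_cycles must be >= 1")

    def per_channel(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float),
                              (self.n_channels,))
        return np.array(arr)


@dataclass
class SyntheticGroundTruth:
    """Everything that was injected: the recovery oracle."""

    coupling_depth: np.ndarray           # per channel
    preferred_phase_deg: np.ndarray      # per channel
    so_events: list[list[SOEvent]]       # per channel
    burst_intervals: dict                # band -> per channel [(t0, t1)]
    artifact: dict | None = None         # frequency, amplitude, harmonics...
    trigger_times: np.ndarray | None = None
    outlier_intervals: list = field(default_factory=list)
    duration: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for events in self.so_events:
            for ev in events:
                if not (0.0 <= ev.onset and ev.onset + ev.duration
                        <= self.duration + 1e-9):
                    raise ValueError(
                        f"event at {ev.onset}s extends outside the recording"
                    )

    def to_json(self, path=None) -> str:
        payload = {
            "coupling_depth": list(map(float, self.coupling_depth)),
            "preferred_phase_deg": list(map(float, self.preferred_phase_deg)),
            "so_events": [[asdict(ev) for ev in ch] for ch in self.so_events],
            "burst_intervals": {
                band: [[(float(a), float(b)) for a, b in ch] for ch in chans]
                for band, chans in self.burst_intervals.items()
            },
            "artifact": self.artifact,
            "trigger_times": (None if self.trigger_times is None
                              else list(map(float, self.trigger_times))),
            "outlier_intervals": [(float(a), float(b))
                                  for a, b in self.outlier_intervals],
            "duration": self.duration,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


def _one_over_f_noise(rng, n, fs, exponent, rms):
    """Gaussian noise with a 1/f^exponent power spectrum, scaled to ``rms``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n=n)
    scale = rms / max(np.std(shaped), 1e-300)
    return shaped * scale


def _narrowband_noise(rng, n, fs, band):
    """Unit-mean-envelope narrowband Gaussian noise and its envelope."""
    analytic = morlet_bandpass(rng.standard_normal(n), fs, band)
    carrier = np.real(analytic.data)
    env = np.abs(analytic.data)
    mean_env = max(env.mean(), 1e-300)
    return carrier / mean_env, env / mean_env


def _draw_so_events(rng, cfg: SyntheticConfig) -> list[SOEvent]:
    lo, hi = cfg.so_band
    if cfg.so_event_onsets is not None:
        # trigger-locked events (acoustic entrainment): fixed onsets, the
        # event frequency still drawn per event from the slow-wave band
        events = []
        for onset in sorted(cfg.so_event_onsets):
            freq = float(rng.uniform(lo, hi))
            n_cyc = int(rng.integers(1, cfg.max_consecutive_so_cycles + 1))
            dur = n_cyc / freq
            if onset < 0 or onset + dur > cfg.duration:
                continue
            if events and onset < events[-1].onset + events[-1].duration:
                continue  # keep events non-overlapping
            amp = float(cfg.signal_scale * rng.uniform(0.8, 1.2))
            events.append(SOEvent(onset=float(onset), duration=dur,
                                  frequency=freq, n_cycles=n_cyc,
                                  amplitude=amp))
        return events
    mean_event_dur = cfg.max_consecutive_so_cycles / ((lo + hi) / 2.0)
    mean_gap = max(60.0 / cfg.so_event_rate - mean_event_dur, 0.2)
    events = []
    t = float(rng.exponential(mean_gap))
    while True:
        freq = float(rng.uniform(lo, hi))
        n_cyc = int(rng.integers(1, cfg.max_consecutive_so_cycles + 1))
        dur = n_cyc / freq
        if t + dur > cfg.duration:
            break
        amp = float(cfg.signal_scale * rng.uniform(0.8, 1.2))
        events.append(SOEvent(onset=t, duration=dur, frequency=freq,
                              n_cycles=n_cyc, amplitude=amp))
        t += dur + float(rng.exponential(mean_gap)) + 0.2
    return events


def generate_sleep_recording(
        config: SyntheticConfig) -> tuple[TimeSeriesRecording, SyntheticGroundTruth]:
    """Generate a multichannel NREM-like recording with known coupling.

    Returns the recording (uV) and the ground truth of every draw.  The
    same seed gives bit-identical output.
    """
    cfg = config
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    depths = cfg.per_channel(cfg.coupling_depth)
    phases = cfg.per_channel(cfg.preferred_phase_deg)

    root = np.random.SeedSequence(cfg.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(cfg.n_channels)]

    data = np.zeros((cfg.n_channels, n))
    all_events: list[list[SOEvent]] = []
    spindle_intervals, gamma_intervals = [], []

    for ch, rng in enumerate(streams):
        noise = _one_over_f_noise(rng, n, cfg.fs, cfg.noise_exponent,
                                  cfg.noise_scale)
        events = _draw_so_events(rng, cfg)
        all_events.append(events)

        so = np.zeros(n)
        gate = np.full(n, cfg.baseline_burst_level)
        modulation = np.ones(n)
        for ev in events:
            i0 = int(round(ev.onset * cfg.fs))
            i1 = min(int(round((ev.onset + ev.duration) * cfg.fs)), n)
            tau = t[i0:i1] - ev.onset
            phi = 360.0 * ev.frequency * tau        # event phase, deg; 0=peak
            window = np.hanning(i1 - i0)
            so[i0:i1] += ev.amplitude * window * np.cos(np.radians(phi))
            gate[i0:i1] = np.maximum(gate[i0:i1], window)
            modulation[i0:i1] = 1.0 + depths[ch] * np.cos(
                np.radians(phi - phases[ch]))

        sp_carrier, _ = _narrowband_noise(rng, n, cfg.fs, cfg.spindle_band)
        ga_carrier, _ = _narrowband_noise(rng, n, cfg.fs, cfg.gamma_band)
        spindle = cfg.spindle_scale * gate * modulation * sp_carrier
        gamma = cfg.gamma_scale * gate * modulation * ga_carrier

        data[ch] = noise + so + spindle + gamma
        intervals = [(ev.onset, ev.onset + ev.duration) for ev in events]
        spindle_intervals.append(intervals)
        gamma_intervals.append(list(intervals))

    recording = TimeSeriesRecording(data=data, fs=cfg.fs)
    truth = SyntheticGroundTruth(
        coupling_depth=depths,
        preferred_phase_deg=phases,
        so_events=all_events,
        burst_intervals={"spindle": spindle_intervals,
                         "gamma": gamma_intervals},
        duration=cfg.duration,
        seed=cfg.seed,
    )
    return recording, truth


def inject_tacs_artifact(recording: TimeSeriesRecording, f_stim: float,
                         amplitude: float, harmonic_coeffs: dict | None = None,
                         drift: float | None = None,
                         truth: SyntheticGroundTruth | None = None
                         ) -> TimeSeriesRecording:
    """Add a sinusoidal tACS artifact with harmonic distortion.

    The fundamental is ``amplitude * cos(2 pi f_stim t)`` (0 degrees at the
    positive/anodal peak).  ``harmonic_coeffs`` maps harmonic number ``k >= 2``
    to ``(a_k, b_k)`` cosine/sine amplitudes in uV.  ``drift``, if given, is
    a fractional linear amplitude change over the recording (e.g. 0.2 ramps
    the artifact by +/-10% around its mean), emulating the slow
    non-stationarity of real stimulation artifacts.
    """
    if amplitude <= 0:
        raise ValueError(f"amplitude must be positive, got {amplitude}")
    if f_stim >= recording.fs / 2.0:
        raise ValueError("f_stim exceeds the Nyquist frequency")
    harmonic_coeffs = harmonic_coeffs or {}
    for k in harmonic_coeffs:
        if k * f_stim >= recording.fs / 2.0:
            raise ValueError(
                f"harmonic {k} at {k * f_stim} Hz exceeds the Nyquist frequency"
            )
    t = recording.times
    wave = amplitude * np.cos(2.0 * np.pi * f_stim * t)
    for k, (a_k, b_k) in harmonic_coeffs.items():
        arg = 2.0 * np.pi * k * f_stim * t
        wave += a_k * np.cos(arg) + b_k * np.sin(arg)
    if drift is not None:
        wave = wave * (1.0 + drift * (t / recording.duration - 0.5))
    out = recording.copy()
    out.data = out.data + wave[None, :]
    if truth is not None:
        truth.artifact = {
            "frequency": f_stim,
            "amplitude": amplitude,
            "harmonic_coeffs": {int(k): (float(a), float(b))
                                for k, (a, b) in harmonic_coeffs.items()},
            "drift": drift,
        }
    return out


def generate_acoustic_triggers(rate: float, duration: float,
                               jitter: float = 0.0, rng=None) -> np.ndarray:
    """Onset times of a periodic noise-burst train.

    With ``jitter=0`` the inter-trigger interval is exactly ``1/rate``; a
    5-minute block at 1 Hz gives 300 triggers and at 0.75 Hz gives 225.
    ``jitter`` is the standard deviation (s) of Gaussian onset jitter.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if duration < 0:
        raise ValueError(f"duration must be non-negative, got {duration}")
    n = int(np.ceil(duration * rate - 1e-9))
    times = np.arange(n) / rate
    if jitter > 0:
        rng = np.random.default_rng(rng)
        times = times + jitter * rng.standard_normal(n)
        times = np.clip(np.sort(times), 0.0, max(duration - 1e-9, 0.0))
    return times


def inject_outlier_epochs(recording: TimeSeriesRecording, intervals,
                          gain: float,
                          truth: SyntheticGroundTruth | None = None
                          ) -> TimeSeriesRecording:
    """Multiply broadband power by ``gain`` inside the given intervals.

    ``intervals`` is a list of ``(t0, t1)`` in seconds; overlapping
    intervals are merged with a warning.  Power scaling by ``gain`` means
    the voltage is scaled by ``sqrt(gain)``; ``gain=1`` is the identity.
    """
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    ivals = sorted((float(a), float(b)) for a, b in intervals)
    for a, b in ivals:
        if not (0.0 <= a < b <= recording.duration + 1e-9):
            raise ValueError(f"interval ({a}, {b}) outside the recording")
    merged: list[list[float]] = []
    overlap = False
    for a, b in ivals:
        if merged and a < merged[-1][1]:
            overlap = True
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    if overlap:
        warnings.warn("overlapping outlier intervals merged", stacklevel=2)
    out = recording.copy()
    factor = np.sqrt(gain)
    for a, b in merged:
        i0, i1 = int(round(a * recording.fs)), int(round(b * recording.fs))
        out.data[:, i0:i1] *= factor
    if truth is not None:
        truth.outlier_intervals.extend((a, b) for a, b in merged)
    return out
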