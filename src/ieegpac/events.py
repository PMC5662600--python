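"""Sleep spindle and slow-wave event detection.

Spindles: the signal is bandpassed in the spindle band, instantaneous power
is the squared envelope, and segments crossing six times the median power
are grown outwards to where power falls below a lower threshold (mean + 1 SD
of power).  Events outside 0.2-2 s are discarded, as are events coinciding
with broadband power increases (movement artifacts).

Slow waves: the trace is bandpassed at (fc=0.75, bw=0.75) Hz and events are
pairs of consecutive negative-going zero crossings separated by 0.5-2 s; the
down-state is the minimum of the filtered voltage within the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .spectral import (BandDefinition, FAST_SPINDLE, SLOW_OSC_075HZ,
                       morlet_bandpass)
from .surrogate import rayleigh_test

__all__ = [
    "SpindleEvent",
    "SlowWaveEvent",
    "detect_spindles",
    "detect_slow_waves",
    "event_phase_preference",
    "event_rate_comparison",
]

SPINDLE_DURATION_RANGE = (0.2, 2.0)     # s
SLOW_WAVE_SEPARATION_RANGE = (0.5, 2.0) # s (2-0.5 Hz)


@dataclass(frozen=True)
class SpindleEvent:
    channel: str
    onset: float          # s
    offset: float         # s
    peak_power: float     # uV^2
    peak_time: float      # s, time of maximum band power

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class SlowWaveEvent:
    channel: str
    zero_crossing_1: float   # s, first negative-going crossing
    zero_crossing_2: float   # s, second negative-going crossing
    down_state_time: float   # s
    down_state_voltage: float  # uV

    @property
    def duration(self) -> float:
        return self.zero_crossing_2 - self.zero_crossing_1


def _broadband_power(x, fs, band_edges, notch_band=None, smooth_s=0.1):
    """Smoothed broadband power, with the detection band notched out so a
    genuine narrowband event cannot trigger its own artifact screen."""
    lo, hi = band_edges
    sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    bb = sp_signal.sosfiltfilt(sos, x)
    if notch_band is not None:
        nlo, nhi = notch_band
        nlo, nhi = max(nlo, lo), min(nhi, hi)
        if nhi > nlo:
            sos_stop = sp_signal.butter(4, [nlo, nhi], btype="bandstop",
                                        fs=fs, output="sos")
            bb = sp_signal.sosfiltfilt(sos_stop, bb)
    power = bb ** 2
    width = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(width) / width
    return np.convolve(power, kernel, mode="same")


def detect_spindles(signal, fs: float, band: BandDefinition = FAST_SPINDLE,
                    channel: str = "ch0", upper_median_mult: float = 6.0,
                    lower_threshold: str = "mean+sd",
                    duration_range=SPINDLE_DURATION_RANGE,
                    broadband_edges=(1.0, 45.0),
                    broadband_percentile: float = 90.0,
                    broadband_stat: str = "median",
                    exclude_broadband: bool = True) -> list[SpindleEvent]:
    """Detect spindle events in one channel.

    ``lower_threshold`` selects the onset/offset criterion: ``"mean+sd"``
    (mean + 1 SD of instantaneous power, default) or ``"sd"`` (1 SD in
    absolute terms).

    The broadband screen drops events coinciding with movement/high-
    frequency artifacts: broadband (1-45 Hz) power is computed with the
    detection band notched out, and an event is excluded when its broadband
    power exceeds the given percentile of the whole-recording distribution.
    ``broadband_stat`` picks the event statistic: ``"median"`` (default)
    compares the event's median smoothed broadband power against the
    sample distribution -- robust against the event maximum being an
    extreme-value draw -- while ``"max"`` compares the event maximum
    against the distribution of 1-s window maxima.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 60.0 * fs:
        raise ValueError(
            "need >= 60 s of signal for stable spindle thresholds, got "
            f"{x.size / fs:.1f} s"
        )
    power = morlet_bandpass(x, fs, band).power
    thr_hi = upper_median_mult * np.median(power)
    if lower_threshold == "mean+sd":
        thr_lo = power.mean() + power.std()
    elif lower_threshold == "sd":
        thr_lo = power.std()
    else:
        raise ValueError(f"unknown lower_threshold {lower_threshold!r}")
    thr_lo = min(thr_lo, thr_hi)

    above_hi = power > thr_hi
    above_lo = power > thr_lo
    if not above_hi.any():
        return []
    # contiguous runs above the lower threshold; keep those containing at
    # least one sample above the upper threshold
    padded = np.r_[False, above_lo, False]
    flips = np.flatnonzero(np.diff(padded.astype(int)))
    runs = list(zip(flips[0::2], flips[1::2]))

    if exclude_broadband:
        bb_power = _broadband_power(x, fs, broadband_edges,
                                    notch_band=band.edges)
        if broadband_stat == "median":
            bb_cut = np.percentile(bb_power, broadband_percentile)
        elif broadband_stat == "max":
            win = int(round(fs))
            n_win = bb_power.size // win
            window_maxima = bb_power[:n_win * win].reshape(n_win, win).max(axis=1)
            bb_cut = np.percentile(window_maxima, broadband_percentile)
        else:
            raise ValueError(f"unknown broadband_stat {broadband_stat!r}")

    events = []
    for s, e in runs:
        if not above_hi[s:e].any():
            continue
        duration = (e - s) / fs
        if not duration_range[0] <= duration <= duration_range[1]:
            continue
        if exclude_broadband:
            stat = (np.median(bb_power[s:e]) if broadband_stat == "median"
                    else bb_power[s:e].max())
            if stat > bb_cut:
                continue
        peak_idx = s + int(np.argmax(power[s:e]))
        events.append(SpindleEvent(
            channel=channel,
            onset=s / fs,
            offset=e / fs,
            peak_power=float(power[peak_idx]),
            peak_time=peak_idx / fs,
        ))
    return events


def detect_slow_waves(signal, fs: float,
                      band: BandDefinition = SLOW_OSC_075HZ,
                      channel: str = "ch0",
                      separation_range=SLOW_WAVE_SEPARATION_RANGE,
                      min_down_state_uv: float = 10.0
                      ) -> list[SlowWaveEvent]:
    """Detect slow-wave events by paired negative-going zero crossings.

    Consecutive negative-going zero crossings of the (0.75, 0.75) Hz
    bandpassed trace separated by 0.5-2 s delimit one event; the down-state
    is the filtered-voltage minimum within the pair.  Events whose
    down-state is shallower than ``min_down_state_uv`` are discarded: the
    bandpass response of an isolated wave rings at the microvolt scale
    beyond the wave itself, and those tail ripples would otherwise pair
    into spurious events (set 0 to disable the guard).
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 30.0 * fs:
        raise ValueError(
            f"need >= 30 s of signal for slow-wave detection, got "
            f"{x.size / fs:.1f} s"
        )
    filt = np.real(morlet_bandpass(x, fs, band).data)
    pos = filt > 0
    crossing_idx = np.flatnonzero(pos[:-1] & ~pos[1:])
    # sub-sample crossing time by linear interpolation
    frac = filt[crossing_idx] / (filt[crossing_idx] - filt[crossing_idx + 1])
    crossing_t = (crossing_idx + frac) / fs

    events = []
    for i in range(len(crossing_t) - 1):
        sep = crossing_t[i + 1] - crossing_t[i]
        if not separation_range[0] <= sep <= separation_range[1]:
            continue
        i0 = crossing_idx[i] + 1
        i1 = crossing_idx[i + 1] + 1
        down_idx = i0 + int(np.argmin(filt[i0:i1]))
        if filt[down_idx] > -min_down_state_uv:
            continue
        events.append(SlowWaveEvent(
            channel=channel,
            zero_crossing_1=float(crossing_t[i]),
            zero_crossing_2=float(crossing_t[i + 1]),
            down_state_time=down_idx / fs,
            down_state_voltage=float(filt[down_idx]),
        ))
    return events


def event_phase_preference(event_times, phase_deg, fs: float
                           ) -> tuple[float, float]:
    """Circular mean phase at event peaks and a Rayleigh test p-value.

    ``event_times`` are the event peak times in seconds; ``phase_deg`` is
    the slow-oscillation phase series the events are referenced to.
    """
    times = np.asarray(event_times, dtype=float)
    if times.size < 5:
        raise ValueError(f"need >= 5 events, got {times.size}")
    phase = np.asarray(phase_deg, dtype=float)
    idx = np.clip(np.round(times * fs).astype(int), 0, phase.size - 1)
    sampled = phase[idx]
    z = np.mean(np.exp(1j * np.radians(sampled)))
    preferred = float(np.degrees(np.angle(z)))
    _, p = rayleigh_test(sampled)
    return preferred, p


def event_rate_comparison(stim_counts, baseline_counts
                          ) -> tuple[float, int, float]:
    """Chi-square comparison of stimulus-locked event-count histograms.

    ``stim_counts`` and ``baseline_counts`` are event counts per time bin
    (same binning in both conditions).  The stimulation histogram is tested
    against the baseline histogram shape (expected counts scaled to the
    stimulation total); degrees of freedom = bins - 1.  Returns
    ``(chi2, dof, p)``.
    """
    obs = np.asarray(stim_counts, dtype=float)
    base = np.asarray(baseline_counts, dtype=float)
    if obs.size == 0 or base.size == 0:
        raise ValueError("empty count table")
    if obs.shape != base.shape:
        raise ValueError("count vectors must share the same binning")
    if base.sum() <= 0:
        raise ValueError("baseline counts sum to zero")
    expected = base * obs.sum() / base.sum()
    low = expected < 5
    if low.mean() > 0.2:
        warnings.warn(
            f"{low.sum()} of {low.size} bins have expected counts < 5; "
            "the chi-square approximation may be poor",
            stacklevel=2,
        )
    dof = obs.size - 1
    if np.allclose(obs, expected):
        return 0.0, dof, 1.0
    chi2 = float(np.sum((obs - expected) ** 2 / np.maximum(expected, 1e-300)))
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, p
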