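"""Cross-rhythm coupling and pre/post stimulation comparisons.

Three analyses live here: the lagged Pearson cross-correlation between the
instantaneous amplitudes of two rhythms (spindle vs gamma alignment), the
multitaper band-power change between a 30-s pre-stimulation segment and the
30-s windows immediately after each stimulation block, and the inter-trial
phase coherence of sinusoid fits (0.5-1.5 Hz) to the stimulation-free
windows following each block of trapezoidal stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .spectral import BandDefinition, multitaper_power, wrap_degrees
from .surrogate import rayleigh_test

__all__ = [
    "CrossCorrelation",
    "amplitude_crosscorrelation",
    "band_power_change",
    "PhaseCoherenceResult",
    "post_stim_phase_coherence",
]


@dataclass
class CrossCorrelation:
    """Normalised cross-correlation as a function of lag.

    Convention: a positive peak lag means the *first* series precedes the
    second.
    """

    lags_s: np.ndarray
    values: np.ndarray
    peak_lag_s: float
    peak_value: float


def amplitude_crosscorrelation(amp_a, amp_b, fs: float, max_lag: float,
                               smooth_hz: float | None = 5.0
                               ) -> CrossCorrelation:
    """Pearson correlation of two amplitude envelopes at each lag.

    Envelopes are low-pass smoothed (default 5 Hz) before correlating to
    suppress carrier leakage.  Positive lag: ``amp_a`` precedes ``amp_b``.
    """
    a = np.asarray(amp_a, dtype=np.float64)
    b = np.asarray(amp_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("amplitude series must be 1-D and equal length")
    max_lag_n = int(round(max_lag * fs))
    if a.size < 10 * max_lag_n:
        raise ValueError(
            f"series of {a.size} samples too short for max_lag={max_lag}s "
            f"(need >= 10 x max lag)"
        )
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant amplitude series: correlation undefined")
    if smooth_hz is not None:
        sos = sp_signal.butter(4, smooth_hz, btype="lowpass", fs=fs,
                               output="sos")
        a = sp_signal.sosfiltfilt(sos, a)
        b = sp_signal.sosfiltfilt(sos, b)

    lags = np.arange(-max_lag_n, max_lag_n + 1)
    values = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[:a.size - lag], b[lag:]
        else:
            x, y = a[-lag:], b[:b.size + lag]
        x = x - x.mean()
        y = y - y.mean()
        denom = np.sqrt((x * x).sum() * (y * y).sum())
        values[i] = (x * y).sum() / denom if denom > 0 else 0.0
    peak = int(np.argmax(values))
    return CrossCorrelation(
        lags_s=lags / fs,
        values=values,
        peak_lag_s=float(lags[peak] / fs),
        peak_value=float(values[peak]),
    )


def band_power_change(pre_segment, post_segments, fs: float,
                      bands: dict, expected_duration: float = 30.0
                      ) -> pd.DataFrame:
    """Band-power difference between pre- and post-stimulation windows.

    ``pre_segment`` is the 30 s preceding the first stimulation block;
    ``post_segments`` are the 30-s windows immediately after each block.
    Powers are multitaper estimates.  The log power ratio is tested with
    the chi-square degrees-of-freedom approximation of each segment's
    band-integrated estimate (``se = sqrt(2/dof_pre + 2/dof_post)``): the
    across-taper jackknife understates the variance of a band integral
    because eigenspectra are correlated across frequencies, so it is not
    used for the p-value.  FDR correction across electrodes is left to
    :func:`ieegpac.surrogate.fdr_correct` on the returned p-values.
    """
    pre = np.asarray(pre_segment, dtype=np.float64)
    n_expected = int(round(expected_duration * fs))
    if abs(pre.size - n_expected) > 1:
        raise ValueError(
            f"pre segment has {pre.size} samples; expected "
            f"{n_expected} ({expected_duration} s at {fs} Hz, tolerance 1)"
        )
    rows = []
    for seg_idx, post in enumerate(post_segments):
        post = np.asarray(post, dtype=np.float64)
        if abs(post.size - n_expected) > 1:
            raise ValueError(
                f"post segment {seg_idx} has {post.size} samples; expected "
                f"{n_expected}"
            )
        for name, band in bands.items():
            mp_pre = multitaper_power(pre, fs, band)
            mp_post = multitaper_power(post, fs, band)
            log_ratio = float(np.log(mp_post.power / mp_pre.power))
            se = float(np.sqrt(2.0 / mp_pre.dof + 2.0 / mp_post.dof))
            z = log_ratio / se if se > 0 else 0.0
            p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
            tcrit = stats.norm.ppf(0.975)
            rows.append({
                "segment": seg_idx,
                "band": name,
                "pre_power": mp_pre.power,
                "post_power": mp_post.power,
                "log_ratio": log_ratio,
                "ratio": float(np.exp(log_ratio)),
                "ci_low": float(np.exp(log_ratio - tcrit * se)),
                "ci_high": float(np.exp(log_ratio + tcrit * se)),
                "p_value": p,
            })
    return pd.DataFrame(rows)


@dataclass
class PhaseCoherenceResult:
    """Inter-trial phase coherence of post-stimulation sinusoid fits."""

    phases_deg: np.ndarray       # per-trial phase at window start
    frequencies: np.ndarray      # per-trial fitted frequency, Hz
    amplitudes: np.ndarray       # per-trial fitted amplitude
    coherence: float             # resultant length of trial phases
    mean_phase_deg: float
    p_value: float               # Rayleigh test
    edge_pinned_fraction: float


def post_stim_phase_coherence(trials, fs: float,
                              f_range=(0.5, 1.5), f_step: float = 0.01
                              ) -> PhaseCoherenceResult:
    """Fit each stimulation-free window with a sinusoid; test phase locking.

    For every trial the best-fit sinusoid (frequency gridded over
    ``f_range``, amplitude/phase solved linearly) is found; the per-trial
    phase is referenced to the window start (stimulation offset), so 0
    degrees means a positive peak at the moment stimulation ended.
    Coherence is the resultant length of these phases; significance comes
    from the Rayleigh test.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=np.float64))
    n_trials, n_samples = trials.shape
    if n_trials < 10:
        raise ValueError(f"need >= 10 trials, got {n_trials}")
    t = np.arange(n_samples) / fs
    freqs = np.arange(f_range[0], f_range[1] + f_step / 2.0, f_step)

    best_rss = np.full(n_trials, np.inf)
    best = np.zeros((n_trials, 3))   # freq, a (cos), b (sin)
    demeaned = trials - trials.mean(axis=1, keepdims=True)
    for f in freqs:
        design = np.column_stack([np.cos(2 * np.pi * f * t),
                                  np.sin(2 * np.pi * f * t)])
        coef, _, _, _ = np.linalg.lstsq(design, demeaned.T, rcond=None)
        resid = demeaned.T - design @ coef
        rss = (resid ** 2).sum(axis=0)
        better = rss < best_rss
        best_rss[better] = rss[better]
        best[better, 0] = f
        best[better, 1:] = coef.T[better]

    a, b = best[:, 1], best[:, 2]
    amplitudes = np.hypot(a, b)
    # fitted = A cos(2 pi f t - phi0); phase at t=0 is -phi0
    phases = wrap_degrees(-np.degrees(np.arctan2(b, a)))
    pinned = np.isclose(best[:, 0], f_range[0]) | np.isclose(best[:, 0],
                                                             f_range[1])
    frac_pinned = float(pinned.mean())
    if frac_pinned > 0.5:
        warnings.warn(
            f"fit frequency pinned at the range edge in "
            f"{100 * frac_pinned:.0f}% of trials",
            stacklevel=2,
        )
    z = np.mean(np.exp(1j * np.radians(phases)))
    _, p = rayleigh_test(phases)
    return PhaseCoherenceResult(
        phases_deg=phases,
        frequencies=best[:, 0].copy(),
        amplitudes=amplitudes,
        coherence=float(np.abs(z)),
        mean_phase_deg=float(wrap_degrees(np.degrees(np.angle(z)))),
        p_value=p,
        edge_pinned_fraction=frac_pinned,
    )
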