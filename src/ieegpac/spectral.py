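"""Band decomposition and power estimation.

All narrowband quantities in this package come from a complex Morlet wavelet
filter.  A band is specified by its centre frequency ``fc`` and bandwidth
``bw``, where the bandwidth is the full width at half maximum (FWHM) of the
wavelet's frequency-domain magnitude response.  The fast-spindle band
``(fc=14, bw=7)`` thus has half-amplitude edges at 10.5 and 17.5 Hz and
splits cleanly from the slow-spindle band ``(10, 5)``.

Phase convention (anchor for the whole package): the instantaneous phase of
``cos(2*pi*fc*t)`` is 0 degrees at the signal peaks and +/-180 degrees at the
troughs.  For slow oscillations 0 degrees is the cortical upstate on most
surface electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal.windows import dpss

__all__ = [
    "BandDefinition",
    "AnalyticSignal",
    "morlet_bandpass",
    "multitaper_power",
    "MultitaperPower",
    "time_frequency_response",
    "TFRResult",
    "wrap_degrees",
    "FAST_SPINDLE",
    "SLOW_SPINDLE",
    "THETA",
    "ALPHA",
    "GAMMA",
    "SLOW_OSC_1HZ",
    "SLOW_OSC_075HZ",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def wrap_degrees(angle):
    """Wrap angles in degrees to the interval (-180, 180]."""
    wrapped = np.asarray(angle, dtype=float) % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # map -180 exactly onto +180 so the interval is half-open at the bottom
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band: centre ``fc`` and FWHM bandwidth ``bw`` in Hz."""

    fc: float
    bw: float

    def __post_init__(self) -> None:
        if not self.fc > 0:
            raise ValueError(f"fc must be positive, got fc={self.fc}")
        if not 0 < self.bw <= 2 * self.fc:
            raise ValueError(
                f"bw must satisfy 0 < bw <= 2*fc, got bw={self.bw}, fc={self.fc}"
            )

    @property
    def sigma_f(self) -> float:
        """Std of the Gaussian frequency response, Hz."""
        return self.bw / _FWHM_TO_SIGMA

    @property
    def sigma_t(self) -> float:
        """Std of the wavelet's temporal envelope, seconds."""
        return 1.0 / (2.0 * np.pi * self.sigma_f)

    @property
    def edges(self) -> tuple[float, float]:
        """Half-amplitude (FWHM) band edges in Hz."""
        return (self.fc - self.bw / 2.0, self.fc + self.bw / 2.0)

    def check_nyquist(self, fs: float) -> None:
        if self.fc + self.bw / 2.0 >= fs / 2.0:
            raise ValueError(
                f"band (fc={self.fc}, bw={self.bw}) exceeds the Nyquist "
                f"frequency {fs / 2.0} Hz"
            )


# canonical bands used throughout the analyses
FAST_SPINDLE = BandDefinition(14.0, 7.0)
SLOW_SPINDLE = BandDefinition(10.0, 5.0)
THETA = BandDefinition(7.0, 3.5)
ALPHA = BandDefinition(10.0, 5.0)
GAMMA = BandDefinition(90.0, 40.0)        # 70-110 Hz
SLOW_OSC_1HZ = BandDefinition(1.0, 1.0)
SLOW_OSC_075HZ = BandDefinition(0.75, 0.75)


@dataclass
class AnalyticSignal:
    """Complex narrowband signal: magnitude = amplitude, angle = phase."""

    data: np.ndarray          # complex, (..., n_samples)
    band: BandDefinition
    fs: float
    edge_samples: int = 0     # samples at each end still touched by padding

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase_deg(self) -> np.ndarray:
        """Instantaneous phase in degrees, in (-180, 180]."""
        return wrap_degrees(np.degrees(np.angle(self.data)))

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.data) ** 2

    def edge_mask(self) -> np.ndarray:
        """Boolean mask of samples free of filter edge effects."""
        n = self.data.shape[-1]
        mask = np.ones(n, dtype=bool)
        k = min(self.edge_samples, n)
        mask[:k] = False
        mask[n - k:] = False
        return mask


def morlet_bandpass(signal, fs: float, band: BandDefinition) -> AnalyticSignal:
    """Complex Morlet wavelet filter.

    Implemented as multiplication of the spectrum with a Gaussian of FWHM
    ``band.bw`` centred at ``band.fc``, keeping positive frequencies only
    (doubled), i.e. convolution with a complex Morlet wavelet normalised to
    unit gain at ``fc``.  A unit cosine at ``fc`` therefore comes out with
    instantaneous amplitude 1 and phase 0 at its peaks.

    The input is reflect-padded by one wavelet support (4 temporal sigma) on
    each side and the pads are discarded; samples within one support of the
    boundary are reported via ``edge_samples`` so cycles overlapping them can
    be flagged rather than silently kept.
    """
    band.check_nyquist(fs)
    x = np.asarray(signal, dtype=np.float64)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[-1]

    pad = int(np.ceil(4.0 * band.sigma_t * fs))
    if n <= 3 * pad:
        raise ValueError(
            f"signal of {n} samples is shorter than 3 wavelet supports "
            f"({3 * pad} samples) for band fc={band.fc}, bw={band.bw}"
        )
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    m = xp.shape[-1]

    freqs = np.fft.fftfreq(m, d=1.0 / fs)
    gain = np.exp(-((freqs - band.fc) ** 2) / (2.0 * band.sigma_f ** 2))
    gain[freqs < 0] = 0.0
    gain *= 2.0
    if m % 2 == 0:
        gain[m // 2] /= 2.0  # Nyquist bin is its own conjugate
    gain[0] = 0.0            # reject DC exactly (zero-mean wavelet)

    out = np.fft.ifft(np.fft.fft(xp, axis=-1) * gain, axis=-1)
    out = out[..., pad:pad + n]
    if squeeze:
        out = out[0]
    return AnalyticSignal(data=out, band=band, fs=fs, edge_samples=pad)


@dataclass
class MultitaperPower:
    """Band-integrated multitaper power with a jackknife confidence interval.

    ``dof`` is the approximate chi-square degrees of freedom of the
    band-integrated estimate, ``2 K max(1, B / 2W)`` for band width B and
    taper resolution half-width W: eigenspectra are independent across
    tapers at any one frequency but correlated across frequencies, so the
    across-taper jackknife understates the variance of a band integral
    while the chi-square count does not.
    """

    power: float              # uV^2 (band-integrated)
    ci_low: float
    ci_high: float
    n_tapers: int
    dof: float
    freqs: np.ndarray
    psd: np.ndarray           # mean one-sided PSD across tapers, uV^2/Hz


def _taper_band_powers(segment, fs, band, nw, n_tapers):
    x = np.asarray(segment, dtype=np.float64)
    n = x.size
    tapers = dpss(n, nw, Kmax=n_tapers)
    tapers = tapers / np.sqrt(np.sum(tapers ** 2, axis=1, keepdims=True))
    spec = np.fft.rfft(tapers * x[None, :], axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.abs(spec) ** 2 / fs
    # one-sided: double everything except DC and (for even n) Nyquist
    psd[:, 1:] *= 2.0
    if n % 2 == 0:
        psd[:, -1] /= 2.0
    df = fs / n
    if band is None:
        sel = np.ones_like(freqs, dtype=bool)
    else:
        lo, hi = band.edges
        sel = (freqs >= lo) & (freqs <= hi)
    return freqs, psd, psd[:, sel].sum(axis=1) * df


def multitaper_power(segment, fs: float, band: BandDefinition | None = None,
                     nw: float = 3.0, n_tapers: int = 5) -> MultitaperPower:
    """Multitaper (DPSS) band-integrated power with jackknife 95% CI.

    ``band=None`` integrates over the whole spectrum, in which case the
    estimate is the signal variance (Parseval).  Defaults: time-bandwidth
    product 3 with 5 tapers.
    """
    x = np.asarray(segment, dtype=np.float64)
    if band is not None:
        f_low = max(band.edges[0], 1e-6)
        min_n = int(np.ceil(10.0 / f_low * fs))
        if x.size < min_n:
            raise ValueError(
                f"segment of {x.size} samples is too short for band "
                f"fc={band.fc}: need >= 10 cycles of the lower band edge "
                f"({min_n} samples at fs={fs})"
            )
    freqs, psd, band_powers = _taper_band_powers(x, fs, band, nw, n_tapers)
    k = band_powers.size
    duration = x.size / fs
    band_width = (band.bw if band is not None else fs / 2.0)
    dof = 2.0 * k * max(1.0, band_width / (2.0 * nw / duration))
    log_p = np.log(np.maximum(band_powers, 1e-300))
    # leave-one-taper-out jackknife on log power
    loo = (log_p.sum() - log_p) / (k - 1)
    jk_var = (k - 1) / k * np.sum((loo - loo.mean()) ** 2)
    se = np.sqrt(jk_var)
    t = stats.t.ppf(0.975, df=k - 1)
    mean_log = log_p.mean()
    return MultitaperPower(
        power=float(band_powers.mean()),
        ci_low=float(np.exp(mean_log - t * se)),
        ci_high=float(np.exp(mean_log + t * se)),
        n_tapers=k,
        dof=float(dof),
        freqs=freqs,
        psd=psd.mean(axis=0),
    )


@dataclass
class TFRResult:
    """Baseline-normalised time-frequency map with a significance mask."""

    tfr_db: np.ndarray        # (n_freqs, n_times), dB re baseline
    p_values: np.ndarray      # per-pixel one-tailed paired t-test
    q_values: np.ndarray
    mask: np.ndarray          # significant after BH-FDR across pixels
    freqs: np.ndarray
    times: np.ndarray

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("tfr_db", data=self.tfr_db)
            f.create_dataset("p_values", data=self.p_values)
            f.create_dataset("q_values", data=self.q_values)
            f.create_dataset("mask", data=self.mask)
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("times", data=self.times)


def time_frequency_response(epochs, fs: float, baseline_epochs,
                            freqs=None, n_cycles: float = 6.0,
                            alpha: float = 0.05) -> TFRResult:
    """Morlet time-frequency response of stimulation-locked epochs.

    Power per epoch is computed with fixed 6-cycle Morlet wavelets (5-25 Hz
    by default), averaged across epochs and expressed in dB relative to the
    mean baseline power per frequency.  Each pixel is tested with a paired
    one-tailed t-test (stimulation > baseline) across epoch pairs and masked
    by Benjamini-Hochberg FDR across all pixels.
    """
    from mne.time_frequency import tfr_array_morlet
    from statsmodels.stats.multitest import multipletests

    epochs = np.atleast_2d(np.asarray(epochs, dtype=np.float64))
    baseline = np.atleast_2d(np.asarray(baseline_epochs, dtype=np.float64))
    if epochs.size == 0 or baseline.size == 0:
        raise ValueError("empty epoch set")
    if epochs.shape[0] < 2 or baseline.shape[0] < 2:
        raise ValueError("need at least 2 epochs per condition")
    if epochs.shape[1] != baseline.shape[1]:
        raise ValueError(
            f"mismatched epoch lengths: {epochs.shape[1]} vs {baseline.shape[1]}"
        )
    if epochs.shape[0] != baseline.shape[0]:
        raise ValueError(
            "paired test requires equal numbers of stimulation and baseline "
            f"epochs, got {epochs.shape[0]} and {baseline.shape[0]}"
        )
    if freqs is None:
        freqs = np.arange(5.0, 25.5, 0.5)
    freqs = np.asarray(freqs, dtype=float)

    def _power(block):
        out = tfr_array_morlet(block[:, None, :], sfreq=fs, freqs=freqs,
                               n_cycles=n_cycles, output="power",
                               verbose="error")
        return out[:, 0]          # (n_epochs, n_freqs, n_times)

    p_stim = _power(epochs)
    p_base = _power(baseline)

    base_mean = p_base.mean(axis=(0, 2))          # per-frequency baseline
    tfr_db = 10.0 * np.log10(p_stim.mean(axis=0) / base_mean[:, None])

    tstat, pvals = stats.ttest_rel(p_stim, p_base, axis=0)
    # one-tailed: stimulation > baseline
    pvals = np.where(tstat > 0, pvals / 2.0, 1.0 - pvals / 2.0)
    flat = pvals.ravel()
    reject, qvals, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
    times = np.arange(epochs.shape[1]) / fs
    return TFRResult(
        tfr_db=tfr_db,
        p_values=pvals,
        q_values=qvals.reshape(pvals.shape),
        mask=reject.reshape(pvals.shape),
        freqs=freqs,
        times=times,
    )
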