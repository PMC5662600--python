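"""Cycle-wise phase-amplitude coupling.

The analysis proceeds per low-frequency (LF) cycle: the recording is
segmented into complete LF cycles (from a continuous phase series, or from
stimulus onsets when the phase reference is a trigger train), cycles with
excessive high-frequency power or insufficient slow-oscillation amplitude
are rejected, the endogenous phase distribution is equalized, and the
modulation index

    r = | < A_HF(t) * exp(i * phi_LF(t)) > |

is computed over all retained samples pooled across cycles.  ``r`` carries
the amplitude's units (it is not normalised); the preferred phase is the
argument of the same average, in degrees with 0 at the LF positive peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import wrap_degrees

__all__ = [
    "CycleTable",
    "PACResult",
    "segment_cycles",
    "reject_outlier_cycles",
    "amplitude_floor_filter",
    "equalize_phase_histogram",
    "modulation_index",
    "cycle_complex_sums",
]

PHASE_SOURCES = ("endogenous", "tacs", "acoustic")
MIN_CYCLES = 10


@dataclass
class CycleTable:
    """Per-LF-cycle bookkeeping: boundaries, retention flags, reasons.

    Backed by a DataFrame with columns ``start``/``end`` (samples, end
    exclusive), ``phase_source``, ``mean_hf_power``, ``retained`` and
    ``reject_reason``.  Cycles are ordered and non-overlapping; a retained
    cycle has no rejection reason.
    """

    df: pd.DataFrame
    fs: float
    phase_source: str = "endogenous"

    def __post_init__(self) -> None:
        if self.phase_source not in PHASE_SOURCES:
            raise ValueError(
                f"phase_source must be one of {PHASE_SOURCES}, "
                f"got {self.phase_source!r}"
            )
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        if np.any(ends <= starts):
            raise ValueError("cycle end must be after cycle start")
        if np.any(starts[1:] < ends[:-1] - 0):
            # trigger-defined cycles may touch but must not overlap
            if np.any(starts[1:] < starts[:-1]):
                raise ValueError("cycles must be ordered")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_retained(self) -> int:
        return int(self.df["retained"].sum())

    def retained(self) -> pd.DataFrame:
        return self.df[self.df["retained"]]

    def reject(self, mask, reason: str) -> "CycleTable":
        """Return a copy with ``mask`` cycles flagged as rejected."""
        df = self.df.copy()
        mask = np.asarray(mask, dtype=bool)
        newly = mask & df["retained"].to_numpy()
        df.loc[newly, "retained"] = False
        df.loc[newly, "reject_reason"] = reason
        return CycleTable(df=df, fs=self.fs, phase_source=self.phase_source)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _table_from_bounds(starts, ends, fs, phase_source) -> CycleTable:
    df = pd.DataFrame({
        "start": np.asarray(starts, dtype=int),
        "end": np.asarray(ends, dtype=int),
        "phase_source": phase_source,
        "mean_hf_power": np.nan,
        "retained": True,
        "reject_reason": "",
    })
    return CycleTable(df=df, fs=fs, phase_source=phase_source)


def segment_cycles(fs: float, phase=None, triggers=None, n_samples=None,
                   phase_source: str = "endogenous") -> CycleTable:
    """Segment a recording into complete low-frequency cycles.

    Either a continuous ``phase`` series (degrees) or a monotone ``triggers``
    onset list (seconds, requires ``n_samples``) must be given.

    From a phase series, cycle boundaries are the successive crossings of the
    unwrapped phase through multiples of 360 degrees from its starting value;
    a final cycle whose boundary falls within one sample of the end of the
    series counts as complete.  From triggers, each cycle starts at an onset
    and lasts the mean inter-stimulus interval.

    Fewer than 10 complete cycles is an error (insufficient data).
    """
    if (phase is None) == (triggers is None):
        raise ValueError("provide exactly one of phase or triggers")

    if phase is not None:
        phase = np.asarray(phase, dtype=np.float64)
        unwrapped = np.unwrap(np.radians(phase)) / (2.0 * np.pi)  # cycles
        # enforce monotonicity for boundary search: first-crossing times of
        # the running maximum equal those of the raw series
        mono = np.maximum.accumulate(unwrapped)
        total = mono[-1] - mono[0]
        step = total / max(len(mono) - 1, 1)
        n_complete = int(np.floor(total + step + 1e-6))
        bounds = np.searchsorted(mono, mono[0] + np.arange(n_complete + 1),
                                 side="left")
        bounds = np.minimum(bounds, len(mono))
        starts, ends = bounds[:-1], bounds[1:]
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
    else:
        triggers = np.asarray(triggers, dtype=np.float64)
        if n_samples is None:
            raise ValueError("n_samples is required with trigger input")
        if triggers.size < 2:
            raise ValueError(
                "insufficient data: need at least 2 triggers to determine "
                "the cycle duration"
            )
        if np.any(np.diff(triggers) <= 0):
            raise ValueError("triggers must be strictly increasing")
        isi = float(np.mean(np.diff(triggers)))
        dur = int(round(isi * fs))
        starts = np.round(triggers * fs).astype(int)
        ends = starts + dur
        keep = (starts >= 0) & (ends <= n_samples)
        starts, ends = starts[keep], ends[keep]

    if len(starts) < MIN_CYCLES:
        raise ValueError(
            f"insufficient data: only {len(starts)} complete cycles "
            f"(need >= {MIN_CYCLES})"
        )
    return _table_from_bounds(starts, ends, fs, phase_source)


def _per_cycle(values: np.ndarray, table: CycleTable, reducer) -> np.ndarray:
    out = np.empty(len(table))
    for i, (s, e) in enumerate(zip(table.df["start"], table.df["end"])):
        out[i] = reducer(values[s:e])
    return out


def reject_outlier_cycles(table: CycleTable, hf_amplitude,
                          rule: str = "median+2iqr") -> CycleTable:
    """Flag cycles with excessive mean high-frequency power.

    For each cycle the mean HF power (squared amplitude averaged over the
    cycle) is computed; a cycle is rejected when its power strictly exceeds
    the threshold.  ``rule="median+2iqr"`` (default) uses median + 2 x IQR of
    the cycle powers; ``rule="2iqr"`` is the literal reading, power > 2 x IQR.
    A single pass over all cycles; the threshold is not recomputed on the
    retained set.
    """
    if len(table) < MIN_CYCLES:
        raise ValueError(f"need >= {MIN_CYCLES} cycles for outlier statistics")
    amp = np.asarray(hf_amplitude, dtype=np.float64)
    powers = _per_cycle(amp ** 2, table, np.mean)
    iqr = stats.iqr(powers)
    if rule == "median+2iqr":
        threshold = np.median(powers) + 2.0 * iqr
    elif rule == "2iqr":
        threshold = 2.0 * iqr
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    mask = powers > threshold  # strict: zero-IQR ties are kept
    out = table.reject(mask, "outlier power")
    out.df["mean_hf_power"] = powers
    return out


def amplitude_floor_filter(table: CycleTable, so_amplitude,
                           floor: float = 50.0) -> CycleTable:
    """Flag cycles whose peak slow-oscillation amplitude is below ``floor``.

    Only meaningful for the endogenous phase source: during tACS and
    acoustic stimulation the phase reference is external and the
    slow-oscillation amplitude plays no role.
    """
    if table.phase_source != "endogenous":
        raise ValueError(
            "amplitude floor applies to endogenous cycles only, "
            f"not phase_source={table.phase_source!r}"
        )
    amp = np.asarray(so_amplitude, dtype=np.float64)
    peaks = _per_cycle(amp, table, np.max)
    return table.reject(peaks < floor, "low SO amplitude")


def equalize_phase_histogram(phase_deg) -> np.ndarray:
    """Rank-based circular histogram equalization.

    Sorted phases are mapped onto equally spaced values around the circle,
    anchored at the smallest input phase so an already-uniform grid is a
    fixed point.  Rank order is preserved; the output phase distribution is
    uniform by construction.  Applied to endogenous phase only -- tACS and
    acoustic phases are uniform by construction.
    """
    phase = wrap_degrees(np.asarray(phase_deg, dtype=np.float64))
    n = phase.size
    if n == 0:
        return phase
    order = np.argsort(phase, kind="stable")
    out = np.empty(n)
    out[order] = phase[order[0]] + 360.0 * np.arange(n) / n
    return wrap_degrees(out)


def modulation_index(amplitude, phase_deg) -> tuple[float, float]:
    """Modulation index r and preferred phase.

    ``r = |mean(A * exp(i*phi))|`` over all samples (pooled across retained
    cycles); preferred phase is the argument of that mean, in degrees.  ``r``
    is unnormalised and carries the units of ``amplitude``.
    """
    amp = np.asarray(amplitude, dtype=np.float64)
    phase = np.asarray(phase_deg, dtype=np.float64)
    if amp.size == 0:
        raise ValueError("empty input: no retained samples")
    if amp.shape != phase.shape:
        raise ValueError("amplitude and phase must have the same shape")
    z = np.mean(amp * np.exp(1j * np.radians(phase)))
    return float(np.abs(z)), float(wrap_degrees(np.degrees(np.angle(z))))


def cycle_complex_sums(table: CycleTable, amplitude, phase_deg,
                       aligned: bool = False):
    """Per-retained-cycle sums of ``A * exp(i*phi)`` and sample counts.

    These are the sufficient statistics for the cycle-shift surrogate test:
    rotating cycle ``c`` by ``delta`` multiplies its sum by ``exp(i*delta)``.
    With ``aligned=True`` the arrays span *all* cycles of the table, with
    zeros at rejected cycles, so electrodes with different retained subsets
    of a shared segmentation stay cycle-aligned for shared shuffle draws.
    """
    amp = np.asarray(amplitude, dtype=np.float64)
    z = amp * np.exp(1j * np.radians(np.asarray(phase_deg, dtype=np.float64)))
    rows = table.df if aligned else table.retained()
    sums = np.zeros(len(rows), dtype=complex)
    counts = np.zeros(len(rows), dtype=int)
    keep = rows["retained"].to_numpy()
    for i, (s, e, ok) in enumerate(zip(rows["start"], rows["end"], keep)):
        if aligned and not ok:
            continue
        sums[i] = z[s:e].sum()
        counts[i] = e - s
    return sums, counts


@dataclass
class PACResult:
    """Per-electrode PAC outcome for one analysis block."""

    electrode: str
    r: float                   # modulation index, amplitude units
    r_normalized: float        # r / mean amplitude, dimensionless
    preferred_phase_deg: float
    n_cycles: int
    p_value: float = np.nan
    q_value: float = np.nan
    significant: bool = False
    block: str = ""
    phase_source: str = "endogenous"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("modulation index r must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @staticmethod
    def table(results: list["PACResult"]) -> pd.DataFrame:
        return pd.DataFrame([{
            "electrode": r.electrode,
            "block": r.block,
            "phase_source": r.phase_source,
            "r": r.r,
            "r_normalized": r.r_normalized,
            "preferred_phase_deg": r.preferred_phase_deg,
            "n_cycles": r.n_cycles,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": r.significant,
        } for r in results])
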