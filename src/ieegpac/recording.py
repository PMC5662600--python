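"""Multichannel voltage-trace container and file I/O.

The in-memory container is a thin dataclass around a ``(n_channels,
n_samples)`` float array in microvolts.  On disk, recordings live either in
an HDF5 container (lossless, the internal format) or in EDF (16-bit, for
interchange with clinical viewers).  Event/trigger tables are plain
tab-separated files with ``onset / duration / label`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesRecording",
    "write_events_tsv",
    "read_events_tsv",
]


@dataclass
class TimeSeriesRecording:
    """Multichannel voltage trace.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage samples in ``units``.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel labels, one per row of ``data``.
    units : str
        Physical unit of ``data`` (microvolts by default).
    """

    data: np.ndarray
    fs: float
    channels: list[str] = field(default_factory=list)
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channels:
            self.channels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "TimeSeriesRecording":
        return replace(self, data=self.data.copy(), channels=list(self.channels))

    def crop(self, tmin: float, tmax: float) -> "TimeSeriesRecording":
        """Return the samples in ``[tmin, tmax)`` seconds."""
        i0 = int(round(tmin * self.fs))
        i1 = int(round(tmax * self.fs))
        if not 0 <= i0 < i1 <= self.n_samples:
            raise ValueError(f"crop window [{tmin}, {tmax}) outside recording")
        return replace(self, data=self.data[:, i0:i1].copy(),
                       channels=list(self.channels))

    # ------------------------------------------------------------------ HDF5
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=self.data)
            dset.attrs["fs"] = self.fs
            dset.attrs["units"] = self.units
            f.create_dataset(
                "channels",
                data=np.array(self.channels, dtype=h5py.string_dtype()),
            )

    @classmethod
    def from_hdf5(cls, path) -> "TimeSeriesRecording":
        with h5py.File(path, "r") as f:
            dset = f["data"]
            data = dset[()]
            fs = float(dset.attrs["fs"])
            units = str(dset.attrs.get("units", "uV"))
            channels = [c.decode() if isinstance(c, bytes) else str(c)
                        for c in f["channels"][()]]
        return cls(data=data, fs=fs, channels=channels, units=units)

    # ------------------------------------------------------------------- EDF
    def to_edf(self, path) -> None:
        """Write the recording as a plain EDF file.

        Samples are quantised to 16 bits over each channel's observed
        physical range.  One-second data records are used, so a trailing
        sub-second remainder is dropped.  The sampling rate must be an
        integer for this layout.
        """
        fs = int(round(self.fs))
        if abs(fs - self.fs) > 1e-9:
            raise ValueError("EDF export requires an integer sampling rate")
        n_rec = self.n_samples // fs
        if n_rec < 1:
            raise ValueError("recording shorter than one EDF data record (1 s)")
        ns = self.n_channels
        data = self.data[:, : n_rec * fs]

        phys_min = data.min(axis=1)
        phys_max = data.max(axis=1)
        # avoid a zero physical range on flat channels
        flat = phys_max - phys_min < 1e-12
        phys_max = np.where(flat, phys_min + 1.0, phys_max)
        dig_min, dig_max = -32768, 32767
        scale = (dig_max - dig_min) / (phys_max - phys_min)
        digital = np.clip(
            np.round((data - phys_min[:, None]) * scale[:, None]) + dig_min,
            dig_min, dig_max,
        ).astype("<i2")

        def pad(text: str, width: int) -> bytes:
            b = text.encode("ascii")[:width]
            return b + b" " * (width - len(b))

        header = b"".join([
            pad("0", 8),                       # version
            pad("X X X X", 80),                # patient id
            pad("Startdate X X X X", 80),      # recording id
            pad("01.01.00", 8),                # start date
            pad("00.00.00", 8),                # start time
            pad(str(256 * (ns + 1)), 8),       # header bytes
            pad("", 44),                       # reserved
            pad(str(n_rec), 8),                # number of data records
            pad("1", 8),                       # record duration, seconds
            pad(str(ns), 4),                   # number of signals
        ])
        blocks = [
            [(lbl[:16], 16) for lbl in self.channels],            # label
            [("", 80)] * ns,                                      # transducer
            [(self.units, 8)] * ns,                               # dimension
            [("%.6g" % v, 8) for v in phys_min],
            [("%.6g" % v, 8) for v in phys_max],
            [(str(dig_min), 8)] * ns,
            [(str(dig_max), 8)] * ns,
            [("", 80)] * ns,                                      # prefilter
            [(str(fs), 8)] * ns,                                  # samples/rec
            [("", 32)] * ns,                                      # reserved
        ]
        sig_header = b"".join(
            pad(text, width) for block in blocks for text, width in block
        )
        with open(path, "wb") as f:
            f.write(header)
            f.write(sig_header)
            for r in range(n_rec):
                chunk = digital[:, r * fs:(r + 1) * fs]
                f.write(chunk.tobytes())

    @classmethod
    def from_edf(cls, path) -> "TimeSeriesRecording":
        """Read an EDF file via MNE; voltages returned in microvolts."""
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # MNE loads volts
        return cls(data=data, fs=float(raw.info["sfreq"]),
                   channels=list(raw.ch_names), units="uV")


def write_events_tsv(path, onsets, durations=None, labels=None) -> None:
    """Write an ``onset / duration / label`` events table (BIDS-style)."""
    onsets = np.asarray(onsets, dtype=float)
    if durations is None:
        durations = np.zeros_like(onsets)
    if labels is None:
        labels = ["event"] * len(onsets)
    pd.DataFrame(
        {"onset": onsets, "duration": durations, "label": labels}
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")

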