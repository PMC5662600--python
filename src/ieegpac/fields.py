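"""Projected electric fields from stimulation voltages at the electrodes.

During sinusoidal stimulation each intracranial electrode records a
sinusoid whose amplitude reflects the local stimulation potential.  The
projected electric field between two adjacent electrodes is the potential
difference divided by their separation (V/m), i.e. the field component
along the pair axis -- a lower bound on the local field magnitude, since
the true field vector is generally not parallel to the pair.  Fields are
normalised to 1 mA of stimulation current (voltages scale linearly with
current below amplifier saturation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import wrap_degrees

__all__ = [
    "ElectrodeArray",
    "StimVoltage",
    "estimate_stim_voltage",
    "projected_field",
    "field_summary",
]

logger = logging.getLogger(__name__)

# adjacency vicinity by electrode kind, mm (centre-centre spacing is 10 mm
# for grids/strips, 5 mm for depth arrays)
VICINITY_MM = {"grid": 10.0, "strip": 10.0, "depth": 5.0}


@dataclass
class ElectrodeArray:
    """Electrode geometry: id, array kind and membership, 3-D position (mm)."""

    df: pd.DataFrame    # columns: id, kind, array, x, y, z

    REQUIRED = ("id", "kind", "array", "x", "y", "z")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"geometry table missing columns {sorted(missing)}")
        bad_kind = set(self.df["kind"]) - set(VICINITY_MM)
        if bad_kind:
            raise ValueError(
                f"unknown electrode kind(s) {sorted(bad_kind)}; "
                f"expected one of {sorted(VICINITY_MM)}"
            )
        xyz = self.df[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("electrode positions must be finite")
        if self.df["id"].duplicated().any():
            raise ValueError("duplicate electrode ids in geometry")

    @classmethod
    def from_tsv(cls, path) -> "ElectrodeArray":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def positions(self) -> dict:
        return {row.id: np.array([row.x, row.y, row.z])
                for row in self.df.itertuples()}


@dataclass
class StimVoltage:
    """Fitted stimulation sinusoid at one electrode."""

    amplitude_uv: float
    phase_deg: float       # 0 deg = positive peak at t=0
    clipped: bool
    clip_fraction: float


def estimate_stim_voltage(signal, fs: float, f_stim: float,
                          clip_threshold: float = 0.01) -> StimVoltage:
    """Amplitude of the best-fit sinusoid at the stimulation frequency.

    The fit is linear least squares with free phase and DC offset.
    Channels where more than ``clip_threshold`` of samples sit at the
    digitiser extremes are flagged as saturated (``clipped=True``) and
    should be excluded from field estimates.
    """
    x = np.asarray(signal, dtype=np.float64)
    min_n = int(np.ceil(10.0 / f_stim * fs))
    if x.size < min_n:
        raise ValueError(
            f"need >= 10 stimulation periods ({min_n} samples), got {x.size}"
        )
    lo, hi = x.min(), x.max()
    span = hi - lo
    if span <= 0:
        clip_frac = 0.0
    else:
        at_edge = (x >= hi - 1e-9 * max(abs(hi), 1.0)) | \
                  (x <= lo + 1e-9 * max(abs(lo), 1.0))
        clip_frac = float(at_edge.mean())
    t = np.arange(x.size) / fs
    design = np.column_stack([
        np.ones_like(t),
        np.cos(2 * np.pi * f_stim * t),
        np.sin(2 * np.pi * f_stim * t),
    ])
    coef, _, _, _ = np.linalg.lstsq(design, x, rcond=None)
    a, b = coef[1], coef[2]
    return StimVoltage(
        amplitude_uv=float(np.hypot(a, b)),
        phase_deg=float(wrap_degrees(np.degrees(np.arctan2(b, a)))),
        clipped=clip_frac > clip_threshold,
        clip_fraction=clip_frac,
    )


def projected_field(voltages: dict, geometry: ElectrodeArray,
                    stim_current_ma: float = 1.0,
                    reference_phase_deg: float | None = None) -> pd.DataFrame:
    """Projected electric field for each electrode and its nearest neighbour.

    Parameters
    ----------
    voltages : dict of electrode id -> StimVoltage (or amplitude in uV)
        Fitted stimulation voltages.  Clipped electrodes are skipped.
    geometry : ElectrodeArray
    stim_current_ma : float
        Stimulation current the voltages were measured at; fields are
        scaled to 1 mA.
    reference_phase_deg : float, optional
        Stimulation phase reference used to sign the amplitudes: electrodes
        within 90 degrees of the reference count positive, anti-phase
        electrodes negative, so anti-phase neighbours produce summed
        differences.  Defaults to the phase of the largest-amplitude
        electrode.

    Each electrode is paired with its closest same-array neighbour within
    the kind-specific vicinity (10 mm for grids/strips, 5 mm for depth);
    electrodes without a neighbour in the vicinity are omitted with a log
    entry.  Field magnitude = |delta V| / distance in V/m at 1 mA.
    """
    if stim_current_ma <= 0:
        raise ValueError("stim_current_ma must be positive")

    def _amp_phase(v):
        if isinstance(v, StimVoltage):
            return v.amplitude_uv, v.phase_deg, v.clipped
        return float(v), 0.0, False

    usable = {}
    for eid, v in voltages.items():
        amp, ph, clipped = _amp_phase(v)
        if clipped:
            logger.info("electrode %s excluded: amplifier saturation", eid)
            continue
        usable[eid] = (amp, ph)
    columns = ["electrode", "neighbor", "distance_mm", "amplitude_uv",
               "neighbor_amplitude_uv", "field_v_per_m"]
    if not usable:
        return pd.DataFrame(columns=columns)

    if reference_phase_deg is None:
        strongest = max(usable, key=lambda e: usable[e][0])
        reference_phase_deg = usable[strongest][1]

    def _signed(amp, ph):
        dphi = abs(wrap_degrees(ph - reference_phase_deg))
        return amp if dphi <= 90.0 else -amp

    pos = geometry.positions()
    meta = {row.id: (row.kind, row.array) for row in geometry.df.itertuples()}
    rows = []
    for eid, (amp, ph) in usable.items():
        if eid not in pos:
            raise ValueError(f"electrode {eid} missing from geometry")
        kind, array_id = meta[eid]
        vicinity = VICINITY_MM[kind]
        best, best_d = None, np.inf
        for other, (oamp, oph) in usable.items():
            if other == eid or meta[other][1] != array_id:
                continue
            d = float(np.linalg.norm(pos[eid] - pos[other]))
            if d <= vicinity + 1e-9 and d < best_d:
                best, best_d = other, d
        if best is None:
            logger.info("electrode %s omitted: no neighbor within %.0f mm",
                        eid, vicinity)
            continue
        dv_uv = _signed(amp, ph) - _signed(*usable[best])
        # uV over mm -> V/m carries a factor 1e-3; normalise to 1 mA
        field = abs(dv_uv) / best_d * 1e-3 / stim_current_ma
        rows.append({
            "electrode": eid,
            "neighbor": best,
            "distance_mm": best_d,
            "amplitude_uv": amp,
            "neighbor_amplitude_uv": usable[best][0],
            "field_v_per_m": field,
        })
    return pd.DataFrame(rows, columns=columns)


def field_summary(fields: pd.DataFrame) -> dict:
    """Median and 5-95% range of the projected fields (report helper)."""
    v = fields["field_v_per_m"].to_numpy(dtype=float)
    if v.size == 0:
        return {"n": 0, "median": np.nan, "p5": np.nan, "p95": np.nan,
                "min": np.nan, "max": np.nan}
    return {
        "n": int(v.size),
        "median": float(np.median(v)),
        "p5": float(np.percentile(v, 5)),
        "p95": float(np.percentile(v, 95)),
        "min": float(v.min()),
        "max": float(v.max()),
    }
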