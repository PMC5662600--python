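"""Harmonic model of the tACS stimulation artifact.

During sinusoidal transcranial stimulation the subdural recordings are
dominated by the stimulation waveform, typically more than ten-fold larger
than the neural signal, together with harmonic distortion from amplifier
nonlinearities.  The artifact is modelled per channel and per stimulation
block as a linear superposition of sines and cosines at multiples of a base
frequency (harmonics up to 40 Hz), with the base frequency itself refined by
a bounded 1-D search.  The fitted fundamental also serves as the stimulation
phase reference: 0 degrees at the positive (anodal) peak.

Trapezoidal stimulation waveforms generate broadband artifacts that this
model cannot represent; fitting them is refused outright.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .spectral import wrap_degrees

__all__ = [
    "HarmonicFitModel",
    "TrapezoidalWaveformError",
    "fit_harmonic_artifact",
    "subtract_artifact",
    "stimulation_phase",
]

MAX_HARMONIC_HZ = 40.0
# residual-variance ratio above which artifact removal is considered poor
POOR_REMOVAL_THRESHOLD = 0.2


class TrapezoidalWaveformError(ValueError):
    """Raised when a harmonic fit is requested for trapezoidal stimulation."""


@dataclass
class HarmonicFitModel:
    """Fitted harmonic artifact: base frequency plus per-harmonic coefficients.

    The reconstruction is ``dc + sum_k a_k cos(2 pi k f0 t) + b_k sin(...)``
    for ``k = 1..K`` with ``K = floor(40 / f0)``; it is periodic with period
    ``1/f0``.
    """

    f0: float
    a: np.ndarray             # cosine coefficients, uV, k = 1..K
    b: np.ndarray             # sine coefficients, uV
    dc: float
    fs: float
    residual_ratio: float = np.nan   # residual variance / total variance
    converged: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    @staticmethod
    def harmonic_count(f0: float) -> int:
        """floor(40/f0), robust to f0 sitting within the frequency-search
        tolerance above an integer divisor."""
        return int(np.floor(MAX_HARMONIC_HZ / f0 + 1e-5))

    @property
    def fundamental_amplitude(self) -> float:
        return float(np.hypot(self.a[0], self.b[0]))

    @property
    def poor_removal(self) -> bool:
        return bool(self.residual_ratio > POOR_REMOVAL_THRESHOLD)

    def reconstruct(self, n_samples: int | None = None,
                    t=None) -> np.ndarray:
        """Evaluate the fitted artifact at sample times (seconds)."""
        if t is None:
            if n_samples is None:
                raise ValueError("provide n_samples or t")
            t = np.arange(n_samples) / self.fs
        t = np.asarray(t, dtype=np.float64)
        k = np.arange(1, self.n_harmonics + 1)
        arg = 2.0 * np.pi * self.f0 * k[:, None] * t[None, :]
        return (self.dc
                + self.a @ np.cos(arg)
                + self.b @ np.sin(arg))

    def to_json(self, path=None) -> str:
        payload = {
            "f0": self.f0,
            "a": list(map(float, self.a)),
            "b": list(map(float, self.b)),
            "dc": self.dc,
            "fs": self.fs,
            "residual_ratio": self.residual_ratio,
            "converged": self.converged,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "HarmonicFitModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as f:
                payload = json.load(f)
        payload["a"] = np.asarray(payload["a"], dtype=float)
        payload["b"] = np.asarray(payload["b"], dtype=float)
        return cls(**payload)


def _design_matrix(t: np.ndarray, f0: float) -> np.ndarray:
    n_harm = HarmonicFitModel.harmonic_count(f0)
    k = np.arange(1, n_harm + 1)
    arg = 2.0 * np.pi * f0 * np.outer(t, k)
    return np.column_stack([np.ones_like(t), np.cos(arg), np.sin(arg)])


def _lstsq_at(x: np.ndarray, t: np.ndarray, f0: float):
    design = _design_matrix(t, f0)
    coef, _, _, _ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    return coef, float(np.mean(resid ** 2))


def fit_harmonic_artifact(signal, fs: float, f0_init: float,
                          search_frac: float = 0.01,
                          stim_waveform: str = "sine") -> HarmonicFitModel:
    """Fit the harmonic artifact model to one channel of one block.

    The sine/cosine amplitudes are solved by linear least squares; the base
    frequency is refined by a bounded derivative-free 1-D minimisation of the
    residual variance over ``f0_init * (1 +/- search_frac)``.  If the search
    does not converge the fit falls back to ``f0_init`` with
    ``converged=False``.
    """
    if stim_waveform.lower() in ("trapezoid", "trapezoidal"):
        raise TrapezoidalWaveformError(
            "trapezoidal stimulation blocks generate broadband artifacts and "
            "cannot be fit with a harmonic series; analyse the stimulation-"
            "free intervals instead"
        )
    x = np.asarray(signal, dtype=np.float64)
    min_n = int(np.ceil(10.0 / f0_init * fs))
    if x.size < min_n:
        raise ValueError(
            f"signal of {x.size} samples is shorter than 10 periods of "
            f"f0={f0_init} Hz ({min_n} samples at fs={fs})"
        )
    t = np.arange(x.size) / fs
    total_var = float(np.mean((x - x.mean()) ** 2))

    # the f0 search only needs a cheap objective: evaluate the residual on a
    # strided subset (still sampling above 4x the highest harmonic), then
    # solve the final coefficients on every sample
    stride = max(1, int(fs // (4.0 * MAX_HARMONIC_HZ)))
    xs, ts = x[::stride], t[::stride]
    lo, hi = f0_init * (1.0 - search_frac), f0_init * (1.0 + search_frac)
    result = minimize_scalar(
        lambda f0: _lstsq_at(xs, ts, f0)[1],
        bounds=(lo, hi), method="bounded",
        options={"xatol": f0_init * 1e-7},
    )
    if result.success:
        f0 = float(result.x)
        converged = True
    else:
        f0 = float(f0_init)
        converged = False
    coef, resid_var = _lstsq_at(x, t, f0)
    n_harm = HarmonicFitModel.harmonic_count(f0)
    return HarmonicFitModel(
        f0=f0,
        a=coef[1:1 + n_harm].copy(),
        b=coef[1 + n_harm:].copy(),
        dc=float(coef[0]),
        fs=fs,
        residual_ratio=resid_var / total_var if total_var > 0 else np.nan,
        converged=converged,
        meta={"f0_init": f0_init, "search_frac": search_frac},
    )


def subtract_artifact(signal, model: HarmonicFitModel) -> np.ndarray:
    """Residual after removing the fitted harmonic artifact."""
    x = np.asarray(signal, dtype=np.float64)
    return x - model.reconstruct(n_samples=x.size)


def stimulation_phase(model: HarmonicFitModel, t) -> np.ndarray:
    """Phase of the fitted fundamental at times ``t`` (seconds), in degrees.

    0 degrees at the positive peak of the fundamental (anodal peak),
    increasing with time, wrapped to (-180, 180].
    """
    if model.fundamental_amplitude <= 0 or not np.isfinite(
            model.fundamental_amplitude):
        raise ValueError("fundamental amplitude is zero: no phase reference")
    t = np.asarray(t, dtype=np.float64)
    # a1 cos(th) + b1 sin(th) = A cos(th - phi0), phi0 = atan2(b1, a1)
    phi0 = np.degrees(np.arctan2(model.b[0], model.a[0]))
    return wrap_degrees(360.0 * model.f0 * t - phi0)
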