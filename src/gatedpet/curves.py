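"""Core time--volume-curve containers.

The left-ventricular time--volume curve V(t) is represented as a truncated
Fourier series (a trigonometric polynomial) over one cardiac cycle:

    V(t) = a0 + sum_{k=1}^{K} [ a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T) ]

which makes V periodic and infinitely differentiable, with the exact
analytic derivative available in closed form.  A band-limited curve with
K <= 7 harmonics is information-complete under 16-gate sampling (Nyquist),
so round-trip recovery tests can be exact.

Two containers live here:

``ContinuousVolumeCurve``
    The analytic curve, used both as phantom ground truth and as the result
    of the Fourier fit to gated samples.

``VolumeCurve``
    Discrete gate samples (midpoint times + volumes) within one period --
    what the segmentation stage produces and the curve-analysis stage
    consumes.

``CardiacFunctionResult`` carries the per-subject functional parameters
(EDV, ESV, SV, EF, PFR, 1/3MFR, TPFR, HR) in the units conventional in
gated cardiac imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import DataError

__all__ = [
    "ContinuousVolumeCurve",
    "VolumeCurve",
    "CardiacFunctionResult",
]


@dataclass(frozen=True)
class ContinuousVolumeCurve:
    """Band-limited periodic volume curve with analytic derivative.

    Parameters
    ----------
    period : float
        Cardiac cycle length, seconds.
    dc : float
        Mean volume coefficient a0, microliters.
    harmonics : tuple of (float, float)
        (cosine, sine) coefficient pairs (a_k, b_k), microliters, for
        k = 1 .. K.
    """

    period: float
    dc: float
    harmonics: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.period) or self.period <= 0:
            raise DataError(f"period must be positive, got {self.period}")
        object.__setattr__(self, "harmonics",
                           tuple((float(a), float(b)) for a, b in self.harmonics))

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    def _angles(self, t):
        t = np.asarray(t, dtype=float)
        k = np.arange(1, self.n_harmonics + 1)
        return 2.0 * np.pi * np.multiply.outer(t, k) / self.period  # (..., K)

    def volume(self, t):
        """V(t) in microliters; vectorized over t."""
        t = np.asarray(t, dtype=float)
        if self.n_harmonics == 0:
            return np.broadcast_to(self.dc, t.shape).copy() if t.ndim else float(self.dc)
        ang = self._angles(t)
        ab = np.asarray(self.harmonics)  # (K, 2)
        out = self.dc + np.cos(ang) @ ab[:, 0] + np.sin(ang) @ ab[:, 1]
        return float(out) if t.ndim == 0 else out

    def dvdt(self, t):
        """Exact analytic dV/dt(t) in microliters per second."""
        t = np.asarray(t, dtype=float)
        if self.n_harmonics == 0:
            return np.zeros(t.shape) if t.ndim else 0.0
        ang = self._angles(t)
        ab = np.asarray(self.harmonics)
        k = np.arange(1, self.n_harmonics + 1)
        om = 2.0 * np.pi * k / self.period
        out = -np.sin(ang) @ (om * ab[:, 0]) + np.cos(ang) @ (om * ab[:, 1])
        return float(out) if t.ndim == 0 else out

    __call__ = volume

    def shifted(self, dt: float) -> "ContinuousVolumeCurve":
        """Return the same curve with time origin moved so V'(t) = V(t + dt)."""
        k = np.arange(1, self.n_harmonics + 1)
        ph = 2.0 * np.pi * k * dt / self.period
        ab = np.asarray(self.harmonics, dtype=float).reshape(-1, 2)
        a, b = ab[:, 0], ab[:, 1]
        a2 = a * np.cos(ph) + b * np.sin(ph)
        b2 = -a * np.sin(ph) + b * np.cos(ph)
        return ContinuousVolumeCurve(self.period, self.dc, tuple(zip(a2, b2)))

    def window_average(self, t0, t1):
        """Exact time-average of V over [t0, t1] (closed form).

        Vectorized over matching arrays t0, t1.
        """
        t0 = np.asarray(t0, dtype=float)
        t1 = np.asarray(t1, dtype=float)
        w = t1 - t0
        if np.any(w <= 0):
            raise DataError("window_average requires t1 > t0")
        out = np.broadcast_to(self.dc, np.broadcast_shapes(t0.shape, t1.shape)).astype(float).copy() \
            if t0.ndim or t1.ndim else self.dc
        acc = out
        for k, (a, b) in enumerate(self.harmonics, start=1):
            om = 2.0 * np.pi * k / self.period
            acc = acc + (a * (np.sin(om * t1) - np.sin(om * t0))
                         - b * (np.cos(om * t1) - np.cos(om * t0))) / (om * w)
        return float(acc) if (t0.ndim == 0 and t1.ndim == 0) else acc


@dataclass
class VolumeCurve:
    """Sampled gated volume curve: gate midpoint times + volumes, one period."""

    gate_times: np.ndarray  # s, strictly increasing, within one period
    volumes: np.ndarray     # µL
    period: float           # s

    def __post_init__(self):
        self.gate_times = np.asarray(self.gate_times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.gate_times.shape != self.volumes.shape or self.gate_times.ndim != 1:
            raise DataError("gate_times and volumes must be matching 1-D arrays")
        if self.period <= 0:
            raise DataError("period must be positive")
        if np.any(np.diff(self.gate_times) <= 0):
            raise DataError("gate_times must be strictly increasing")
        if self.gate_times[-1] - self.gate_times[0] >= self.period:
            raise DataError("gate_times must span less than one period")

    @property
    def n_gates(self) -> int:
        return len(self.gate_times)


@dataclass
class CardiacFunctionResult:
    """Left-ventricular functional parameters for one subject.

    Units: volumes µL, EF %, PFR and 1/3MFR in EDV/s (dV/dt normalized by
    EDV), TPFR ms, HR bpm, phases s within the cycle.
    """

    edv: float
    esv: float
    stroke_volume: float
    ef: float
    pfr: float
    third_mfr: float
    tpfr: float
    hr: float
    ed_phase: float = 0.0
    es_phase: float = 0.0
    extras: dict = field(default_factory=dict)

    PARAMETERS = ("edv", "esv", "stroke_volume", "ef", "pfr", "third_mfr", "tpfr", "hr")

    def validate(self):
        """Check the type invariants; raise DataError on violation."""
        if not (0.0 <= self.ef <= 100.0):
            raise DataError(f"EF out of range: {self.ef}")
        if self.edv < self.esv:
            raise DataError("EDV must be >= ESV")
        if self.pfr < self.third_mfr - 1e-9 * max(abs(self.pfr), 1.0):
            raise DataError("PFR must dominate 1/3MFR")
        if self.tpfr <= 0:
            raise DataError("TPFR must be positive")
        return self

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("extras")
        return d
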