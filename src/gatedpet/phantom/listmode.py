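"""Idealized list-mode acquisition: event and ECG trigger stream simulation.

Stand-in for a list-mode PET acquisition with ECG recording: annihilation
events are deposited directly in image space (no sinogram, reconstruction
or physics corrections) as an inhomogeneous Poisson process whose spatial
density at time t is the phantom activity map at the instantaneous cavity
volume V(phase(t)).  R-R intervals are Gaussian with configurable jitter,
truncated below at half the mean interval (a simple, controllable
arrhythmia surrogate for beat-rejection tests).

All randomness flows from one explicit seed per call; repeated calls with
the same seed are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from ..curves import ContinuousVolumeCurve
from ..errors import DataError
from .geometry import PhantomConfig, voxelize_frame

__all__ = ["TriggerStream", "EventStream", "simulate_triggers", "simulate_listmode"]


@dataclass
class TriggerStream:
    """R-wave trigger times, seconds, strictly increasing."""

    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise DataError("trigger times must be 1-D")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise DataError("trigger times must be strictly increasing")

    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.times)

    def __len__(self):
        return len(self.times)


@dataclass
class EventStream:
    """Time-stamped idealized annihilation events with mm positions."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        arrs = [np.asarray(a, dtype=float) for a in (self.t, self.x, self.y, self.z)]
        n = len(arrs[0])
        if any(a.ndim != 1 or len(a) != n for a in arrs):
            raise DataError("event stream columns must be equal-length 1-D arrays")
        if not all(np.all(np.isfinite(a)) for a in arrs[1:]):
            raise DataError("event coordinates must be finite")
        self.t, self.x, self.y, self.z = arrs

    def positions(self) -> np.ndarray:
        return np.stack([self.x, self.y, self.z], axis=1)

    def __len__(self):
        return len(self.t)


def simulate_triggers(mean_hr: float, duration_s: float,
                      rr_jitter_sd: float = 0.0, seed: int = 0) -> TriggerStream:
    """Cumulative R-R intervals: Gaussian(60/HR, sd), truncated at half mean."""
    if mean_hr <= 0 or duration_s <= 0:
        raise DataError("mean_hr and duration_s must be positive")
    rng = np.random.default_rng(seed)
    mean_rr = 60.0 / mean_hr
    n_guess = int(duration_s / mean_rr * 1.5) + 10
    times = [0.0]
    t = 0.0
    while t <= duration_s:
        draws = rng.normal(mean_rr, rr_jitter_sd, size=n_guess) \
            if rr_jitter_sd > 0 else np.full(n_guess, mean_rr)
        for rr in draws:
            if rr < 0.5 * mean_rr:       # truncation: redraw implicitly
                continue
            t += rr
            times.append(t)
            if t > duration_s:
                break
    return TriggerStream(np.asarray(times))


def simulate_listmode(config: PhantomConfig, curve: ContinuousVolumeCurve,
                      duration_s: float, mean_hr: float,
                      rr_jitter_sd: float = 0.0, seed: int = 0,
                      n_phase_maps: int = 32,
                      ) -> Tuple[EventStream, TriggerStream]:
    """Simulate an ECG-recorded list-mode acquisition of the beating phantom.

    ``config.total_counts`` is the expected number of recorded events over
    ``duration_s``; the per-phase intensity is proportional to the total
    activity of the phantom at that phase (the myocardial volume varies
    slightly over the cycle, so the count rate does too).  Events before
    the first or after the last trigger are not generated (the gating
    stage would discard them).
    """
    mean_rr = 60.0 / mean_hr
    if duration_s < 10 * mean_rr:
        raise DataError("duration must cover at least 10 cardiac cycles")
    rng = np.random.default_rng(seed)
    triggers = simulate_triggers(mean_hr, duration_s, rr_jitter_sd,
                                 seed=rng.integers(2 ** 31))

    # per-phase activity maps at bin-centre phases of the ground-truth curve
    P = n_phase_maps
    phases = (np.arange(P) + 0.5) / P
    maps = []
    for ph in phases:
        frame = voxelize_frame(config, float(curve.volume(ph * curve.period)))
        maps.append(frame.activity.ravel())
    maps = np.asarray(maps)                      # (P, nvox)
    lam = maps.sum(axis=1)                       # relative intensity per phase
    scale = config.total_counts / (duration_s * lam.mean())

    rr = triggers.rr_intervals()                 # (nbeats,)
    t0 = triggers.times[:-1]
    # expected counts per (beat, phase bin)
    expected = scale * np.multiply.outer(rr / P, lam)     # (nbeats, P)
    counts = rng.poisson(expected)

    o = config.grid_origin()
    vs = config.voxel_size
    shape = config.grid_shape
    ts, xs, ys, zs = [], [], [], []
    for b in range(P):
        n_b = int(counts[:, b].sum())
        if n_b == 0:
            continue
        p = maps[b] / maps[b].sum()
        flat = rng.choice(len(p), size=n_b, p=p)
        ix, iy, iz = np.unravel_index(flat, shape)
        jit = rng.random((n_b, 3))
        xs.append(o[0] + (ix + jit[:, 0]) * vs)
        ys.append(o[1] + (iy + jit[:, 1]) * vs)
        zs.append(o[2] + (iz + jit[:, 2]) * vs)
        # times: uniform within each beat's phase-bin window
        beat_idx = np.repeat(np.arange(len(rr)), counts[:, b])
        u = rng.random(n_b)
        ts.append(t0[beat_idx] + (b + u) * rr[beat_idx] / P)
    if ts:
        t = np.concatenate(ts)
        order = np.argsort(t, kind="stable")
        events = EventStream(t[order], np.concatenate(xs)[order],
                             np.concatenate(ys)[order], np.concatenate(zs)[order])
    else:
        events = EventStream(np.array([]), np.array([]), np.array([]), np.array([]))
    return events, triggers
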