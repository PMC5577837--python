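"""Prey-encounter-event (PEE) detection from 5 Hz tri-axial acceleration.

Rapid head/body jerks during prey capture attempts leave a broadband,
high-frequency signature on all three acceleration axes.  The detector:

1. extracts dynamic acceleration per axis with a zero-phase order-3
   high-pass Butterworth filter (cut-off 2.4 Hz at 5 Hz sampling, i.e. a
   normalized cut-off of 0.96 of Nyquist);
2. summarises each axis with the SD over non-overlapping 1 s windows,
   then a centered 5 s moving SD of that series;
3. splits each axis's summary into a "high" and a "low" state with an
   exact deterministic two-means clustering;
4. declares a PEE wherever all three axes are simultaneously in the high
   state, merging any continuous succession of high-state seconds into a
   single event.

Events carry no prey identity -- they are capture *attempts* inferred from
movement alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PeeEvent",
    "dynamic_acceleration",
    "two_means_states",
    "state_signal",
    "detect_pee",
]

FS = 5.0  # Hz
HIGHPASS_CUTOFF_HZ = 2.4


@dataclass(frozen=True)
class PeeEvent:
    """One prey encounter event on the 1 Hz clock (seconds, inclusive)."""

    start_time: float
    end_time: float
    dive_id: int = -1
    in_bottom: bool = False

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_time + self.end_time)


def dynamic_acceleration(accel_xyz: np.ndarray, fs: float = FS) -> np.ndarray:
    """High-frequency (dynamic) component of tri-axial acceleration.

    Zero-phase (forward-backward) order-3 Butterworth high-pass with a
    cut-off of 2.4 Hz; DC and slow gravity content are rejected.
    """
    a = np.atleast_2d(np.asarray(accel_xyz, float))
    if a.shape[0] == 1 and a.ndim == 2 and np.asarray(accel_xyz).ndim == 1:
        a = a.T
    n = a.shape[0]
    sos = signal.butter(3, HIGHPASS_CUTOFF_HZ / (fs / 2.0), btype="highpass", output="sos")
    # forward-backward filtering needs several filter lengths of warm-up
    if n < 16:
        raise ValueError(
            f"series shorter than filter warm-up ({n} samples at {fs:g} Hz)"
        )
    return signal.sosfiltfilt(sos, a, axis=0)


def two_means_states(x: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D two-means clustering; True marks the high cluster.

    Centers start at the 10th/90th percentiles and Lloyd iterations run to
    convergence (at most ``max_iter``).  A near-degenerate series (range
    below 1e-6) is all low state: with no variance structure there is
    nothing to cluster.
    """
    x = np.asarray(x, float)
    finite = np.isfinite(x)
    out = np.zeros(x.shape, dtype=bool)
    xv = x[finite]
    if xv.size == 0 or np.ptp(xv) < 1e-6:
        return out
    lo, hi = np.percentile(xv, [10.0, 90.0])
    if hi - lo < 1e-12:
        lo, hi = xv.min(), xv.max()
    for _ in range(max_iter):
        assign = np.abs(xv - hi) < np.abs(xv - lo)
        if not assign.any() or assign.all():
            break
        new_lo, new_hi = xv[~assign].mean(), xv[assign].mean()
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    out[finite] = np.abs(xv - hi) < np.abs(xv - lo)
    return out


def state_signal(dyn: np.ndarray, fs: float = FS) -> np.ndarray:
    """1 Hz binary high/low state series for one dynamic-acceleration axis.

    The SD over fixed non-overlapping 1 s windows downsamples the signal
    to 1 Hz; a centered 5 s moving standard deviation of the dynamic
    signal -- pooled from the per-second SDs -- then gives a smooth
    jerk-energy envelope, and a deterministic two-means split labels the
    cluster with the larger mean as "high".  Pooling (rather than taking
    the SD of the SD series) keeps the feature an amplitude envelope, so
    one capture burst produces one contiguous high run rather than a
    double-fire on the rising and falling flanks.
    """
    dyn = np.asarray(dyn, float)
    n_sec = len(dyn) // int(fs)
    if n_sec < 1:
        raise ValueError("need at least 1 s of data")
    blocks = dyn[: n_sec * int(fs)].reshape(n_sec, int(fs))
    sd1 = blocks.std(axis=1, ddof=1)
    sd5 = np.sqrt(
        pd.Series(sd1**2)
        .rolling(window=5, center=True, min_periods=2)
        .mean()
        .to_numpy()
    )
    return two_means_states(sd5)


def detect_pee(states_xyz: np.ndarray | list[np.ndarray]) -> list[PeeEvent]:
    """Events where all three axes are simultaneously in the high state.

    A continuous succession of high-state seconds is merged into a single
    event; ``start_time``/``end_time`` are the first and last second of
    the run (1 Hz clock).
    """
    states = [np.asarray(s, bool) for s in states_xyz]
    if len(states) != 3:
        raise ValueError("expected exactly three axis state series")
    n = len(states[0])
    if any(len(s) != n for s in states):
        raise ValueError("axis state series have mismatched lengths")
    conj = states[0] & states[1] & states[2]
    if not conj.any():
        return []
    edges = np.flatnonzero(np.diff(conj.astype(np.int8)))
    starts = np.r_[0 if conj[0] else [], edges[~conj[edges]] + 1].astype(int)
    ends = np.r_[edges[conj[edges]], n - 1 if conj[-1] else []].astype(int)
    return [PeeEvent(start_time=float(a), end_time=float(b)) for a, b in zip(starts, ends)]


def assign_events_to_dives(events: list[PeeEvent], dives) -> list[PeeEvent]:
    """Attach dive ids and bottom-phase membership (by event midpoint)."""
    out = []
    for ev in events:
        dive_id, in_bottom = -1, False
        for d in dives:
            if d.start <= ev.midpoint <= d.end:
                dive_id = d.dive_id
                in_bottom = d.descent_end >= 0 and (
                    d.descent_end <= ev.midpoint <= d.ascent_start
                )
                break
        out.append(
            PeeEvent(ev.start_time, ev.end_time, dive_id=dive_id, in_bottom=bool(in_bottom))
        )
    return out
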