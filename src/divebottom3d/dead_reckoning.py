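"""Dead-reckoning 3D path reconstruction with GPS closure.

The underwater path is integrated at 1 Hz by summing velocity vectors
derived from heading, pitch and swim speed, assuming the animal moves
along its longitudinal axis.  The vertical coordinate is always taken
from pressure depth -- a direct measurement -- rather than from the
integrated pitch/speed component.  Because the integration is blind to
water currents and accumulates sensor error, the raw track is then closed
onto the GPS fix following the dive by a correction that grows linearly in
time: the effect of a constant-velocity current over the dive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attitude_and_speed import AttitudeSeries, SpeedSeries

__all__ = ["Track3D", "integrate_path", "close_track"]

MAX_SPEED_GAP_S = 5


@dataclass
class Track3D:
    """1 Hz positions (east, north, z) in the local metric frame.

    ``z = -depth``.  ``times`` are seconds on the deployment clock.
    ``correction_velocity`` is the constant current (east, north) applied
    by :func:`close_track`; ``closed`` is False for tracks kept uncorrected
    because no closing fix was available.
    """

    times: np.ndarray
    positions: np.ndarray  # (n, 3)
    anchor_xy: np.ndarray
    closing_xy: np.ndarray | None = None
    correction_velocity: np.ndarray = field(
        default_factory=lambda: np.zeros(2)
    )
    closed: bool = False

    def __len__(self) -> int:
        return len(self.times)

    @property
    def path_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.positions, axis=0), axis=1).sum())


def _fill_speed(speed: np.ndarray, max_gap: int = MAX_SPEED_GAP_S) -> np.ndarray:
    """Linearly interpolate NaN gaps of at most ``max_gap`` samples."""
    v = np.asarray(speed, float).copy()
    bad = ~np.isfinite(v)
    if not bad.any():
        return v
    if bad.all():
        raise ValueError("no finite speed samples in dive")
    # reject if any gap longer than max_gap
    idx = np.flatnonzero(bad)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        interior = (run[0] > 0) and (run[-1] < len(v) - 1)
        if interior and len(run) > max_gap:
            raise ValueError(f"speed gap of {len(run)} s exceeds {max_gap} s")
    good = np.flatnonzero(~bad)
    v[bad] = np.interp(np.flatnonzero(bad), good, v[good])
    return v


def integrate_path(
    attitude: AttitudeSeries,
    speed: SpeedSeries | np.ndarray,
    depth: np.ndarray,
    anchor_xy: np.ndarray,
    times: np.ndarray | None = None,
) -> Track3D:
    """Integrate heading/pitch/speed into an uncorrected 1 Hz track.

    The horizontal step over second ``t`` uses the left-endpoint attitude
    and speed: ``v * cos(alpha) * (sin(psi), cos(psi))``.  The vertical
    coordinate is overwritten with ``-depth`` at every sample.  NaN speed
    gaps up to 5 s are linearly interpolated; longer interior gaps reject
    the dive.
    """
    depth = np.asarray(depth, float)
    n = len(depth)
    if len(attitude) != n:
        raise ValueError("attitude and depth must have equal length")
    v = speed.speed if isinstance(speed, SpeedSeries) else np.asarray(speed, float)
    if len(v) != n:
        raise ValueError("speed and depth must have equal length")
    v = _fill_speed(v)
    if times is None:
        times = np.arange(n, dtype=float)
    ca = np.cos(attitude.pitch[:-1])
    psi = attitude.heading[:-1]
    if np.isnan(psi).any():
        raise ValueError("heading contains NaN inside the dive")
    step = v[:-1] * ca
    de = step * np.sin(psi)
    dn = step * np.cos(psi)
    east = anchor_xy[0] + np.r_[0.0, np.cumsum(de)]
    north = anchor_xy[1] + np.r_[0.0, np.cumsum(dn)]
    positions = np.column_stack([east, north, -depth])
    return Track3D(
        times=np.asarray(times, float),
        positions=positions,
        anchor_xy=np.asarray(anchor_xy, float),
    )


def close_track(track: Track3D, closing_xy: np.ndarray | None) -> Track3D:
    """Close the track onto the post-dive GPS fix.

    The horizontal mismatch between the raw endpoint and the closing fix,
    divided by elapsed time, gives a constant ``correction_velocity``;
    every position is shifted by ``correction_velocity * (t - t0)``.  The
    vertical coordinate is untouched.  With no closing fix the track is
    returned unchanged and flagged unclosed.
    """
    if closing_xy is None:
        track.closed = False
        return track
    closing_xy = np.asarray(closing_xy, float)
    t = track.times - track.times[0]
    elapsed = t[-1]
    if elapsed <= 0:
        raise ValueError("track must span positive time")
    offset = closing_xy - track.positions[-1, :2]
    vel = offset / elapsed
    track.positions = track.positions.copy()
    track.positions[:, 0] += vel[0] * t
    track.positions[:, 1] += vel[1] * t
    track.correction_velocity = vel
    track.closing_xy = closing_xy
    track.closed = True
    return track
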