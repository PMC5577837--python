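"""Body attitude and swim-speed estimation from tag sensors.

Conventions (fixed package-wide):

* World frame is local East-North-Up (ENU); ``z = -depth``.
* Body frame: ``x1`` longitudinal (forward), ``x2`` lateral (right),
  ``x3`` dorsoventral (up through the back).
* Pitch ``alpha`` is positive nose-up, ``|alpha| <= pi/2``.
* Roll ``phi`` is positive right-side-down.
* Heading ``psi`` is clockwise from magnetic north, in ``[0, 2*pi)``.
* The static accelerometer channel reads ``+1 g`` on the dorsal axis when
  the animal is level: ``s_body = g * (sin(alpha), -sin(phi) cos(alpha),
  cos(phi) cos(alpha))``.

The static (gravity) and slow magnetic components are isolated with a
zero-phase order-3 Butterworth low-pass at 0.20 Hz (5 Hz sampling), the
standard choice for stroking rates well above 0.2 Hz.  Swim speed comes
from the vertical rate and pitch in descent/ascent (``v = v_z /
sin(alpha)``) and from a calibrated flow-noise relationship elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

G = 9.81  # m s^-2

__all__ = [
    "AttitudeSeries",
    "SpeedSeries",
    "CalibrationError",
    "NoiseSpeedCalibration",
    "rotation_body_to_world",
    "render_static_acceleration",
    "render_magnetics",
    "static_acceleration",
    "pitch_roll",
    "tilt_compensated_heading",
    "speed_from_pitch",
    "calibrate_noise_speed",
]


@dataclass
class AttitudeSeries:
    """Pitch/roll/heading time series (radians).

    ``heading`` may be NaN where not yet computed (or indeterminate, e.g.
    magnetic vector parallel to gravity).
    """

    pitch: np.ndarray
    roll: np.ndarray
    heading: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.pitch = np.asarray(self.pitch, float)
        self.roll = np.asarray(self.roll, float)
        if self.heading is None:
            self.heading = np.full_like(self.pitch, np.nan)
        else:
            self.heading = np.asarray(self.heading, float)
        if not (len(self.pitch) == len(self.roll) == len(self.heading)):
            raise ValueError("pitch, roll, heading must have equal length")

    def __len__(self) -> int:
        return len(self.pitch)


@dataclass
class SpeedSeries:
    """Swim speed (m/s, >= 0) with a per-sample provenance flag.

    ``source`` codes: ``'pitch'`` (vertical rate / sin(pitch)),
    ``'noise'`` (flow-noise calibration), ``'none'`` (missing).
    """

    speed: np.ndarray
    source: np.ndarray

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, float)
        self.source = np.asarray(self.source)
        if len(self.speed) != len(self.source):
            raise ValueError("speed and source must have equal length")

    def __len__(self) -> int:
        return len(self.speed)


# ---------------------------------------------------------------------------
# Rotations and forward rendering (shared with the simulator)
# ---------------------------------------------------------------------------

def rotation_body_to_world(
    pitch: np.ndarray, roll: np.ndarray, heading: np.ndarray
) -> np.ndarray:
    """Rotation matrices mapping body-frame vectors into the ENU world frame.

    Returns an array of shape ``(..., 3, 3)`` whose columns are the body
    axes (forward, right, dorsal) expressed in world coordinates.
    """
    pitch, roll, heading = np.broadcast_arrays(
        np.asarray(pitch, float), np.asarray(roll, float), np.asarray(heading, float)
    )
    sa, ca = np.sin(pitch), np.cos(pitch)
    sf, cf = np.sin(roll), np.cos(roll)
    sh, ch = np.sin(heading), np.cos(heading)
    # forward axis
    b1 = np.stack([ca * sh, ca * ch, sa], axis=-1)
    # zero-roll right axis (horizontal) and dorsal axis
    b2_0 = np.stack([ch, -sh, np.zeros_like(ch)], axis=-1)
    b3_0 = np.cross(b2_0, b1)
    # roll about the forward axis, right-side-down positive
    b2 = cf[..., None] * b2_0 - sf[..., None] * b3_0
    b3 = sf[..., None] * b2_0 + cf[..., None] * b3_0
    return np.stack([b1, b2, b3], axis=-1)


def render_static_acceleration(attitude: AttitudeSeries) -> np.ndarray:
    """Noise-free static (gravity) accelerometer signal, shape (n, 3), m/s^2."""
    sa = np.sin(attitude.pitch)
    ca = np.cos(attitude.pitch)
    sf = np.sin(attitude.roll)
    cf = np.cos(attitude.roll)
    return G * np.stack([sa, -sf * ca, cf * ca], axis=-1)


def render_magnetics(attitude: AttitudeSeries, field_world: np.ndarray) -> np.ndarray:
    """Body-frame magnetic signal for a constant world-frame field vector."""
    rot = rotation_body_to_world(attitude.pitch, attitude.roll, attitude.heading)
    # m_body = R^T m_world
    return np.einsum("...ij,...i->...j", rot, np.asarray(field_world, float))


# ---------------------------------------------------------------------------
# Inverse problem: sensors -> attitude
# ---------------------------------------------------------------------------

def _lowpass_sos(cutoff_hz: float = 0.20, fs: float = 5.0):
    return signal.butter(3, cutoff_hz / (fs / 2.0), btype="lowpass", output="sos")


def static_acceleration(
    accel_xyz: np.ndarray, fs: float = 5.0, cutoff_hz: float = 0.20
) -> np.ndarray:
    """Gravity-dominated component of tri-axial acceleration.

    Zero-phase order-3 Butterworth low-pass per axis.  The same routine is
    applied to tri-axial magnetics before heading computation.

    Parameters
    ----------
    accel_xyz : (n, 3) array at ``fs`` Hz; requires >= 30 s of data.
    """
    accel_xyz = np.asarray(accel_xyz, float)
    if accel_xyz.ndim != 2 or accel_xyz.shape[1] != 3:
        raise ValueError("accel_xyz must have shape (n, 3)")
    if accel_xyz.shape[0] < 30 * fs:
        raise ValueError("need at least 30 s of data for static extraction")
    sos = _lowpass_sos(cutoff_hz, fs)
    return signal.sosfiltfilt(sos, accel_xyz, axis=0)


def pitch_roll(static_xyz: np.ndarray) -> AttitudeSeries:
    """Pitch and roll from the static (gravity) acceleration vector.

    Exact on noise-free input.  Zero-norm static vectors yield NaN; in the
    gimbal case (gravity along the longitudinal axis) roll is set to 0 by
    convention.
    """
    s = np.asarray(static_xyz, float)
    norm = np.linalg.norm(s, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pitch = np.arcsin(np.clip(s[..., 0] / norm, -1.0, 1.0))
    roll = np.arctan2(-s[..., 1], s[..., 2])
    gimbal = np.isclose(np.abs(s[..., 0]), norm)
    roll = np.where(gimbal, 0.0, roll)
    bad = ~(norm > 0)
    pitch = np.where(bad, np.nan, pitch)
    roll = np.where(bad, np.nan, roll)
    return AttitudeSeries(pitch=pitch, roll=roll)


def tilt_compensated_heading(
    attitude: AttitudeSeries, static_mag_xyz: np.ndarray, min_horizontal: float = 1e-9
) -> AttitudeSeries:
    """Heading from low-passed magnetics de-rotated by pitch and roll.

    The magnetic vector is rotated into the world frame the animal would
    occupy at heading zero; the heading is then read from the horizontal
    components.  A magnetic vector (anti)parallel to gravity leaves no
    horizontal part and yields NaN.
    """
    m = np.asarray(static_mag_xyz, float)
    rot0 = rotation_body_to_world(
        attitude.pitch, attitude.roll, np.zeros_like(attitude.pitch)
    )
    h = np.einsum("...ij,...j->...i", rot0, m)
    horiz = np.hypot(h[..., 0], h[..., 1])
    heading = np.mod(np.arctan2(-h[..., 0], h[..., 1]), 2 * np.pi)
    heading = np.where(horiz < min_horizontal, np.nan, heading)
    return AttitudeSeries(pitch=attitude.pitch, roll=attitude.roll, heading=heading)


# ---------------------------------------------------------------------------
# Swim speed
# ---------------------------------------------------------------------------

def speed_from_pitch(
    v_z: np.ndarray, alpha: np.ndarray, min_pitch: float = np.deg2rad(20.0)
) -> np.ndarray:
    """Swim speed from vertical rate and pitch: ``v = |v_z / sin(alpha)|``.

    ``v_z`` is the depth rate (m/s, positive down).  Samples with
    ``|alpha| < min_pitch`` are NaN: near-horizontal swimming makes the
    division blow up, which is why the relation is only used in the steep
    descent/ascent phases.
    """
    v_z = np.asarray(v_z, float)
    alpha = np.asarray(alpha, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.abs(v_z / np.sin(alpha))
    return np.where(np.abs(alpha) >= min_pitch, v, np.nan)


class CalibrationError(ValueError):
    """Raised when flow-noise / speed calibration cannot be established."""


@dataclass
class NoiseSpeedCalibration:
    """Fitted flow-noise-level -> swim-speed relationship.

    Model: ``level = intercept + slope * log(speed)``, least squares, so the
    inverse prediction is ``speed = exp((level - intercept) / slope)``
    clipped to ``[v_min, v_max]``.  Flow-noise power grows roughly
    log-linearly with speed over the 0.5-3 m/s range of interest.
    """

    intercept: float
    slope: float
    residual_sd: float
    n_pairs: int
    v_min: float = 0.0
    v_max: float = 3.0

    def predict(self, level: np.ndarray) -> np.ndarray:
        level = np.asarray(level, float)
        with np.errstate(over="ignore"):
            v = np.exp((level - self.intercept) / self.slope)
        return np.clip(v, self.v_min, self.v_max)


def calibrate_noise_speed(
    noise_level: np.ndarray,
    v_seal: np.ndarray,
    min_pairs: int = 100,
    min_speed_range: float = 0.5,
) -> NoiseSpeedCalibration:
    """Calibrate noise level against pitch-derived swim speed.

    Pairs come from descent/ascent samples where both the noise level and
    the pitch-derived speed are finite; the fit is extrapolated to predict
    speed over whole dives (bottom phases included).

    Raises
    ------
    CalibrationError
        Fewer than ``min_pairs`` finite pairs, speed range below
        ``min_speed_range`` m/s, or a degenerate (non-monotone) fit.
    """
    level = np.asarray(noise_level, float)
    v = np.asarray(v_seal, float)
    ok = np.isfinite(level) & np.isfinite(v) & (v > 0)
    level, v = level[ok], v[ok]
    if level.size < min_pairs:
        raise CalibrationError(
            f"only {level.size} usable noise/speed pairs (need {min_pairs})"
        )
    if v.max() - v.min() < min_speed_range:
        raise CalibrationError(
            f"speed range {v.max() - v.min():.3f} m/s too narrow for calibration"
        )
    x = np.log(v)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, level, rcond=None)
    resid = level - design @ coef
    if abs(coef[1]) < 1e-12:
        raise CalibrationError("degenerate (flat) noise/speed relationship")
    if coef[1] < 0:
        warnings.warn("noise level decreases with speed; calibration suspect")
    return NoiseSpeedCalibration(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        residual_sd=float(resid.std(ddof=2)) if resid.size > 2 else 0.0,
        n_pairs=int(level.size),
    )
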