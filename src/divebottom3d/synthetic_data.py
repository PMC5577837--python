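"""Forward simulator: layered prey fields, dive kinematics, tag sensors.

The generator produces one deployment at a time: a sequence of deep
foraging dives to a prey layer, rendered all the way down to the raw tag
streams (1 Hz depth and flow-noise level, 5 Hz tri-axial acceleration and
magnetics, surface GPS fixes) together with a truth bundle so every
downstream stage has a parameter-recovery test.

Model summary
-------------
* Kinematics: the animal swims along its longitudinal axis; per-second
  positions follow the same left-endpoint integration the dead-reckoning
  stage inverts.  Descent/ascent use a steep constant pitch; the bottom
  phase holds the animal inside the prey layer with a proportional
  depth controller plus a smooth random vertical wander, while the heading
  wanders around a per-dive azimuth with a magnitude set by
  ``bottom_linearity`` (1 = perfectly directional).  All attitude profiles
  are smoothed so the sensor content stays well below the 0.20 Hz
  static-extraction cut-off.
* Prey: a Poisson point process of intensity ``prey_intensity`` inside the
  layer slab, realized lazily in the bounding box of each dive's path
  (through-the-water frame).  An encounter occurs when a prey point first
  comes within ``detection_radius`` of the path; each encounter stamps a
  high-frequency burst on all three acceleration axes.  Drift (passive)
  dives produce no encounters: a resting animal does not react to prey.
* Currents: a constant ``current_velocity`` displaces the animal over
  ground between GPS fixes; prey and swimming live in the water frame.
* Acoustics: the flow-noise level is synthesized directly as
  ``a + b log(speed)`` plus noise, and is masked outside the acoustic duty
  cycle (``duty_cycle`` hours on per 12 h period, as in the 2011 tag
  programming).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .attitude_and_speed import (
    AttitudeSeries,
    render_magnetics,
    render_static_acceleration,
)
from .pipeline_io import GpsFixes, SensorFrame, unproject_xy

__all__ = ["SimConfig", "TruthBundle", "simulate_deployment"]


@dataclass
class SimConfig:
    """Study conditions of a simulated deployment.

    Defaults emulate the study system: post-breeding female southern
    elephant seals diving to a mesopelagic prey layer near 500 m, swimming
    ~1.5 m/s, with duty-cycled acoustics (3 h on per 12 h).
    """

    seed: int = 0
    n_dives: int = 10
    layer_center_depth: float = 500.0  # m
    layer_thickness: float = 50.0  # m, gives bottom vertical widths near reported means
    prey_intensity: float = 7e-4  # prey per m^3
    detection_radius: float = 1.5  # m
    bottom_linearity: float = 0.9  # 0-1, fraction of bottom motion along azimuth
    current_velocity: tuple = (0.0, 0.0)  # (east, north) m/s
    swim_speed_mean: float = 1.5  # m/s
    swim_speed_sd: float = 0.35  # m/s, matches reported bottom speed SD
    bottom_pitch_dither: float = 0.22  # rad, low-frequency vertical searching
    accel_noise_sd: float = 0.1  # m/s^2, propulsive + sensor noise
    burst_amplitude: float = 0.6  # m/s^2
    burst_duration: float = 2.0  # s
    mag_inclination_deg: float = -64.0  # Kerguelen-like (field points up, south hemi)
    mag_strength: float = 1.0  # arbitrary field units
    mag_noise_sd: float = 0.005
    duty_cycle: float = 3.0  # hours on per 12 h period
    bottom_duration_mean: float = 500.0  # s, matches reported mean
    bottom_duration_sd: float = 60.0
    descent_pitch_deg: float = 55.0
    surface_duration: float = 120.0  # s
    depth_offset: float = 1.5  # m, pressure-sensor zero offset at t=0
    depth_drift_per_hour: float = 0.15  # m/h sensor drift
    noise_cal_intercept: float = 60.0  # flow-noise level units
    noise_cal_slope: float = 20.0  # level units per log(m/s)
    noise_level_sd: float = 0.3
    drift_dive_fraction: float = 0.1  # passive drift dives, removed by the pipeline
    base_lat: float = -49.35
    base_lon: float = 70.22

    def __post_init__(self) -> None:
        numeric = {k: v for k, v in asdict(self).items() if k != "current_velocity"}
        for k, v in numeric.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite config value {k}={v!r}")
        if not np.all(np.isfinite(self.current_velocity)):
            raise ValueError("non-finite current_velocity")
        if self.prey_intensity < 0:
            raise ValueError("prey_intensity must be >= 0")
        if not 0.0 <= self.bottom_linearity <= 1.0:
            raise ValueError("bottom_linearity must lie in [0, 1]")
        if self.layer_thickness <= 0 or self.detection_radius <= 0:
            raise ValueError("layer_thickness and detection_radius must be > 0")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "current_velocity" in raw:
            raw["current_velocity"] = tuple(raw["current_velocity"])
        return cls(**raw)


@dataclass
class TruthBundle:
    """Ground truth of one simulated deployment (1 Hz unless noted)."""

    true_positions: np.ndarray  # (n, 3) over-ground ENU, z = -depth
    true_attitude: AttitudeSeries
    true_speed: np.ndarray  # through-the-water swim speed
    true_pee_times: np.ndarray  # s (prey first within detection radius)
    true_prey_density: float
    dive_intervals: list  # (start, end) inclusive index pairs
    true_bottom_intervals: list  # (start, end) inclusive index pairs per dive
    is_drift: np.ndarray  # bool per dive
    water_positions: np.ndarray = None  # (n, 3) through-the-water frame
    prey_points: list = field(default_factory=list)  # realized prey per dive

    @property
    def true_bottom_interval(self):
        """Bottom interval of the first dive (convenience accessor)."""
        return self.true_bottom_intervals[0]


def _smooth(x: np.ndarray, sigma: float = 4.0) -> np.ndarray:
    return gaussian_filter1d(x, sigma, mode="nearest")


def _ar1(n: int, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary AR(1) series with correlation time ``tau`` s."""
    rho = np.exp(-1.0 / tau)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1) * np.sqrt(1 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return x


def _plan_dive(cfg: SimConfig, rng: np.random.Generator, drift: bool):
    """1 Hz pitch/heading/speed profiles and phase labels for one dive."""
    v_desc = max(cfg.swim_speed_mean, 0.5)
    pitch_d = np.deg2rad(cfg.descent_pitch_deg)
    t_desc = int(np.ceil(cfg.layer_center_depth / (v_desc * np.sin(pitch_d)))) + 10
    bottom_dur = int(
        max(120.0, rng.normal(cfg.bottom_duration_mean, cfg.bottom_duration_sd))
    )
    azimuth = rng.uniform(0, 2 * np.pi)

    n_guess = 2 * t_desc + bottom_dur + 400
    pitch = np.zeros(n_guess)
    heading = np.full(n_guess, azimuth)
    speed = np.full(n_guess, cfg.swim_speed_mean)

    # speed fluctuations (smooth, through-the-water)
    if cfg.swim_speed_sd > 0:
        speed = speed + cfg.swim_speed_sd * _smooth(_ar1(n_guess, 60.0, rng), 5.0)
    speed = np.clip(speed, 0.4, 2.9)

    # bottom-phase wander processes
    z_margin = cfg.detection_radius + 2.0
    z_amp = max(cfg.layer_thickness / 2.0 - z_margin, 0.0)
    z_wander = np.clip(
        z_amp / 1.5 * _smooth(_ar1(bottom_dur + 2, 60.0, rng), 8.0), -z_amp, z_amp
    )
    head_sd = (1.0 - cfg.bottom_linearity) * 1.2  # rad
    head_dev = head_sd * _smooth(_ar1(bottom_dur + 2, 45.0, rng), 6.0)

    depth = 0.0
    phase = np.zeros(n_guess, dtype=np.int8)  # 0 descent, 1 bottom, 2 ascent, 3 done
    state = 0
    t_bot = 0
    end = n_guess
    for t in range(n_guess):
        if state == 0:
            pitch[t] = -pitch_d
            if depth >= cfg.layer_center_depth - 5.0:
                state = 1
        elif state == 1:
            if drift:
                pitch[t] = np.deg2rad(-80.0)
                speed[t] = 0.3
                heading[t] = azimuth + 0.2 * np.sin(2 * np.pi * t_bot / 300.0)
            else:
                target = cfg.layer_center_depth + z_wander[min(t_bot, bottom_dur + 1)]
                dither = cfg.bottom_pitch_dither * np.sin(2 * np.pi * t_bot / 23.0)
                pitch[t] = np.clip(0.08 * (depth - target), -0.25, 0.25) + dither
                heading[t] = azimuth + head_dev[min(t_bot, bottom_dur + 1)]
            t_bot += 1
            if t_bot >= bottom_dur:
                state = 2
        elif state == 2:
            pitch[t] = pitch_d
            if depth <= 0.5:
                end = t + 1
                break
        phase[t] = state
        # depth rate = -v sin(pitch), depth positive down
        depth = max(depth - speed[t] * np.sin(pitch[t]), 0.0)
    pitch = _smooth(pitch[:end], 4.0)
    heading = _smooth(heading[:end], 4.0)
    speed = speed[:end]
    phase = phase[:end]
    if drift:
        # passive drift: no stroking, near-constant slow sink
        speed[phase == 1] = 0.3
    return pitch, heading, speed, phase, azimuth


def _telegraph_envelope(
    n5: int,
    rng: np.random.Generator,
    mean_interval_s: float = 90.0,
    levels: tuple = (0.25, 1.0),
) -> np.ndarray:
    """Activity-level envelope: a smoothed two-state telegraph process.

    Emulates shifts between quiet (gliding) and active swimming, which are
    what give the windowed-SD detector feature its heavy upper tail on
    real records.
    """
    fs = 5.0
    env = np.empty(n5)
    state = int(rng.integers(2))
    i = 0
    while i < n5:
        run = max(int(rng.exponential(mean_interval_s) * fs), int(5 * fs))
        env[i : i + run] = levels[state]
        state = 1 - state
        i += run
    return gaussian_filter1d(env, 5.0, mode="nearest")


def _realize_prey(
    cfg: SimConfig, path: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson prey points in the layer slab near one dive path.

    Returns (points, encounter_time_index) where the time index is the
    first path sample within ``detection_radius`` (-1 for never).
    """
    r = cfg.detection_radius
    z_lo = -(cfg.layer_center_depth + cfg.layer_thickness / 2.0)
    z_hi = -(cfg.layer_center_depth - cfg.layer_thickness / 2.0)
    lo = path.min(axis=0) - r
    hi = path.max(axis=0) + r
    lo[2], hi[2] = max(lo[2], z_lo), min(hi[2], z_hi)
    if hi[2] <= lo[2]:
        return np.empty((0, 3)), np.empty(0, int)
    vol = float(np.prod(hi - lo))
    n = rng.poisson(cfg.prey_intensity * vol)
    if n == 0:
        return np.empty((0, 3)), np.empty(0, int)
    pts = lo + (hi - lo) * rng.random((n, 3))
    tree = cKDTree(path)
    hits = tree.query_ball_point(pts, r)
    first = np.array([min(h) if h else -1 for h in hits], dtype=int)
    return pts, first


def simulate_deployment(config: SimConfig) -> tuple[SensorFrame, GpsFixes, TruthBundle]:
    """Simulate one deployment: sensors, GPS fixes and ground truth.

    Deterministic for a given ``config.seed`` (bit-identical re-runs).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_surf = int(cfg.surface_duration)

    pitch_parts, heading_parts, speed_parts, phase_parts = [], [], [], []
    dive_marks = []  # (start, end, bottom_start, bottom_end, drift) in sample idx
    is_drift = []
    cursor = 0

    def add_surface(azimuth: float) -> None:
        nonlocal cursor
        pitch_parts.append(np.zeros(n_surf))
        heading_parts.append(np.full(n_surf, azimuth))
        speed_parts.append(np.zeros(n_surf))
        phase_parts.append(np.full(n_surf, -1, dtype=np.int8))
        cursor += n_surf

    for _ in range(cfg.n_dives):
        drift = bool(rng.random() < cfg.drift_dive_fraction)
        pitch, heading, speed, phase, azimuth = _plan_dive(cfg, rng, drift)
        add_surface(azimuth)
        start = cursor
        bottom_idx = np.flatnonzero(phase == 1)
        dive_marks.append(
            (start, start + len(pitch) - 1, start + bottom_idx[0], start + bottom_idx[-1], drift)
        )
        is_drift.append(drift)
        pitch_parts.append(pitch)
        heading_parts.append(heading)
        speed_parts.append(speed)
        phase_parts.append(phase)
        cursor += len(pitch)
    add_surface(heading_parts[-1][-1])

    pitch1 = np.concatenate(pitch_parts)
    heading1 = np.mod(np.concatenate(heading_parts), 2 * np.pi)
    speed1 = np.concatenate(speed_parts)
    phase1 = np.concatenate(phase_parts)
    n1 = len(pitch1)
    time1 = np.arange(n1, dtype=float)

    # roll: small smooth wander (zero at surface makes no difference downstream)
    roll1 = 0.08 * _smooth(_ar1(n1, 30.0, rng), 6.0)

    # --- integrate true kinematics (left-endpoint scheme, as dead-reckoning) ---
    depth = np.zeros(n1)
    east = np.zeros(n1)
    north = np.zeros(n1)
    sa, ca = np.sin(pitch1), np.cos(pitch1)
    sh, ch = np.sin(heading1), np.cos(heading1)
    for t in range(n1 - 1):
        v = speed1[t]
        if phase1[t + 1] < 0:  # surface: the animal rests at 0 m
            depth[t + 1] = 0.0
        else:
            depth[t + 1] = max(depth[t] - v * sa[t], 0.0)
        east[t + 1] = east[t] + v * ca[t] * sh[t]
        north[t + 1] = north[t] + v * ca[t] * ch[t]
    water_positions = np.column_stack([east, north, -depth])
    current = np.asarray(cfg.current_velocity, float)
    ground = water_positions.copy()
    ground[:, 0] += current[0] * time1
    ground[:, 1] += current[1] * time1

    # --- prey encounters (water frame) ---
    pee_times: list[float] = []
    prey_points = []
    if cfg.prey_intensity > 0:
        for (a, b, _ba, _bb, drift) in dive_marks:
            if drift:
                continue
            path = water_positions[a : b + 1]
            pts, first = _realize_prey(cfg, path, rng)
            enc = first[first >= 0]
            prey_points.append(pts)
            pee_times.extend((a + enc).tolist())
    pee_times = np.array(sorted(pee_times), dtype=float)

    # --- 5 Hz attitude by interpolating angles, then rendering sensors ---
    t5 = np.arange(n1 * 5) / 5.0
    heading_unwrapped = np.unwrap(heading1)
    att5 = AttitudeSeries(
        pitch=np.interp(t5, time1, pitch1),
        roll=np.interp(t5, time1, roll1),
        heading=np.mod(np.interp(t5, time1, heading_unwrapped), 2 * np.pi),
    )
    accel = render_static_acceleration(att5)
    if cfg.accel_noise_sd > 0:
        n5 = len(accel)
        # propulsive noise is stroking-dominated: a quasi-periodic ~0.9 Hz
        # component (removed by the detector's 2.4 Hz high-pass by design)
        # plus a smaller broadband part whose amplitude switches between
        # activity levels (telegraph process, common to all axes)
        phases = rng.uniform(0, 2 * np.pi, 3)
        stroke = cfg.accel_noise_sd * np.sin(
            2 * np.pi * 0.9 * t5[:, None] + phases[None, :]
        )
        env = np.stack([_telegraph_envelope(n5, rng) for _ in range(3)], axis=1)
        broadband = 0.3 * cfg.accel_noise_sd * env * rng.standard_normal((n5, 3))
        noise = stroke + broadband
        # passive drift dives have no stroking
        for (a, b, ba, bb, drift) in dive_marks:
            if drift:
                noise[ba * 5 : (bb + 1) * 5] *= 0.1
        accel = accel + noise

    # prey-capture bursts: alternating-sign transients in the detector's
    # high-frequency band, on all three axes simultaneously
    n_burst = max(int(round(cfg.burst_duration * 5)), 1)
    for t_enc in pee_times:
        i0 = int(t_enc) * 5
        seg = slice(i0, min(i0 + n_burst, len(accel)))
        # phase-aligned to the absolute sample parity so that adjacent or
        # overlapping bursts stay coherent in the detector's passband;
        # per-sample random magnitudes emulate the irregularity of real
        # capture jerks (and keep the windowed-SD feature rough at the
        # burst centre)
        pattern = (-1.0) ** np.arange(seg.start, seg.stop)
        k = np.arange(seg.stop - seg.start)
        # initial strike then subsiding handling movements: the amplitude
        # decays second to second, with irregular per-sample magnitudes
        decay = 0.45 ** (k // 5)
        mags = (0.3 + 1.4 * rng.random((seg.stop - seg.start, 3))) * decay[:, None]
        accel[seg] += cfg.burst_amplitude * pattern[:, None] * mags

    inc = np.deg2rad(cfg.mag_inclination_deg)
    field_world = cfg.mag_strength * np.array([0.0, np.cos(inc), -np.sin(inc)])
    mag = render_magnetics(att5, field_world)
    if cfg.mag_noise_sd > 0:
        mag = mag + rng.normal(0.0, cfg.mag_noise_sd, mag.shape)

    # --- 1 Hz depth sensor (with zero-offset drift) and flow noise ---
    depth_sensor = depth + cfg.depth_offset + cfg.depth_drift_per_hour * time1 / 3600.0
    noise_level = (
        cfg.noise_cal_intercept
        + cfg.noise_cal_slope * np.log(np.maximum(speed1, 1e-3))
        + (rng.normal(0.0, cfg.noise_level_sd, n1) if cfg.noise_level_sd > 0 else 0.0)
    )
    period, on = 12 * 3600.0, cfg.duty_cycle * 3600.0
    duty_on = np.mod(time1, period) < on
    noise_level = np.where(duty_on, noise_level, np.nan)

    frame = SensorFrame(
        time=time1, depth=depth_sensor, accel=accel, mag=mag, noise_level=noise_level
    )

    # --- GPS fixes at surface-interval midpoints (over-ground + current) ---
    fix_times = [0.0]
    for (a, b, *_rest) in dive_marks:
        fix_times.append(max(a - n_surf / 2.0, 0.0))
    fix_times.append(n1 - n_surf / 2.0)
    fix_idx = np.unique(np.round(fix_times).astype(int))
    fix_idx = fix_idx[(fix_idx >= 0) & (fix_idx < n1)]
    lat, lon = unproject_xy(
        ground[fix_idx, 0], ground[fix_idx, 1], cfg.base_lat, cfg.base_lon
    )
    fixes = GpsFixes(time=time1[fix_idx], lat=lat, lon=lon)

    truth = TruthBundle(
        true_positions=ground,
        true_attitude=AttitudeSeries(pitch=pitch1, roll=roll1, heading=heading1),
        true_speed=speed1,
        true_pee_times=pee_times,
        true_prey_density=cfg.prey_intensity,
        dive_intervals=[(a, b) for (a, b, *_r) in dive_marks],
        true_bottom_intervals=[(ba, bb) for (_a, _b, ba, bb, _d) in dive_marks],
        is_drift=np.array(is_drift, dtype=bool),
        water_positions=water_positions,
        prey_points=prey_points,
    )
    return frame, fixes, truth
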