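"""Data model, file I/O and end-to-end pipeline orchestration.

The deployment data model is deliberately small: a :class:`SensorFrame`
holds the time-aligned raw streams of one deployment (depth and flow-noise
level at 1 Hz; tri-axial acceleration and magnetics at 5 Hz) and a
:class:`GpsFixes` table holds the surface locations.  Frames round-trip
through NetCDF (via xarray's scipy backend, one dimension per sampling
rate) and paired CSV files; GPS fixes through CSV with ISO-8601 times.

:func:`run_pipeline` chains the analysis stages in order -- depth
correction, dive and bottom delimitation, PEE detection, attitude and
speed estimation, dead-reckoning with GPS closure, shape metrics,
Monte-Carlo prospected volumes and the density proxy -- and returns one
row per non-drift dive with a reconstructable 3D path.  Dives without
flow-noise (hence speed) coverage are excluded, mirroring duty-cycled
acoustic sampling.  All angles are radians internally; depth is positive
down; the local frame is East-North-Up with ``z = -depth``; GPS positions
are projected onto a local equirectangular tangent plane anchored at the
deployment's first fix (dive-scale distances make the projection error
negligible).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import attitude_and_speed as att
from . import bottom_shape, dead_reckoning, dive_segmentation, pee_detection
from . import prospected_volume as pvol

__all__ = [
    "SensorFrame",
    "GpsFixes",
    "FormatError",
    "PipelineParams",
    "PipelineResult",
    "read_sensor_frame",
    "run_pipeline",
    "project_lonlat",
    "unproject_xy",
]

logger = logging.getLogger("divebottom3d")

EARTH_RADIUS_M = 6_371_000.0
EPOCH = np.datetime64("2011-11-01T00:00:00")


class FormatError(ValueError):
    """A file does not conform to the documented schema."""


def project_lonlat(lat, lon, lat0: float, lon0: float) -> np.ndarray:
    """Equirectangular projection to local (east, north) metres."""
    lat, lon = np.asarray(lat, float), np.asarray(lon, float)
    east = np.deg2rad(lon - lon0) * EARTH_RADIUS_M * np.cos(np.deg2rad(lat0))
    north = np.deg2rad(lat - lat0) * EARTH_RADIUS_M
    return np.stack([east, north], axis=-1)


def unproject_xy(east, north, lat0: float, lon0: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_lonlat`."""
    east, north = np.asarray(east, float), np.asarray(north, float)
    lat = lat0 + np.rad2deg(north / EARTH_RADIUS_M)
    lon = lon0 + np.rad2deg(east / (EARTH_RADIUS_M * np.cos(np.deg2rad(lat0))))
    return lat, lon


@dataclass
class SensorFrame:
    """Time-aligned raw sensor streams for one deployment.

    1 Hz streams: ``time`` (s since deployment start), ``depth`` (m,
    positive down; small negatives allowed pre-correction), ``noise_level``
    (arbitrary flow-noise units, NaN outside the acoustic duty cycle).
    5 Hz streams: ``accel`` and ``mag``, shape (5n, 3) in body axes
    (longitudinal, lateral, dorsoventral); sample ``5t`` is aligned with
    second ``t``.
    """

    time: np.ndarray
    depth: np.ndarray
    accel: np.ndarray
    mag: np.ndarray
    noise_level: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.depth = np.asarray(self.depth, float)
        self.accel = np.asarray(self.accel, float)
        self.mag = np.asarray(self.mag, float)
        self.noise_level = np.asarray(self.noise_level, float)
        n = len(self.time)
        if n and (np.diff(self.time) <= 0).any():
            raise FormatError("time must be strictly increasing")
        if len(self.depth) != n or len(self.noise_level) != n:
            raise FormatError("1 Hz streams must share the same length")
        for name, s in (("accel", self.accel), ("mag", self.mag)):
            if s.shape != (5 * n, 3):
                raise FormatError(f"{name} must have shape (5n, 3) = ({5 * n}, 3)")
        if n and np.nanmin(self.depth) < -5.0:
            raise FormatError("depth below -5 m: not a plausible pre-correction offset")

    def __len__(self) -> int:
        return len(self.time)

    # -- I/O ---------------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        n = len(self.time)
        time5 = np.repeat(self.time, 5) + np.tile(np.arange(5) / 5.0, n)
        return xr.Dataset(
            {
                "depth": ("time_1hz", self.depth),
                "noise_level": ("time_1hz", self.noise_level),
                "accel": (("time_5hz", "axis"), self.accel),
                "mag": (("time_5hz", "axis"), self.mag),
            },
            coords={
                "time_1hz": self.time,
                "time_5hz": time5,
                "axis": ["x", "y", "z"],
            },
            attrs={"conventions": "depth positive down; body axes fwd/right/dorsal"},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    def to_csv(self, stem) -> tuple[Path, Path]:
        """Write ``<stem>_1hz.csv`` and ``<stem>_5hz.csv``; returns the paths."""
        stem = Path(stem)
        p1 = stem.with_name(stem.name + "_1hz.csv")
        p5 = stem.with_name(stem.name + "_5hz.csv")
        pd.DataFrame(
            {"time": self.time, "depth": self.depth, "noise_level": self.noise_level}
        ).to_csv(p1, index=False)
        n = len(self.time)
        time5 = np.repeat(self.time, 5) + np.tile(np.arange(5) / 5.0, n)
        pd.DataFrame(
            {
                "time": time5,
                "ax": self.accel[:, 0], "ay": self.accel[:, 1], "az": self.accel[:, 2],
                "mx": self.mag[:, 0], "my": self.mag[:, 1], "mz": self.mag[:, 2],
            }
        ).to_csv(p5, index=False)
        return p1, p5

    @classmethod
    def from_netcdf(cls, path) -> "SensorFrame":
        try:
            ds = xr.open_dataset(path, engine="scipy")
        except (OSError, TypeError) as exc:
            raise FormatError(f"cannot read NetCDF sensor frame: {exc}") from exc
        required = {"depth", "noise_level", "accel", "mag"}
        if not required.issubset(ds.data_vars):
            raise FormatError(f"NetCDF frame missing variables {required - set(ds.data_vars)}")
        return cls(
            time=ds["time_1hz"].values,
            depth=ds["depth"].values,
            accel=ds["accel"].values,
            mag=ds["mag"].values,
            noise_level=ds["noise_level"].values,
        )

    @classmethod
    def from_csv(cls, stem) -> "SensorFrame":
        stem = Path(stem)
        p1 = stem.with_name(stem.name + "_1hz.csv")
        p5 = stem.with_name(stem.name + "_5hz.csv")
        try:
            d1 = pd.read_csv(p1)
            d5 = pd.read_csv(p5)
        except FileNotFoundError as exc:
            raise FormatError(str(exc)) from exc
        need1, need5 = {"time", "depth", "noise_level"}, {"time", "ax", "ay", "az", "mx", "my", "mz"}
        if not need1.issubset(d1.columns) or not need5.issubset(d5.columns):
            raise FormatError("CSV sensor frame missing required columns")
        return cls(
            time=d1["time"].to_numpy(),
            depth=d1["depth"].to_numpy(),
            accel=d5[["ax", "ay", "az"]].to_numpy(),
            mag=d5[["mx", "my", "mz"]].to_numpy(),
            noise_level=d1["noise_level"].to_numpy(),
        )


def read_sensor_frame(path, format: str = "netcdf") -> SensorFrame:
    """Read a sensor frame from ``netcdf`` (one file) or ``csv`` (a stem)."""
    if format == "netcdf":
        return SensorFrame.from_netcdf(path)
    if format == "csv":
        return SensorFrame.from_csv(path)
    raise ValueError(f"unknown format {format!r}")


@dataclass
class GpsFixes:
    """Surface GPS fixes: time (s since deployment start), lat/lon degrees."""

    time: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.lat = np.asarray(self.lat, float)
        self.lon = np.asarray(self.lon, float)
        if not (len(self.time) == len(self.lat) == len(self.lon)):
            raise FormatError("GPS fix columns must have equal length")
        if len(self.time) and (np.diff(self.time) <= 0).any():
            raise FormatError("GPS fix times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def to_csv(self, path, epoch: np.datetime64 = EPOCH) -> None:
        stamps = epoch + (self.time * 1e3).astype("timedelta64[ms]")
        pd.DataFrame(
            {"time": np.datetime_as_string(stamps, unit="ms"), "lat": self.lat, "lon": self.lon}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, epoch: np.datetime64 = EPOCH) -> "GpsFixes":
        df = pd.read_csv(path)
        if not {"time", "lat", "lon"}.issubset(df.columns):
            raise FormatError("GPS CSV must have time, lat, lon columns")
        t = (pd.to_datetime(df["time"]).to_numpy() - epoch) / np.timedelta64(1, "s")
        return cls(time=t, lat=df["lat"].to_numpy(), lon=df["lon"].to_numpy())

    def xy(self, lat0: float | None = None, lon0: float | None = None) -> np.ndarray:
        if lat0 is None:
            lat0, lon0 = float(self.lat[0]), float(self.lon[0])
        return project_lonlat(self.lat, self.lon, lat0, lon0)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineParams:
    """Stage parameters of the end-to-end pipeline (defaults documented)."""

    dive_threshold: float = 15.0  # m
    surface_threshold: float = 10.0  # m, zero-offset candidate surfaces
    v_threshold: float = 0.75  # m/s, bottom delimitation
    min_pitch_deg: float = 20.0  # pitch-derived speed guard
    pitch_rate_max: float = 0.02  # rad/s, steadiness guard for calibration pairs
    radii: tuple = pvol.DEFAULT_RADII
    mc_samples: int = pvol.DEFAULT_N_SAMPLES
    seed: int = 0
    min_noise_coverage: float = 0.95  # fraction of dive samples with noise level
    drift_speed_sd: float = 0.15
    drift_vz_sd: float = 0.10
    drift_min_duration: float = 200.0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


@dataclass
class PipelineResult:
    """Per-dive table plus the intermediate products that generated it."""

    table: pd.DataFrame
    tracks: dict = field(default_factory=dict)  # dive_id -> Track3D (dive slice)
    segment_tracks: dict = field(default_factory=dict)  # dive_id -> fix-to-fix Track3D
    dives: list = field(default_factory=list)
    events: list = field(default_factory=list)
    calibration: att.NoiseSpeedCalibration | None = None
    speed: att.SpeedSeries | None = None


def _empty_table(params: PipelineParams) -> pd.DataFrame:
    cols = [
        "dive_id", "start", "end", "descent_end", "ascent_start", "max_depth",
        "bottom_duration", "mean_depth", "total_dispersion", "mc1_dispersion",
        "horizontality", "mc1_horizontal_extent", "mc1_vertical_extent",
        "horizontal_width", "vertical_width", "speed_sd", "pee_count",
    ]
    for r in params.radii:
        cols += [f"volume_r{r:g}", f"volume_rse_r{r:g}", f"density_r{r:g}"]
    cols.append("params_hash")
    return pd.DataFrame(columns=cols)


def run_pipeline(
    frame: SensorFrame, fixes: GpsFixes, params: PipelineParams | None = None
) -> PipelineResult:
    """Run every analysis stage and return one row per usable dive.

    A dive is usable when it is not a drift dive, has flow-noise (speed)
    coverage over at least ``min_noise_coverage`` of its samples, and every
    stage succeeds; a stage failure aborts the dive's row (logged), not
    the run.
    """
    params = params or PipelineParams()
    if len(frame) == 0:
        return PipelineResult(table=_empty_table(params))

    depth = dive_segmentation.zero_offset_correct(
        frame.depth, surface_threshold=params.surface_threshold
    )
    dives = dive_segmentation.find_dives(depth, threshold=params.dive_threshold)
    for d in dives:
        dive_segmentation.delimit_bottom(d, depth, v_threshold=params.v_threshold)

    # attitude at 5 Hz, decimated to the 1 Hz clock (sample 5t <-> second t)
    static = att.static_acceleration(frame.accel)
    static_mag = att.static_acceleration(frame.mag)
    attitude5 = att.tilt_compensated_heading(att.pitch_roll(static), static_mag)
    sel = np.arange(len(frame)) * 5
    attitude = att.AttitudeSeries(
        pitch=attitude5.pitch[sel], roll=attitude5.roll[sel], heading=attitude5.heading[sel]
    )

    # PEE detection on the full record
    dyn = pee_detection.dynamic_acceleration(frame.accel)
    states = [pee_detection.state_signal(dyn[:, i]) for i in range(3)]
    states = [s[: len(frame)] for s in states]
    events = pee_detection.detect_pee(states)
    events = pee_detection.assign_events_to_dives(events, dives)

    # swim speed: pitch-derived in steep phases, flow-noise elsewhere
    v_z = np.r_[np.diff(depth), np.nan]
    min_pitch = np.deg2rad(params.min_pitch_deg)
    in_dive = np.zeros(len(frame), bool)
    in_transit = np.zeros(len(frame), bool)
    for d in dives:
        in_dive[d.start : d.end + 1] = True
        if d.descent_end >= 0:
            in_transit[d.start : d.descent_end] = True
            in_transit[d.ascent_start : d.end + 1] = True
    v_pitch = att.speed_from_pitch(v_z, attitude.pitch, min_pitch=min_pitch)
    # v_z / sin(alpha) assumes steady pitch over the 1 s interval; samples
    # taken during pitch transitions are biased and are left to the
    # flow-noise prediction instead
    steady = np.r_[np.abs(np.diff(attitude.pitch)) < params.pitch_rate_max, False]
    v_pitch = np.where(in_transit & steady, v_pitch, np.nan)
    try:
        calib = att.calibrate_noise_speed(frame.noise_level, v_pitch)
    except att.CalibrationError as exc:
        warnings.warn(f"flow-noise calibration failed ({exc}); no speed available")
        return PipelineResult(table=_empty_table(params), dives=dives, events=events)
    v_noise = np.where(np.isfinite(frame.noise_level), calib.predict(frame.noise_level), np.nan)
    speed_vals = np.where(np.isfinite(v_pitch), v_pitch, v_noise)
    source = np.where(
        np.isfinite(v_pitch), "pitch", np.where(np.isfinite(v_noise), "noise", "none")
    )
    speed = att.SpeedSeries(speed=speed_vals, source=source)

    fix_xy = fixes.xy() if len(fixes) else np.empty((0, 2))

    rows = []
    tracks = {}
    segment_tracks = {}
    for d in dives:
        try:
            sl = slice(d.start, d.end + 1)
            coverage = np.isfinite(frame.noise_level[sl]).mean()
            if coverage < params.min_noise_coverage:
                logger.info("dive %d: outside acoustic duty cycle; skipped", d.dive_id)
                continue
            if dive_segmentation.flag_drift_dive(
                d, speed.speed, depth,
                speed_sd_threshold=params.drift_speed_sd,
                vz_sd_threshold=params.drift_vz_sd,
                min_duration=params.drift_min_duration,
            ):
                logger.info("dive %d: drift dive; removed", d.dive_id)
                continue
            if d.ascent_start - d.descent_end < 4:
                logger.info("dive %d: bottom too short for shape metrics", d.dive_id)
                continue
            before = np.flatnonzero(fixes.time <= frame.time[d.start])
            after = np.flatnonzero(fixes.time >= frame.time[d.end])
            if before.size == 0:
                logger.warning("dive %d: no anchor fix; skipped", d.dive_id)
                continue
            anchor = fix_xy[before[-1]]
            closing = fix_xy[after[0]] if after.size else None
            # integrate from the anchor fix (surface) through the dive to
            # the closing fix, so the known location really is the track's
            # starting point; the dive is then a slice of that segment
            seg_a = int(np.searchsorted(frame.time, fixes.time[before[-1]]))
            seg_b = (
                int(np.searchsorted(frame.time, fixes.time[after[0]]))
                if after.size
                else d.end
            )
            seg_b = min(seg_b, len(frame) - 1)
            ssl = slice(seg_a, seg_b + 1)
            seg_att = att.AttitudeSeries(
                pitch=attitude.pitch[ssl], roll=attitude.roll[ssl], heading=attitude.heading[ssl]
            )
            seg_track = dead_reckoning.integrate_path(
                seg_att, speed.speed[ssl], depth[ssl], anchor, times=frame.time[ssl]
            )
            seg_track = dead_reckoning.close_track(seg_track, closing)
            track = dead_reckoning.Track3D(
                times=seg_track.times[d.start - seg_a : d.end - seg_a + 1],
                positions=seg_track.positions[d.start - seg_a : d.end - seg_a + 1],
                anchor_xy=seg_track.anchor_xy,
                closing_xy=seg_track.closing_xy,
                correction_velocity=seg_track.correction_velocity,
                closed=seg_track.closed,
            )
            dive_events = [ev for ev in events if ev.dive_id == d.dive_id]
            metrics = bottom_shape.assemble_metrics(d, track, speed.speed[sl], dive_events)
            dive_seed = (params.seed * 1_000_003 + 7919 * (d.dive_id + 1)) % (2**31)
            bottom = track.positions[d.descent_end - d.start : d.ascent_start - d.start + 1]
            vols = pvol.mc_volume_profile(
                bottom, radii=params.radii, n_samples=params.mc_samples, seed=dive_seed
            )
            row = {
                "dive_id": d.dive_id, "start": d.start, "end": d.end,
                "descent_end": d.descent_end, "ascent_start": d.ascent_start,
                "max_depth": d.max_depth, "bottom_duration": metrics.bottom_duration,
                "mean_depth": metrics.mean_depth,
                "total_dispersion": metrics.total_dispersion,
                "mc1_dispersion": metrics.mc1_dispersion,
                "horizontality": metrics.horizontality,
                "mc1_horizontal_extent": metrics.mc1_horizontal_extent,
                "mc1_vertical_extent": metrics.mc1_vertical_extent,
                "horizontal_width": metrics.horizontal_width,
                "vertical_width": metrics.vertical_width,
                "speed_sd": metrics.speed_sd, "pee_count": metrics.pee_count,
            }
            for vol in vols:
                row[f"volume_r{vol.radius:g}"] = vol.volume
                row[f"volume_rse_r{vol.radius:g}"] = vol.relative_se
                row[f"density_r{vol.radius:g}"] = pvol.density_proxy(
                    metrics.pee_count, vol.volume
                )
            row["params_hash"] = params.hash()
            rows.append(row)
            tracks[d.dive_id] = track
            segment_tracks[d.dive_id] = seg_track
        except Exception as exc:  # noqa: BLE001 -- stage failure aborts the dive, not the run
            logger.warning("dive %d: stage failure (%s); row dropped", d.dive_id, exc)
    table = pd.DataFrame(rows) if rows else _empty_table(params)
    return PipelineResult(
        table=table, tracks=tracks, segment_tracks=segment_tracks, dives=dives,
        events=events, calibration=calib, speed=speed,
    )
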