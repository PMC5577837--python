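"""Dive delimitation and phase segmentation from a 1 Hz depth series.

A dive is a maximal period continuously deeper than 15 m -- a conservative
threshold that keeps brief sub-surface excursions out of the dive set.
Pressure sensors drift over a deployment, so a zero-offset correction is
applied first.  Within each dive, the bottom (foraging) phase is the
contiguous interval around the deepest point where a degree-4 polynomial
model of the vertical speed stays below 0.75 m/s; the polynomial responds
to the overall shape of the time-depth profile rather than to small steps
in the descent or ascent, and has enough freedom for both V- and U-shaped
dives.  Drift dives (passive resting/digesting descents) are flagged with
a documented threshold rule so they can be removed before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiveRecord",
    "zero_offset_correct",
    "find_dives",
    "delimit_bottom",
    "flag_drift_dive",
]

DIVE_THRESHOLD_M = 15.0
VERTICAL_SPEED_THRESHOLD = 0.75  # m/s, from blind-experiment calibration


@dataclass
class DiveRecord:
    """One dive, indexed into the deployment's 1 Hz clock.

    ``phase_bounds = (descent_end, ascent_start)`` delimit the bottom phase
    ``[descent_end, ascent_start]`` (inclusive, global indices); equal
    bounds denote an empty bottom (V-dive).
    """

    dive_id: int
    start: int
    end: int  # inclusive
    descent_end: int = -1
    ascent_start: int = -1
    max_depth: float = np.nan
    is_drift: bool = False

    @property
    def phase_bounds(self) -> tuple[int, int]:
        return (self.descent_end, self.ascent_start)

    @property
    def bottom_duration(self) -> float:
        if self.descent_end < 0:
            return np.nan
        return float(max(self.ascent_start - self.descent_end, 0))

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


def zero_offset_correct(
    depth: np.ndarray, surface_threshold: float = 10.0
) -> np.ndarray:
    """Remove slow pressure-sensor drift so surface intervals read ~0 m.

    The offset is estimated as the median depth of each contiguous
    candidate surface interval (raw depth below ``surface_threshold``) and
    interpolated linearly across dives before subtraction, so a drift that
    accumulates between surfacings is tracked.  Within-dive depth
    differences are essentially unchanged.  A record with no surface
    interval falls back to subtracting the global minimum (with a warning).
    """
    depth = np.asarray(depth, float)
    at_surface = depth < surface_threshold
    if not at_surface.any():
        warnings.warn("no surface interval found; subtracting global minimum depth")
        return depth - np.nanmin(depth)
    edges = np.flatnonzero(np.diff(at_surface.astype(np.int8)))
    starts = np.r_[0 if at_surface[0] else [], edges[~at_surface[edges]] + 1].astype(int)
    ends = np.r_[edges[at_surface[edges]], len(depth) - 1 if at_surface[-1] else []].astype(int)
    centers = (starts + ends) / 2.0
    offsets = np.array([np.median(depth[a : b + 1]) for a, b in zip(starts, ends)])
    t = np.arange(len(depth), dtype=float)
    return depth - np.interp(t, centers, offsets)


def find_dives(depth: np.ndarray, threshold: float = DIVE_THRESHOLD_M) -> list[DiveRecord]:
    """Maximal runs continuously deeper than ``threshold`` (default 15 m).

    Operates on zero-offset-corrected depth.  Runs touching the record ends
    are kept (truncated dives are delimited like any other).
    """
    depth = np.asarray(depth, float)
    deep = depth > threshold
    if not deep.any():
        return []
    edges = np.flatnonzero(np.diff(deep.astype(np.int8)))
    starts = np.r_[0 if deep[0] else [], edges[~deep[edges]] + 1].astype(int)
    ends = np.r_[edges[deep[edges]], len(depth) - 1 if deep[-1] else []].astype(int)
    dives = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        dives.append(
            DiveRecord(dive_id=i, start=int(a), end=int(b), max_depth=float(depth[a : b + 1].max()))
        )
    return dives


def delimit_bottom(
    dive: DiveRecord,
    depth: np.ndarray,
    v_threshold: float = VERTICAL_SPEED_THRESHOLD,
) -> DiveRecord:
    """Delimit descent/bottom/ascent with the polynomial vertical-speed rule.

    The 1 Hz vertical speed (first difference of depth) over the dive is
    modelled with a least-squares polynomial of degree 4 in time; the
    bottom phase is the contiguous interval containing the deepest sample
    where the fitted |vertical speed| stays under ``v_threshold``.  Dives
    too short for the fit (< 5 samples) get an empty bottom.
    """
    depth = np.asarray(depth, float)
    d = depth[dive.start : dive.end + 1]
    # deepest sample; for a flat maximum (square-bottomed dive) anchor at
    # the middle of the deepest run rather than its corner
    ties = np.flatnonzero(d >= d.max() - 1e-9)
    imax = int(ties[len(ties) // 2])
    if len(d) < 5:
        warnings.warn(f"dive {dive.dive_id}: too short for polynomial fit; empty bottom")
        dive.descent_end = dive.ascent_start = dive.start + imax
        return dive
    v_z = np.diff(d)  # m/s at 1 Hz, positive down
    t = np.arange(len(v_z), dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(t, v_z, deg=4)
    fitted = np.polynomial.polynomial.polyval(t, coeffs)
    # vertical speed sample k sits between depth samples k and k+1; the
    # deepest depth sample maps to the adjacent speed sample
    k0 = min(imax, len(v_z) - 1)
    slow = np.abs(fitted) < v_threshold
    if not slow[k0] and imax > 0 and slow[imax - 1]:
        k0 = imax - 1
    if not slow[k0]:
        dive.descent_end = dive.ascent_start = dive.start + imax
        return dive
    a = k0
    while a > 0 and slow[a - 1]:
        a -= 1
    b = k0
    while b < len(v_z) - 1 and slow[b + 1]:
        b += 1
    # speed run [a, b] covers depth samples [a, b + 1]
    dive.descent_end = dive.start + a
    dive.ascent_start = dive.start + b + 1
    return dive


def flag_drift_dive(
    dive: DiveRecord,
    speed: np.ndarray | None,
    depth: np.ndarray,
    speed_sd_threshold: float = 0.15,
    vz_sd_threshold: float = 0.10,
    min_duration: float = 200.0,
) -> bool:
    """Flag passive drift (resting/digesting) dives.

    A documented stand-in for the behavioural classifier of the drift-dive
    literature: the bottom phase must last at least ``min_duration`` s with
    swim-speed SD below ``speed_sd_threshold`` and a near-constant vertical
    rate (SD of v_z below ``vz_sd_threshold``).  Sets and returns
    ``dive.is_drift``.
    """
    if dive.descent_end < 0 or dive.ascent_start <= dive.descent_end:
        dive.is_drift = False
        return False
    if dive.ascent_start - dive.descent_end < min_duration:
        dive.is_drift = False
        return False
    if speed is None:
        warnings.warn(f"dive {dive.dive_id}: no speed data; drift flag left False")
        dive.is_drift = False
        return False
    depth = np.asarray(depth, float)
    sl = slice(dive.descent_end, dive.ascent_start + 1)
    v = np.asarray(speed, float)[sl]
    if np.isfinite(v).sum() < 2:
        warnings.warn(f"dive {dive.dive_id}: no finite bottom speed; drift flag left False")
        dive.is_drift = False
        return False
    # the polynomial bottom can include the smoothed tails of the active
    # descent/ascent, so the passive-sinking signature (steady slow sink,
    # no strokes) is sought in any sub-window of at least min_duration
    v_z = np.diff(depth[sl])
    w = int(min_duration)
    stride = max(w // 10, 1)
    flagged = False
    for a in range(0, len(v_z) - w + 1, stride):
        vw = v[a : a + w + 1]
        vw = vw[np.isfinite(vw)]
        if vw.size < 2:
            continue
        if (
            vw.std(ddof=1) < speed_sd_threshold
            and v_z[a : a + w].std(ddof=1) < vz_sd_threshold
        ):
            flagged = True
            break
    dive.is_drift = flagged
    return dive.is_drift
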