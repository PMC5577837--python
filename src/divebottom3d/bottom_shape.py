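"""Shape descriptors of bottom-phase 3D trajectories.

The bottom-phase position cloud is decomposed by eigen-analysis (SVD) of
its 3x3 variance-covariance matrix.  The leading eigenvector, MC1, is the
dominant direction of travel; its eigenvalue share ``lambda1 / (lambda1 +
lambda2 + lambda3)`` (MC1 dispersion) is 1 for a perfectly linear path and
1/3 for isotropic motion.  Because MC1 is overwhelmingly horizontal in
real tracks, the residual dispersion is described in a fixed
horizontal/vertical frame rather than along the minor eigenvectors:

* MC1 extents -- the horizontal and vertical separation of the "ends" of
  the path along MC1, with the ends taken robustly as the 10% and 90%
  quantiles of MC1 scores.
* widths -- spreads of signed distances to two orthogonal planes through
  the centroid: plane A spans MC1 and the gravity vector (distances to it
  are horizontal deviations), plane B spans MC1 and plane A's normal
  (distances to it are vertical deviations); each width is the 10%-90%
  quantile range.

Swim-speed SD over the bottom phase is carried along as a proxy of
foraging effort, and the PEE count as the response of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShapeMetrics",
    "eigen_shape",
    "mc1_extents",
    "plane_widths",
    "assemble_metrics",
]

_QLO, _QHI = 0.10, 0.90


@dataclass
class ShapeMetrics:
    """Bottom-phase shape descriptors for one dive."""

    dive_id: int
    mean_depth: float
    eigenvalues: np.ndarray  # descending, m^2
    eigenvectors: np.ndarray  # columns v1, v2, v3
    total_dispersion: float
    mc1_dispersion: float
    horizontality: float
    mc1_horizontal_extent: float
    mc1_vertical_extent: float
    horizontal_width: float
    vertical_width: float
    speed_sd: float
    bottom_duration: float
    pee_count: int
    vertical_v1_flagged: bool = False


def eigen_shape(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues/eigenvectors of the position variance-covariance matrix.

    Returns eigenvalues sorted descending and the matching unit
    eigenvectors as columns.  The sign of v1 is fixed so that its
    horizontal projection points along the net horizontal displacement of
    the track (falling back to net vertical displacement for vertical v1).
    Requires >= 4 positions.
    """
    p = np.asarray(positions, float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("positions must have shape (n, 3)")
    if p.shape[0] < 4:
        raise ValueError("need at least 4 positions for shape metrics")
    cov = np.cov(p, rowvar=False, ddof=1)
    # SVD of the symmetric PSD covariance = its eigen-decomposition
    u, s, _ = np.linalg.svd(cov)
    order = np.argsort(s)[::-1]
    evals = s[order]
    evecs = u[:, order]
    net = p[-1] - p[0]
    v1 = evecs[:, 0]
    proj = float(v1[:2] @ net[:2])
    if proj == 0.0:
        proj = float(v1[2] * net[2])
    if proj < 0:
        evecs = evecs.copy()
        evecs[:, 0] = -v1
    return evals, evecs


def mc1_extents(positions: np.ndarray, v1: np.ndarray) -> tuple[float, float]:
    """Horizontal and vertical extent of the path along MC1.

    The MC1 score range ``L`` between the 10% and 90% quantiles is split
    into its horizontal and vertical parts by the orientation of v1:
    ``horizontal = L * ||v1_xy||``, ``vertical = L * |v1_z|``.
    """
    p = np.asarray(positions, float)
    v1 = np.asarray(v1, float)
    s = (p - p.mean(axis=0)) @ v1
    length = float(np.quantile(s, _QHI) - np.quantile(s, _QLO))
    return length * float(np.hypot(v1[0], v1[1])), length * float(abs(v1[2]))


def plane_widths(
    positions: np.ndarray, v1: np.ndarray, vertical_tol_deg: float = 1.0
) -> tuple[float, float, bool]:
    """Horizontal and vertical widths about the MC1 axis.

    Plane A passes through the centroid and spans v1 and the gravity
    (vertical) direction; the horizontal width is the 10%-90% quantile
    range of signed point-to-plane distances.  Plane B spans v1 and plane
    A's normal; signed distances to it give the vertical width.  When v1
    is within ``vertical_tol_deg`` of vertical the horizontal direction of
    plane A is arbitrary; a fixed east azimuth is used and the result is
    flagged.
    """
    p = np.asarray(positions, float)
    v1 = np.asarray(v1, float) / np.linalg.norm(v1)
    centered = p - p.mean(axis=0)
    zhat = np.array([0.0, 0.0, 1.0])
    flagged = False
    n_a = np.cross(v1, zhat)
    if np.linalg.norm(n_a) < np.sin(np.deg2rad(vertical_tol_deg)):
        # v1 (anti)parallel to gravity: pick an arbitrary fixed azimuth
        n_a = np.cross(v1, np.array([1.0, 0.0, 0.0]))
        flagged = True
    n_a = n_a / np.linalg.norm(n_a)
    n_b = np.cross(v1, n_a)
    n_b = n_b / np.linalg.norm(n_b)
    d_a = centered @ n_a
    d_b = centered @ n_b
    horizontal_width = float(np.quantile(d_a, _QHI) - np.quantile(d_a, _QLO))
    vertical_width = float(np.quantile(d_b, _QHI) - np.quantile(d_b, _QLO))
    return horizontal_width, vertical_width, flagged


def assemble_metrics(dive, track, speed, pees) -> ShapeMetrics:
    """All shape descriptors for one dive's bottom phase.

    Parameters
    ----------
    dive : DiveRecord with bottom bounds set.
    track : Track3D over the whole dive (1 Hz, aligned to dive.start).
    speed : SpeedSeries or array over the whole dive.
    pees : list of PeeEvent; counted when the event midpoint falls in the
        bottom interval.
    """
    from .attitude_and_speed import SpeedSeries

    a = dive.descent_end - dive.start
    b = dive.ascent_start - dive.start
    positions = track.positions[a : b + 1]
    evals, evecs = eigen_shape(positions)
    v1 = evecs[:, 0]
    total = float(evals.sum())
    h_ext, v_ext = mc1_extents(positions, v1)
    h_wid, v_wid, flagged = plane_widths(positions, v1)
    v_arr = speed.speed if isinstance(speed, SpeedSeries) else np.asarray(speed, float)
    v_bottom = v_arr[a : b + 1]
    v_bottom = v_bottom[np.isfinite(v_bottom)]
    pee_count = sum(
        1 for ev in pees if dive.descent_end <= ev.midpoint <= dive.ascent_start
    )
    return ShapeMetrics(
        dive_id=dive.dive_id,
        mean_depth=float(-positions[:, 2].mean()),
        eigenvalues=evals,
        eigenvectors=evecs,
        total_dispersion=total,
        mc1_dispersion=float(evals[0] / total) if total > 0 else np.nan,
        horizontality=float(np.hypot(v1[0], v1[1])),
        mc1_horizontal_extent=h_ext,
        mc1_vertical_extent=v_ext,
        horizontal_width=h_wid,
        vertical_width=v_wid,
        speed_sd=float(v_bottom.std(ddof=1)) if v_bottom.size > 1 else np.nan,
        bottom_duration=float(b - a),
        pee_count=int(pee_count),
        vertical_v1_flagged=flagged,
    )
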