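"""Probe-trajectory geometry: straight-line fits to traced tracks and
targeting-variability metrics.

All coordinates are (AP, ML, DV) in micrometres in a single right-handed
atlas frame; DV increases with depth, so the brain surface is the plane
DV = 0 unless an explicit surface function is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Trajectory",
    "PLANNED_REPEATED_SITE",
    "fit_trajectory",
    "surface_displacement",
    "angle_difference",
]


@dataclass
class Trajectory:
    """A straight-line insertion: surface entry point plus unit direction.

    ``direction`` is normalized on construction and oriented so that its DV
    component is non-negative (pointing into the brain).
    """

    entry: np.ndarray
    direction: np.ndarray
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("trajectory direction must be non-zero")
        d = d / norm
        if d[2] < 0:
            d = -d
        self.direction = d

    def point_at(self, t: float) -> np.ndarray:
        return self.entry + t * self.direction


def _repeated_site() -> Trajectory:
    # Planned target 2.0 mm AP, -2.24 mm ML at the surface, advanced at a
    # 15 degree angle from vertical (tilt in the ML plane).
    ang = np.deg2rad(15.0)
    return Trajectory(
        entry=np.array([2000.0, -2240.0, 0.0]),
        direction=np.array([0.0, np.sin(ang), np.cos(ang)]),
        source="planned",
    )


#: The single planned insertion shared by every lab.
PLANNED_REPEATED_SITE = _repeated_site()


def fit_trajectory(
    track_points: Sequence[Sequence[float]] | np.ndarray,
    surface: Optional[Callable[[float, float], float]] = None,
    source: str = "histology",
) -> Trajectory:
    """Fit a 3D line to traced track points by total least squares.

    The line is the first principal axis of the point cloud through its
    centroid; the entry point is its intersection with the brain surface
    (the plane DV = 0 by default, or ``surface(ap, ml) -> dv`` if given).

    Parameters
    ----------
    track_points
        (n, 3) array of (AP, ML, DV) coordinates, n >= 2, not all coincident.
    surface
        Optional surface height function; solved by root finding along the
        line when supplied.
    """
    pts = np.asarray(track_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("track_points must be an (n>=2, 3) array")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError("track points are coincident; no line is defined")
    # First right singular vector = direction minimizing orthogonal residuals.
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction[2] < 0:
        direction = -direction
    if abs(direction[2]) < 1e-12:
        raise ValueError("trajectory is parallel to the surface plane")
    if surface is None:
        t_entry = -centroid[2] / direction[2]
    else:
        def gap(t: float) -> float:
            p = centroid + t * direction
            return p[2] - surface(p[0], p[1])

        t0 = -centroid[2] / direction[2]
        lo, hi = t0 - 5000.0, t0 + 5000.0
        # Expand the bracket until the surface gap changes sign.
        for _ in range(20):
            if gap(lo) * gap(hi) <= 0:
                break
            lo -= 5000.0
            hi += 5000.0
        t_entry = brentq(gap, lo, hi)
    entry = centroid + t_entry * direction
    return Trajectory(entry=entry, direction=direction, source=source)


def surface_displacement(
    traj: Trajectory, planned: Trajectory
) -> tuple[float, float, float]:
    """Surface-entry displacement (dAP, dML, Euclidean distance) in um.

    The Euclidean distance is taken in the AP/ML surface plane, matching how
    targeting scatter is reported.
    """
    d_ap = float(traj.entry[0] - planned.entry[0])
    d_ml = float(traj.entry[1] - planned.entry[1])
    return d_ap, d_ml, float(np.hypot(d_ap, d_ml))


def angle_difference(
    traj: Trajectory, planned: Trajectory
) -> tuple[float, float, float]:
    """Angle between two insertions in degrees.

    Returns ``(angle_3d, angle_ml, angle_ap)``: the full 3D angle
    (arccos of the absolute dot product, since traced directions carry a
    sign ambiguity) and its projections onto the coronal (ML/DV) and
    sagittal (AP/DV) planes.
    """
    d1, d2 = traj.direction, planned.direction
    cos3 = np.clip(abs(float(np.dot(d1, d2))), 0.0, 1.0)
    angle_3d = float(np.degrees(np.arccos(cos3)))

    def _plane_angle(i: int) -> float:
        a = np.array([d1[i], d1[2]])
        b = np.array([d2[i], d2[2]])
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-12 or nb < 1e-12:
            return 0.0
        c = np.clip(abs(float(np.dot(a, b))) / (na * nb), 0.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    return angle_3d, _plane_angle(1), _plane_angle(0)
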