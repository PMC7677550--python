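"""Trajectory-shape features: movement focus, concentricity, head scans."""

from __future__ import annotations

import numpy as np

from ..core import TrajectorySeries
from ..errors import InsufficientDataError
from ..geometry import SceneGeometry
from .kinematics import smoothed_speed

__all__ = ["trajectory_shape_features", "head_scan_count"]

GRID_CELL = 0.25  # m
SCAN_THRESHOLD = 30.0  # deg, yaw excursion from heading
SCAN_RETURN = 3.0  # s, excursion must return within this time
WALK_SPEED = 0.2  # m/s, "while walking" threshold
CONCENTRIC_TOL = 45.0  # deg around the tangential direction


def trajectory_shape_features(
    traj: TrajectorySeries, geometry: SceneGeometry
) -> dict[str, float]:
    """Movement focus (occupancy entropy) and concentric path fraction.

    ``focus = 1 - H(p) / log K`` over the dwell distribution ``p`` of the
    ``K`` visited grid cells (1 when all time is in one cell, toward 0 for a
    uniform spread).  ``concentric`` is the fraction of traveled path whose
    direction lies within +/-45 deg of the tangent to the circle through the
    current point centered at the room center.
    """
    if traj.n < 3:
        raise InsufficientDataError("shape features need >= 3 samples")
    nx = int(np.ceil(geometry.room_width / GRID_CELL))
    ny = int(np.ceil(geometry.room_length / GRID_CELL))
    ix = np.clip((traj.x / GRID_CELL).astype(int), 0, nx - 1)
    iy = np.clip((traj.y / GRID_CELL).astype(int), 0, ny - 1)
    _, counts = np.unique(ix * ny + iy, return_counts=True)
    p = counts / counts.sum()
    k = p.size
    if k == 1:
        focus = 1.0
    else:
        entropy = -np.sum(p * np.log(p))
        focus = 1.0 - entropy / np.log(k)

    cx = geometry.room_width / 2.0
    cy = geometry.room_length / 2.0
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    step = np.hypot(dx, dy)
    moving = step > 1e-6
    concentric = float("nan")
    if moving.any():
        rx = traj.x[:-1] - cx
        ry = traj.y[:-1] - cy
        # angle between step direction and the tangential direction (+/-90
        # deg from the radial direction)
        dot_rad = dx * rx + dy * ry
        r = np.hypot(rx, ry)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_rad = np.abs(dot_rad) / (step * r)
        cos_rad = np.clip(cos_rad, 0.0, 1.0)
        ang_from_tangent = 90.0 - np.rad2deg(np.arccos(cos_rad))
        ok = (ang_from_tangent <= CONCENTRIC_TOL) & moving & (r > 1e-9)
        concentric = float(step[ok].sum() / step[moving].sum())
    return {"focus": float(focus), "concentric": concentric}


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    return (a + 180.0) % 360.0 - 180.0


def head_scan_count(traj: TrajectorySeries) -> dict[str, float]:
    """Count yaw excursions from heading (> 30 deg, returning within 3 s)
    initiated while walking (> 0.2 m/s)."""
    if traj.n < 3:
        raise InsufficientDataError("head scans need >= 3 samples")
    dt = traj.dt
    speed, _ = smoothed_speed(traj)
    vx = np.gradient(traj.x, dt)
    vy = np.gradient(traj.y, dt)
    heading = np.rad2deg(np.arctan2(vy, vx))
    moving = speed > 0.05
    if moving.any():
        idx = np.where(moving, np.arange(traj.n), -1)
        np.maximum.accumulate(idx, out=idx)
        heading = np.where(idx >= 0, heading[np.clip(idx, 0, None)], heading)
    dev = np.abs(_wrap_deg(traj.yaw - heading))
    out = dev > SCAN_THRESHOLD
    walking = speed > WALK_SPEED

    count = 0
    i = 0
    max_len = int(round(SCAN_RETURN / dt))
    while i < traj.n:
        if out[i] and walking[i]:
            j = i
            while j < traj.n and out[j]:
                j += 1
            # must return to baseline (excursion ended) within the window
            if j < traj.n and (j - i) <= max_len:
                count += 1
            i = j
        else:
            i += 1
    walked_min = walking.sum() * dt / 60.0
    per_min = count / walked_min if walked_min > 0 else 0.0
    return {"head_scan_count": float(count), "head_scans_per_min": float(per_min)}
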