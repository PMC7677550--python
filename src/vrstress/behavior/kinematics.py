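"""Velocity/acceleration features from the head trajectory.

Derivatives use central differences after a 0.5 s moving-average smoothing
of the position channels; the trajectory is linearly resampled to a uniform
grid first.
"""

from __future__ import annotations

import numpy as np

from ..core import TrajectorySeries
from ..errors import InsufficientDataError

__all__ = ["kinematics_features", "smoothed_speed", "SMOOTH_WINDOW"]

SMOOTH_WINDOW = 0.5  # s


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return x
    kernel = np.ones(win) / win
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + x.size]
    return out


def _uniform(traj: TrajectorySeries) -> TrajectorySeries:
    if traj.n < 2:
        return traj
    dts = np.diff(traj.t)
    if np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        return traj
    return traj.resample(1.0 / np.median(dts))


def smoothed_speed(traj: TrajectorySeries) -> tuple[np.ndarray, np.ndarray]:
    """(horizontal speed, vertical speed) on the uniform grid, smoothed."""
    traj = _uniform(traj)
    dt = traj.dt
    win = max(1, int(round(SMOOTH_WINDOW / dt)))
    x = _moving_average(traj.x, win)
    y = _moving_average(traj.y, win)
    z = _moving_average(traj.z, win)
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    vz = np.gradient(z, dt)
    return np.hypot(vx, vy), vz


def kinematics_features(traj: TrajectorySeries) -> dict[str, float]:
    """Speed, acceleration and path-length summaries."""
    if traj.n < 3:
        raise InsufficientDataError("kinematics needs >= 3 samples")
    traj = _uniform(traj)
    dt = traj.dt
    win = max(1, int(round(SMOOTH_WINDOW / dt)))
    x = _moving_average(traj.x, win)
    y = _moving_average(traj.y, win)
    z = _moving_average(traj.z, win)
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    vz = np.gradient(z, dt)
    speed = np.hypot(vx, vy)
    ax = np.gradient(vx, dt)
    ay = np.gradient(vy, dt)
    az = np.gradient(vz, dt)
    acc_h = np.hypot(ax, ay)
    # edge-padded smoothing bends the first/last window into spurious
    # curvature; exclude those samples from the acceleration statistics
    if traj.n > 4 * win:
        acc_h = acc_h[win:-win]
        az = az[win:-win]
    return {
        "speed_mean": float(speed.mean()),
        "speed_sd": float(speed.std(ddof=1)) if speed.size > 1 else 0.0,
        "speed_max": float(speed.max()),
        "horiz_acc_rms": float(np.sqrt(np.mean(acc_h**2))),
        "vert_acc_rms": float(np.sqrt(np.mean(az**2))),
        "path_length": float(np.sum(np.hypot(np.diff(x), np.diff(y)))),
    }
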