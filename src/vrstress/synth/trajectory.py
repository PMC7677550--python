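"""Room-constrained exploratory head trajectories.

The empty-room walk is a biased random-waypoint process: waypoints are drawn
from a mixture of a wall-adjacent band (mixture weight = ``thigmotaxis_bias``)
and the full interior, with waypoints in the center zone resampled with
probability ``center_avoidance``.  Successive waypoints are constrained to a
maximum jump distance so a pure wall-hugger actually travels along the walls
instead of cutting across the room.  Head yaw follows the instantaneous
heading plus scripted square-pulse scan excursions (amplitude 40 deg,
duration 1 s) at a Poisson rate of ``scan_rate`` per walked minute.

The elevated-alley walk is a forward/backward progression along the alley
axis whose farthest excursion shrinks with ``center_avoidance``.
"""

from __future__ import annotations

import numpy as np

from ..core import TrajectorySeries
from ..errors import InvalidArgumentError
from ..geometry import SceneGeometry, DEFAULT_GEOMETRY
from .traits import TraitProfile

__all__ = ["simulate_trajectory", "simulate_alley_trajectory"]

WALL_BAND = 0.35  # m, width of the wall-adjacent waypoint band
MAX_JUMP = 2.0  # m, max distance between successive waypoints
SCAN_AMPLITUDE = 40.0  # deg
SCAN_DURATION = 1.0  # s
PAUSE_MEAN = 1.5  # s, mean dwell at a waypoint
HEAD_HEIGHT = 1.7  # m
HEAD_BOB_AMP = 0.02  # m


def _draw_waypoint(
    rng: np.random.Generator,
    geometry: SceneGeometry,
    profile: TraitProfile,
    current: np.ndarray,
) -> np.ndarray:
    w, l = geometry.room_width, geometry.room_length
    for _ in range(200):
        if rng.random() < profile.thigmotaxis_bias:
            # point in the wall band: pick a wall, then a position along it
            side = rng.integers(4)
            d = rng.uniform(0.0, WALL_BAND)
            if side == 0:
                p = np.array([rng.uniform(0, w), d])
            elif side == 1:
                p = np.array([rng.uniform(0, w), l - d])
            elif side == 2:
                p = np.array([d, rng.uniform(0, l)])
            else:
                p = np.array([w - d, rng.uniform(0, l)])
        else:
            p = np.array([rng.uniform(0, w), rng.uniform(0, l)])
        if geometry.in_center(p[0], p[1]) and rng.random() < profile.center_avoidance:
            continue  # resample: avoid the exposed center
        if np.linalg.norm(p - current) <= MAX_JUMP:
            return p
    return current  # pathological profile; stay put


def _walk_segments(
    rng: np.random.Generator,
    geometry: SceneGeometry,
    profile: TraitProfile,
    duration: float,
    start: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear path as (times, positions) knot arrays."""
    knots_t = [0.0]
    knots_p = [start.copy()]
    t = 0.0
    pos = start.copy()
    sigma = np.sqrt(np.log(1.0 + profile.gait_speed_cv**2))
    mu = np.log(max(profile.walk_speed, 1e-9)) - 0.5 * sigma**2
    while t < duration:
        target = _draw_waypoint(rng, geometry, profile, pos)
        dist = np.linalg.norm(target - pos)
        if dist < 1e-9 or profile.walk_speed <= 0:
            t += PAUSE_MEAN
            knots_t.append(t)
            knots_p.append(pos.copy())
            continue
        speed = float(np.exp(mu + sigma * rng.standard_normal()))
        speed = min(max(speed, 0.05), 2.5)
        t += dist / speed
        knots_t.append(t)
        knots_p.append(target.copy())
        pos = target
        pause = rng.exponential(PAUSE_MEAN)
        if pause > 0.05:
            t += pause
            knots_t.append(t)
            knots_p.append(pos.copy())
    return np.asarray(knots_t), np.asarray(knots_p)


def _scan_offsets(
    rng: np.random.Generator,
    t: np.ndarray,
    walking: np.ndarray,
    scan_rate: float,
) -> tuple[np.ndarray, int]:
    """Square-pulse yaw offsets from Poisson-timed scans while walking."""
    offsets = np.zeros_like(t)
    if scan_rate <= 0:
        return offsets, 0
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    walked_min = walking.sum() * dt / 60.0
    n_events = rng.poisson(scan_rate * walked_min)
    walk_idx = np.flatnonzero(walking)
    count = 0
    if walk_idx.size == 0 or n_events == 0:
        return offsets, 0
    starts = np.sort(rng.choice(walk_idx, size=n_events, replace=False))
    last_end = -1
    for i0 in starts:
        i1 = i0 + int(round(SCAN_DURATION / dt)) if dt > 0 else i0
        if i0 <= last_end or i1 >= t.size:
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        offsets[i0:i1] += sign * SCAN_AMPLITUDE
        last_end = i1 + int(round(0.5 / dt)) if dt > 0 else i1
        count += 1
    return offsets, count


def simulate_trajectory(
    profile: TraitProfile,
    geometry: SceneGeometry = DEFAULT_GEOMETRY,
    duration: float = 90.0,
    rate: float = 90.0,
    seed: int | np.random.Generator = 0,
) -> tuple[TrajectorySeries, dict]:
    """Simulate an empty-room head trajectory.

    Returns the trajectory and a ground-truth dict with the number of
    scripted head scans (``n_scans``) and the waypoint knots.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be > 0")
    if rate < 10:
        raise InvalidArgumentError("rate must be >= 10 Hz")
    rng = np.random.default_rng(seed)
    start = np.array([geometry.room_width / 2.0, 0.3])
    knots_t, knots_p = _walk_segments(rng, geometry, profile, duration, start)

    t = np.arange(0.0, duration, 1.0 / rate)
    x = np.interp(t, knots_t, knots_p[:, 0])
    y = np.interp(t, knots_t, knots_p[:, 1])
    x = np.clip(x, 0.0, geometry.room_width)
    y = np.clip(y, 0.0, geometry.room_length)

    vx = np.gradient(x, t) if t.size > 1 else np.zeros_like(x)
    vy = np.gradient(y, t) if t.size > 1 else np.zeros_like(y)
    speed = np.hypot(vx, vy)
    heading = np.rad2deg(np.arctan2(vy, vx))
    # hold last heading through standstills
    moving = speed > 0.05
    if moving.any():
        idx = np.where(moving, np.arange(t.size), -1)
        np.maximum.accumulate(idx, out=idx)
        heading = np.where(idx >= 0, heading[np.clip(idx, 0, None)], heading)

    walking = speed > 0.2
    scan_off, n_scans = _scan_offsets(rng, t, walking, profile.scan_rate)
    yaw = heading + scan_off

    z = HEAD_HEIGHT + HEAD_BOB_AMP * np.sin(2 * np.pi * 1.8 * t) * (speed > 0.05)
    traj = TrajectorySeries(t=t, x=x, y=y, z=z, yaw=yaw)
    truth = {"n_scans": n_scans, "knots_t": knots_t, "knots_p": knots_p}
    return traj, truth


def simulate_alley_trajectory(
    profile: TraitProfile,
    geometry: SceneGeometry = DEFAULT_GEOMETRY,
    duration: float = 90.0,
    rate: float = 90.0,
    seed: int | np.random.Generator = 0,
) -> tuple[TrajectorySeries, dict]:
    """Simulate an elevated-alley trajectory.

    The subject advances along the alley axis toward a farthest excursion
    ``y_max`` that shrinks with ``center_avoidance``, with occasional
    retreats toward the board; lateral position stays within the local patch
    width.  Returns the trajectory and a truth dict with ``y_max``.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be > 0")
    if rate < 10:
        raise InvalidArgumentError("rate must be >= 10 Hz")
    rng = np.random.default_rng(seed)
    end = geometry.alley_end
    reach = (1.0 - profile.center_avoidance) * (end - geometry.board_length)
    y_max = geometry.board_length + max(0.0, reach + 0.3 * rng.standard_normal())
    y_max = float(np.clip(y_max, 0.2, end - 0.05))

    # waypoint sequence along y: advance / retreat cycles
    knots_t = [0.0]
    knots_y = [0.1]
    t = 0.0
    y = 0.1
    sigma = np.sqrt(np.log(1.0 + profile.gait_speed_cv**2))
    mu = np.log(max(profile.walk_speed, 1e-9)) - 0.5 * sigma**2
    going_out = True
    while t < duration:
        if going_out:
            target = y_max * rng.uniform(0.6, 1.0)
        else:
            target = rng.uniform(0.0, geometry.board_length)
        going_out = not going_out
        dist = abs(target - y)
        if dist < 1e-6 or profile.walk_speed <= 0:
            t += PAUSE_MEAN
        else:
            speed = float(np.exp(mu + sigma * rng.standard_normal()))
            speed = min(max(speed, 0.05), 2.5)
            t += dist / speed
        knots_t.append(t)
        knots_y.append(target)
        y = target
        dwell = rng.exponential(2.0 + 4.0 * profile.center_avoidance)
        t += dwell
        knots_t.append(t)
        knots_y.append(y)

    tt = np.arange(0.0, duration, 1.0 / rate)
    yy = np.interp(tt, knots_t, knots_y)
    yy = np.clip(yy, 0.0, end)
    half_w = geometry.alley_half_width(yy)
    lateral = 0.15 * np.sin(2 * np.pi * 0.1 * tt + rng.uniform(0, 2 * np.pi))
    xx = geometry.room_width / 2.0 + np.clip(lateral, -0.9, 0.9) * half_w

    vy = np.gradient(yy, tt) if tt.size > 1 else np.zeros_like(yy)
    heading = np.where(vy >= 0, 90.0, -90.0)
    speed = np.abs(vy)
    z = HEAD_HEIGHT + HEAD_BOB_AMP * np.sin(2 * np.pi * 1.8 * tt) * (speed > 0.05)
    traj = TrajectorySeries(t=tt, x=xx, y=yy, z=z, yaw=heading)
    return traj, {"y_max": y_max}
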