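"""Zone-occupancy ("position tracking") features for the two scenes."""

from __future__ import annotations

import warnings

import numpy as np

from ..core import TrajectorySeries
from ..errors import InvalidArgumentError
from ..geometry import SceneGeometry

__all__ = ["position_features_er", "position_features_ea", "RETREAT_HYSTERESIS"]

GRID_CELL = 0.25  # m, occupancy grid resolution
RETREAT_HYSTERESIS = 0.2  # m, minimum backward excursion counted as a retreat


def _check_bounds(traj: TrajectorySeries, geometry: SceneGeometry) -> None:
    if not np.all(geometry.contains(traj.x, traj.y, tol=1e-3)):
        raise InvalidArgumentError("trajectory leaves the room bounds")


def position_features_er(
    traj: TrajectorySeries, geometry: SceneGeometry
) -> dict[str, float]:
    """Empty-room occupancy features (corner/wall distances, center time)."""
    _check_bounds(traj, geometry)
    dt = traj.dt if traj.n > 1 else 0.0
    duration = traj.n * dt
    corner_d = geometry.corner_distance(traj.x, traj.y)
    wall_d = geometry.wall_distance(traj.x, traj.y)
    in_center = geometry.in_center(traj.x, traj.y)
    time_center = float(in_center.sum() * dt)
    time_periph = float((~in_center).sum() * dt)
    if time_periph <= 0:
        warnings.warn(
            "no periphery time; center/periphery ratio capped", stacklevel=2
        )
        ratio = duration / dt if dt > 0 else float("nan")
    else:
        ratio = time_center / time_periph

    # occupancy-grid coverage
    nx = int(np.ceil(geometry.room_width / GRID_CELL))
    ny = int(np.ceil(geometry.room_length / GRID_CELL))
    ix = np.clip((traj.x / GRID_CELL).astype(int), 0, nx - 1)
    iy = np.clip((traj.y / GRID_CELL).astype(int), 0, ny - 1)
    visited = np.unique(ix * ny + iy).size
    coverage = visited / (nx * ny)

    if in_center.any():
        latency = float(traj.t[np.argmax(in_center)] - traj.t[0])
    else:
        latency = float(duration)

    return {
        "corner_dist_min": float(corner_d.min()),
        "corner_dist_mean": float(corner_d.mean()),
        "wall_dist_mean": float(wall_d.mean()),
        "time_center": time_center,
        "time_periphery": time_periph,
        "ratio_time_center_periphery": float(ratio),
        "coverage_fraction": float(coverage),
        "latency_first_center_entry": latency,
    }


def position_features_ea(
    traj: TrajectorySeries, geometry: SceneGeometry
) -> dict[str, float]:
    """Elevated-alley progression features (patch dwell, crossings, retreats)."""
    _check_bounds(traj, geometry)
    dt = traj.dt if traj.n > 1 else 0.0
    y = traj.y
    t = traj.t
    out: dict[str, float] = {}
    patch = geometry.patch_index(y)
    n_patches = len(geometry.patch_widths)
    for k in range(n_patches):
        out[f"time_patch_{k + 1}"] = float((patch == k).sum() * dt)
    out["time_narrow"] = out[f"time_patch_{n_patches}"]
    out["time_board"] = float((y < geometry.board_length).sum() * dt)
    # first crossing of each internal patch threshold; censored at the
    # recording duration when the threshold is never reached
    duration = float(t[-1] - t[0]) if traj.n > 1 else 0.0
    for k, edge in enumerate(geometry.patch_edges[1:-1], start=1):
        crossed = y >= edge
        out[f"first_cross_{k}"] = (
            float(t[np.argmax(crossed)] - t[0]) if crossed.any() else duration
        )
    out["max_longitudinal"] = float(y.max())

    # retreats: backward excursions of at least RETREAT_HYSTERESIS from a
    # running forward extreme
    retreats = 0
    peak = y[0]
    retreating = False
    for yi in y[1:]:
        if not retreating:
            peak = max(peak, yi)
            if peak - yi >= RETREAT_HYSTERESIS:
                retreats += 1
                retreating = True
                trough = yi
        else:
            trough = min(trough, yi)
            if yi - trough >= RETREAT_HYSTERESIS:
                retreating = False
                peak = yi
    out["n_retreats"] = float(retreats)
    return out
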