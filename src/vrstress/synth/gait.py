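"""Foot-track synthesis from a head trajectory.

Heel strikes are laid down alternately left/right every half stride along
the walked path (path segments where horizontal head speed exceeds the
immobility threshold).  Between consecutive ipsilateral strikes the foot is
stationary on the ground for the stance phase and then swings to the next
strike position along a vertical arc.  True heel-strike times are returned
for oracle tests.
"""

from __future__ import annotations

import numpy as np

from ..core import FootTracks, TrajectorySeries
from ..errors import InvalidArgumentError
from .traits import TraitProfile

__all__ = ["simulate_gait"]

STRIDE_LENGTH = 0.7  # m, per-foot stride (two steps)
STANCE_FRACTION = 0.6
SWING_LIFT = 0.06  # m
LATERAL_OFFSET = 0.10  # m
WALK_THRESHOLD = 0.15  # m/s head speed counted as walking


def simulate_gait(
    head_track: TrajectorySeries,
    profile: TraitProfile,
    seed: int | np.random.Generator = 0,
    rate: float = 60.0,
    stride_length: float = STRIDE_LENGTH,
) -> tuple[FootTracks, dict]:
    """Synthesize left/right foot tracks following the head path.

    Returns the tracks and a truth dict with per-foot heel-strike times
    (``heel_strikes = {"left": [...], "right": [...]}``).
    """
    if head_track.n == 0:
        raise InvalidArgumentError("head_track must be non-empty")
    rng = np.random.default_rng(seed)
    t = head_track.t
    x, y = head_track.x, head_track.y
    if t.size < 2:
        tm = np.arange(0.0, 1.0, 1.0 / rate)
        flat = np.column_stack(
            [np.full_like(tm, x[0]), np.full_like(tm, y[0]), np.zeros_like(tm)]
        )
        return (
            FootTracks(t=tm, left=flat.copy(), right=flat.copy()),
            {"heel_strikes": {"left": np.array([]), "right": np.array([])}},
        )

    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    walking = speed > WALK_THRESHOLD

    # cumulative walked path length (frozen while immobile)
    seg = np.hypot(np.diff(x), np.diff(y))
    seg = np.where(walking[:-1] & walking[1:], seg, 0.0)
    s = np.concatenate([[0.0], np.cumsum(seg)])

    step = stride_length / 2.0
    strikes = []  # (time, x, y, foot)
    next_s = step / 2.0
    foot = 0  # 0 = left, 1 = right
    for i in range(1, t.size):
        while s[i] >= next_s and s[i] > s[i - 1]:
            frac = (next_s - s[i - 1]) / (s[i] - s[i - 1])
            ts = t[i - 1] + frac * (t[i] - t[i - 1])
            px = x[i - 1] + frac * (x[i] - x[i - 1])
            py = y[i - 1] + frac * (y[i] - y[i - 1])
            hx = x[i] - x[i - 1]
            hy = y[i] - y[i - 1]
            norm = np.hypot(hx, hy) or 1.0
            side = -1.0 if foot == 0 else 1.0
            px += side * LATERAL_OFFSET * (-hy / norm)
            py += side * LATERAL_OFFSET * (hx / norm)
            strikes.append((ts, px, py, foot))
            foot = 1 - foot
            next_s += step

    tm = np.arange(t[0], t[-1], 1.0 / rate)
    tracks = {}
    truth = {"heel_strikes": {}}
    head_x = np.interp(tm, t, x)
    head_y = np.interp(tm, t, y)
    for foot_id, name, side in ((0, "left", -1.0), (1, "right", 1.0)):
        own = [sk for sk in strikes if sk[3] == foot_id]
        truth["heel_strikes"][name] = np.array([sk[0] for sk in own])
        fx = np.full_like(tm, head_x[0] + side * LATERAL_OFFSET)
        fy = head_y.copy() * 0 + head_y[0]
        fz = np.zeros_like(tm)
        if own:
            # before first strike: stationary at initial position
            for k in range(len(own)):
                ts, px, py, _ = own[k]
                if k + 1 < len(own):
                    tn, nx, ny, _ = own[k + 1]
                else:
                    tn, nx, ny = t[-1] + 1.0, px, py
                stance_end = ts + STANCE_FRACTION * (tn - ts)
                m_stance = (tm >= ts) & (tm < stance_end)
                fx[m_stance] = px
                fy[m_stance] = py
                m_swing = (tm >= stance_end) & (tm < tn)
                if m_swing.any() and tn > stance_end:
                    u = (tm[m_swing] - stance_end) / (tn - stance_end)
                    fx[m_swing] = px + u * (nx - px)
                    fy[m_swing] = py + u * (ny - py)
                    fz[m_swing] = SWING_LIFT * np.sin(np.pi * u)
            first = own[0][0]
            m0 = tm < first
            fx[m0] = own[0][1]
            fy[m0] = own[0][2]
            last_t, last_x, last_y, _ = own[-1]
            m1 = tm >= last_t
            # handled above (stance continues to end)
        tracks[name] = np.column_stack([fx, fy, fz])
    return FootTracks(t=tm, left=tracks["left"], right=tracks["right"]), truth
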