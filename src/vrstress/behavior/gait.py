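"""Gait-cycle detection from foot tracks and movement-burst segmentation.

A foot contact is a run where foot speed stays below 0.15 m/s for at least
0.1 s with the foot height in its lowest quartile; the heel strike is the
run onset and the toe-off its end.  Strides join consecutive ipsilateral
strikes.  Bursts are maximal runs of gait cycles (pooled strikes) separated
by gaps shorter than 1.5 s; immobility is horizontal head speed below
0.1 m/s sustained for at least 2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import FootTracks, TrajectorySeries
from .kinematics import smoothed_speed

__all__ = ["GaitEvents", "Stride", "detect_gait_cycles", "detect_bursts", "gait_features"]

CONTACT_SPEED = 0.15  # m/s
CONTACT_MIN_DURATION = 0.1  # s
HEIGHT_QUANTILE = 0.25
IMMOBILITY_SPEED = 0.1  # m/s
IMMOBILITY_MIN_DURATION = 2.0  # s
BURST_GAP = 1.5  # s


@dataclass
class Stride:
    start: float
    end: float
    length: float  # m
    speed: float  # m/s
    stance_fraction: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GaitEvents:
    heel_strikes: dict[str, np.ndarray] = field(
        default_factory=lambda: {"left": np.array([]), "right": np.array([])}
    )
    toe_offs: dict[str, np.ndarray] = field(
        default_factory=lambda: {"left": np.array([]), "right": np.array([])}
    )
    strides: list[Stride] = field(default_factory=list)

    @property
    def all_strikes(self) -> np.ndarray:
        return np.sort(
            np.concatenate([self.heel_strikes["left"], self.heel_strikes["right"]])
        )

    @property
    def n_strides(self) -> int:
        return len(self.strides)


def _contact_runs(t, pos, fs) -> list[tuple[int, int]]:
    """Index runs satisfying the contact rule for one foot."""
    v = np.gradient(pos, axis=0) * fs
    speed = np.linalg.norm(v, axis=1)
    z = pos[:, 2]
    low = z <= np.quantile(z, HEIGHT_QUANTILE) + 1e-3
    slow = speed < CONTACT_SPEED
    mask = slow & low
    runs = []
    i = 0
    n = mask.size
    min_len = max(1, int(round(CONTACT_MIN_DURATION * fs)))
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                runs.append((i, j - 1))
            i = j
        else:
            i += 1
    return runs


def detect_gait_cycles(foot_tracks: FootTracks) -> GaitEvents:
    """Detect heel strikes, toe-offs and strides; empty on failure."""
    events = GaitEvents()
    if foot_tracks is None or foot_tracks.n < 3:
        return events
    t = foot_tracks.t
    if t[-1] - t[0] < 2.0:
        return events
    fs = 1.0 / float(np.median(np.diff(t)))
    for name, pos in (("left", foot_tracks.left), ("right", foot_tracks.right)):
        runs = _contact_runs(t, pos, fs)
        strikes = np.array([t[a] for a, _ in runs])
        toeoffs = np.array([t[b] for _, b in runs])
        events.heel_strikes[name] = strikes
        events.toe_offs[name] = toeoffs
        for k in range(len(runs) - 1):
            a0, b0 = runs[k]
            a1, _ = runs[k + 1]
            start, end = t[a0], t[a1]
            dur = end - start
            if dur <= 0:
                continue
            p0 = pos[a0, :2]
            p1 = pos[a1, :2]
            length = float(np.linalg.norm(p1 - p0))
            stance = t[b0] - t[a0]
            stance_fraction = float(np.clip(stance / dur, 1e-6, 1 - 1e-6))
            events.strides.append(
                Stride(
                    start=float(start),
                    end=float(end),
                    length=length,
                    speed=length / dur,
                    stance_fraction=stance_fraction,
                )
            )
    events.strides.sort(key=lambda s: s.start)
    return events


def gait_features(events: GaitEvents) -> dict[str, float]:
    """Stride summaries; NaN when no strides were detected."""
    nan = float("nan")
    if events.n_strides == 0:
        return {
            "stride_count": 0.0,
            "stride_speed_mean": nan,
            "stride_speed_sd": nan,
            "stride_speed_cv": nan,
            "stride_length_mean": nan,
            "stride_length_sd": nan,
            "stride_duration_mean": nan,
            "stance_fraction_mean": nan,
            "cadence": 0.0,
        }
    speeds = np.array([s.speed for s in events.strides])
    lengths = np.array([s.length for s in events.strides])
    durations = np.array([s.duration for s in events.strides])
    stance = np.array([s.stance_fraction for s in events.strides])
    span_min = (
        (events.strides[-1].end - events.strides[0].start) / 60.0
        if events.n_strides > 1
        else nan
    )
    sd = float(speeds.std(ddof=1)) if speeds.size > 1 else 0.0
    return {
        "stride_count": float(events.n_strides),
        "stride_speed_mean": float(speeds.mean()),
        "stride_speed_sd": sd,
        "stride_speed_cv": sd / float(speeds.mean()) if speeds.mean() > 0 else nan,
        "stride_length_mean": float(lengths.mean()),
        "stride_length_sd": float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0,
        "stride_duration_mean": float(durations.mean()),
        "stance_fraction_mean": float(stance.mean()),
        "cadence": float(events.n_strides / span_min) if span_min and span_min > 0 else nan,
    }


def detect_bursts(
    events: GaitEvents, traj: TrajectorySeries
) -> dict[str, float]:
    """Movement-burst and immobility features."""
    duration = traj.duration
    dt = traj.dt if traj.n > 1 else 0.0
    speed, _ = smoothed_speed(traj) if traj.n > 2 else (np.zeros(traj.n), None)
    # immobility: sustained sub-threshold horizontal speed
    immobile_total = 0.0
    immobile_longest = 0.0
    mask = speed < IMMOBILITY_SPEED
    i = 0
    min_len = max(1, int(round(IMMOBILITY_MIN_DURATION / dt))) if dt > 0 else 1
    while i < mask.size:
        if mask[i]:
            j = i
            while j < mask.size and mask[j]:
                j += 1
            if j - i >= min_len:
                span = (j - i) * dt
                immobile_total += span
                immobile_longest = max(immobile_longest, span)
            i = j
        else:
            i += 1

    strikes = events.all_strikes
    if strikes.size == 0:
        return {
            "burst_count": 0.0,
            "burst_duration_mean": float("nan"),
            "burst_duration_max": float("nan"),
            "cycles_per_burst_mean": float("nan"),
            "immobility_total": float(immobile_total),
            "immobility_longest": float(immobile_longest),
        }
    gaps = np.diff(strikes)
    breaks = np.flatnonzero(gaps >= BURST_GAP)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [strikes.size - 1]])
    durations = strikes[ends] - strikes[starts]
    cycles = ends - starts + 1
    return {
        "burst_count": float(starts.size),
        "burst_duration_mean": float(durations.mean()),
        "burst_duration_max": float(durations.max()),
        "cycles_per_burst_mean": float(cycles.mean()),
        "immobility_total": float(immobile_total),
        "immobility_longest": float(immobile_longest),
    }
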