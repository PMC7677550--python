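"""Shared container types for raw session data.

These are deliberately thin: numpy arrays plus sampling metadata, with
validation in ``__post_init__``.  Heavier semantics (resampling, feature
extraction, detection) live in the processing modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "Waveform",
    "EcgSignal",
    "RespSignal",
    "TrajectorySeries",
    "FootTracks",
    "SessionRecording",
    "SCENARIOS",
]

SCENARIOS = ("empty_room", "elevated_alley", "dark_maze")


@dataclass
class Waveform:
    """A uniformly sampled 1-D signal."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidArgumentError("samples must be 1-D")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise InvalidArgumentError("fs must be positive and finite")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


class EcgSignal(Waveform):
    pass


class RespSignal(Waveform):
    pass


@dataclass
class TrajectorySeries:
    """Head-tracking time series: time, room-plane position, height, yaw."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    yaw: np.ndarray  # degrees

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("t", "x", "y", "z", "yaw"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 1:
                raise InvalidArgumentError(f"{name} must be 1-D")
            if n is None:
                n = a.size
            elif a.size != n:
                raise InvalidArgumentError("trajectory channels differ in length")
            if not np.all(np.isfinite(a)):
                raise InvalidArgumentError(f"{name} contains non-finite values")
            arrays[name] = a
        if n is not None and n >= 2 and np.any(np.diff(arrays["t"]) <= 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n > 1 else 0.0

    @property
    def dt(self) -> float:
        if self.n < 2:
            raise InvalidArgumentError("need >= 2 samples for dt")
        return float(np.median(np.diff(self.t)))

    def resample(self, rate: float) -> "TrajectorySeries":
        """Linear resampling to a uniform grid at ``rate`` Hz."""
        if rate <= 0:
            raise InvalidArgumentError("rate must be positive")
        t_new = np.arange(self.t[0], self.t[-1] + 0.5 / rate, 1.0 / rate)
        t_new = t_new[t_new <= self.t[-1] + 1e-12]
        out = {"t": t_new}
        for name in ("x", "y", "z"):
            out[name] = np.interp(t_new, self.t, getattr(self, name))
        # yaw interpolated on the unit circle to survive wrap-around
        yaw_rad = np.deg2rad(self.yaw)
        c = np.interp(t_new, self.t, np.cos(yaw_rad))
        s = np.interp(t_new, self.t, np.sin(yaw_rad))
        out["yaw"] = np.rad2deg(np.arctan2(s, c))
        return TrajectorySeries(**out)


@dataclass
class FootTracks:
    """Left/right foot positions from lower-body motion capture."""

    t: np.ndarray
    left: np.ndarray  # (n, 3) x, y, z
    right: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        for name in ("left", "right"):
            a = getattr(self, name)
            if a.ndim != 2 or a.shape[1] != 3:
                raise InvalidArgumentError(f"{name} must have shape (n, 3)")
            if a.shape[0] != self.t.size:
                raise InvalidArgumentError("foot tracks differ in length from t")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return self.t.size


@dataclass
class SessionRecording:
    """All raw channels for one subject in one scenario."""

    subject_id: str
    scenario_id: str
    head_track: TrajectorySeries
    foot_tracks: FootTracks | None = None
    ecg: EcgSignal | None = None
    respiration: RespSignal | None = None
    duration: float = 90.0

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIOS:
            raise InvalidArgumentError(
                f"unknown scenario {self.scenario_id!r}; expected one of {SCENARIOS}"
            )
        if self.duration <= 0:
            raise InvalidArgumentError("duration must be positive")
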