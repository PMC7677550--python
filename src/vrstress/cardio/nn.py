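"""Normal-to-normal interval series and artifact cleaning.

The artifact rule is a single pass: intervals further than 3 standard
deviations from the raw-series mean (plain moments, computed once) are
flagged and replaced by linear interpolation between the nearest unflagged
neighbors; flagged endpoints take the nearest unflagged value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InsufficientDataError, InvalidArgumentError
from .rpeaks import BeatSeries

__all__ = ["NNSeries", "nn_from_beats", "clean_rr"]


@dataclass
class NNSeries:
    """Interbeat intervals in ms with artifact flags and onset times."""

    intervals: np.ndarray  # ms
    artifact_flags: np.ndarray  # True where the value was interpolated
    onset_times: np.ndarray  # s, time of the beat opening each interval

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        if not (
            self.intervals.size == self.artifact_flags.size == self.onset_times.size
        ):
            raise InvalidArgumentError("NNSeries channels differ in length")
        if np.any(self.intervals <= 0):
            raise InvalidArgumentError("intervals must be positive")

    @property
    def n(self) -> int:
        return self.intervals.size


def nn_from_beats(beats: BeatSeries) -> NNSeries:
    """Raw (unflagged) interval series from beat times."""
    if beats.n < 2:
        raise InsufficientDataError("need >= 2 beats for intervals")
    intervals = np.diff(beats.r_times) * 1000.0
    return NNSeries(
        intervals=intervals,
        artifact_flags=np.zeros(intervals.size, dtype=bool),
        onset_times=beats.r_times[:-1],
    )


def clean_rr(beats: BeatSeries | NNSeries, n_sd: float = 3.0) -> NNSeries:
    """Flag |x - mean| > n_sd * SD intervals and interpolate across them."""
    if isinstance(beats, BeatSeries):
        if beats.n < 4:
            raise InsufficientDataError("need >= 4 beats to clean")
        nn = nn_from_beats(beats)
    else:
        nn = beats
        if nn.n < 3:
            raise InsufficientDataError("need >= 3 intervals to clean")
    x = nn.intervals.copy()
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    flags = np.abs(x - mean) > n_sd * sd if sd > 0 else np.zeros(x.size, dtype=bool)
    if flags.all():
        raise InsufficientDataError("every interval flagged as artifact")
    if flags.any():
        good = np.flatnonzero(~flags)
        bad = np.flatnonzero(flags)
        # np.interp holds endpoint values constant outside [good[0], good[-1]],
        # which implements the nearest-unflagged endpoint rule
        x[bad] = np.interp(bad, good, x[good])
    return NNSeries(
        intervals=x,
        artifact_flags=flags | nn.artifact_flags,
        onset_times=nn.onset_times,
    )
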