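"""Time-domain HRV metrics on NN series.

All functions accept either an :class:`~vrstress.cardio.nn.NNSeries` or a
plain array of intervals in milliseconds.
"""

from __future__ import annotations

import numpy as np

from ..errors import InsufficientDataError
from .nn import NNSeries

__all__ = ["rmssd", "sdnn", "hrv_ti", "heart_rate", "HRV_TI_BIN_MS"]

#: histogram bin width for the triangular index: 1/128 s, anchored at 0 ms
HRV_TI_BIN_MS = 1000.0 / 128.0


def _intervals(nn) -> np.ndarray:
    if isinstance(nn, NNSeries):
        return nn.intervals
    return np.asarray(nn, dtype=float)


def rmssd(nn) -> float:
    """Root mean square of successive differences, ms."""
    x = _intervals(nn)
    if x.size < 3:
        raise InsufficientDataError("rmssd needs >= 3 intervals")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d**2)))


def sdnn(nn) -> float:
    """Sample standard deviation (n-1 denominator) of the intervals, ms."""
    x = _intervals(nn)
    if x.size < 2:
        raise InsufficientDataError("sdnn needs >= 2 intervals")
    return float(np.std(x, ddof=1))


def hrv_ti(nn) -> float:
    """Triangular index: interval count / modal histogram bin count.

    Bin width 1/128 s (7.8125 ms), bins anchored at 0.
    """
    x = _intervals(nn)
    if x.size < 2:
        raise InsufficientDataError("hrv_ti needs >= 2 intervals")
    bins = np.floor(x / HRV_TI_BIN_MS).astype(int)
    counts = np.bincount(bins)
    return float(x.size / counts.max())


def heart_rate(nn) -> float:
    """Mean heart rate over the series: 60000 / mean NN (ms), in bpm."""
    x = _intervals(nn)
    if x.size < 1:
        raise InsufficientDataError("heart_rate needs >= 1 interval")
    return float(60000.0 / np.mean(x))
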