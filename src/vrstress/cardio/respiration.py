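"""Respiration-rate estimation by bandpassed peak counting.

The trace is FIR-bandpassed to 0.17-0.73 Hz; peaks must exceed one
robustified standard deviation (1.4826 x MAD) of the filtered trace, be
separated by at least 0.8 s and be at least 0.4 s wide at half prominence.
The rate is the qualifying peak count divided by the duration.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from ..core import RespSignal
from ..errors import InvalidArgumentError

__all__ = ["respiration_rate", "RESP_BAND"]

RESP_BAND = (0.17, 0.73)  # Hz
MIN_PEAK_GAP = 0.8  # s
MIN_PEAK_WIDTH = 0.4  # s


def _bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    lo, hi = RESP_BAND
    numtaps = int(round(6.0 * fs))  # ~6 s of taps resolves a 0.17 Hz edge
    numtaps += 1 - numtaps % 2  # odd length
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return sps.filtfilt(taps, [1.0], x)


def respiration_rate(resp: RespSignal) -> float:
    """Breaths per minute, or NaN (with a warning) if no peaks qualify."""
    if resp.fs < 25:
        raise InvalidArgumentError("fs must be >= 25 Hz")
    if resp.duration < 10.0:
        raise InvalidArgumentError("need >= 10 s of respiration")
    filtered = _bandpass(resp.samples, resp.fs)
    raw_sd = float(np.std(resp.samples))
    if raw_sd > 0 and float(np.std(filtered)) < 0.1 * raw_sd:
        # out-of-band input: the band residual is noise, not breathing
        warnings.warn("no in-band respiration power; rate is missing", stacklevel=2)
        return float("nan")
    mad = np.median(np.abs(filtered - np.median(filtered)))
    # 1.4826 x MAD estimates the SD robustly for noise-like traces but
    # overshoots the plain SD (and the peak amplitude) for near-sinusoidal
    # ones, so the threshold is capped at the classical SD
    robust_sd = min(1.4826 * mad, float(np.std(filtered)))
    if robust_sd <= 0:
        warnings.warn("flat respiration signal; rate is missing", stacklevel=2)
        return float("nan")
    peaks, _ = sps.find_peaks(
        filtered,
        height=robust_sd,
        distance=max(1, int(round(MIN_PEAK_GAP * resp.fs))),
        width=MIN_PEAK_WIDTH * resp.fs,
        rel_height=0.5,
    )
    if peaks.size == 0:
        warnings.warn("no qualifying respiration peaks; rate is missing", stacklevel=2)
        return float("nan")
    return float(peaks.size / resp.duration * 60.0)
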