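"""Pan-Tompkins QRS detection.

Classic chain: 5-15 Hz bandpass, differentiation, squaring, 150 ms moving
integration, adaptive dual thresholds with search-back, 200 ms refractory.
Filtering is zero-phase so detected integrator peaks are time-aligned with
the QRS complex; the final R time is refined to the local ECG maximum
within +/- 25 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ..core import EcgSignal
from ..errors import InvalidArgumentError

__all__ = ["BeatSeries", "detect_r_peaks", "PanTompkinsConfig"]


@dataclass(frozen=True)
class PanTompkinsConfig:
    band_low: float = 5.0  # Hz
    band_high: float = 15.0  # Hz
    integration_window: float = 0.150  # s
    refractory: float = 0.200  # s
    searchback_factor: float = 1.66  # missed-beat search-back at this x mean RR
    threshold_fraction: float = 0.25  # T1 = noise + frac * (signal - noise)
    refine_window: float = 0.025  # s, local-max refinement half-window


@dataclass
class BeatSeries:
    """Strictly increasing R-peak times in seconds."""

    r_times: np.ndarray

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.size >= 2 and np.any(np.diff(self.r_times) <= 0):
            raise InvalidArgumentError("r_times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.r_times.size


def _feature_signal(ecg: EcgSignal, cfg: PanTompkinsConfig) -> np.ndarray:
    nyq = ecg.fs / 2.0
    b, a = sps.butter(2, [cfg.band_low / nyq, cfg.band_high / nyq], btype="band")
    bp = sps.filtfilt(b, a, ecg.samples)
    deriv = np.gradient(bp) * ecg.fs
    squared = deriv**2
    win = max(1, int(round(cfg.integration_window * ecg.fs)))
    kernel = np.ones(win) / win
    return np.convolve(squared, kernel, mode="same"), bp


def detect_r_peaks(
    ecg: EcgSignal, config: PanTompkinsConfig | None = None
) -> BeatSeries:
    """Detect R peaks; a flat/featureless signal yields an empty series."""
    cfg = config or PanTompkinsConfig()
    if ecg.fs < 250:
        raise InvalidArgumentError("fs must be >= 250 Hz")
    if ecg.duration < 5.0:
        raise InvalidArgumentError("need >= 5 s of ECG")
    if np.ptp(ecg.samples) < 1e-12:
        warnings.warn("flat ECG signal; no beats detected", stacklevel=2)
        return BeatSeries(r_times=np.array([]))

    fs = ecg.fs
    # reflect-pad 1 s at both ends so beats at the record boundaries produce
    # full integrator peaks; padded indices are discarded after detection
    pad = int(round(1.0 * fs))
    padded = np.concatenate(
        [ecg.samples[pad:0:-1], ecg.samples, ecg.samples[-2 : -pad - 2 : -1]]
    )
    mwi, bp = _feature_signal(
        EcgSignal(samples=padded, fs=fs, t0=ecg.t0 - pad / fs), cfg
    )
    refr = int(round(cfg.refractory * fs))
    # candidate peaks of the integrated signal
    cand, _ = sps.find_peaks(mwi, distance=refr)
    if cand.size == 0:
        warnings.warn("no integrator peaks found", stacklevel=2)
        return BeatSeries(r_times=np.array([]))

    # threshold initialisation from the first 2 s
    head = mwi[: int(2 * fs)]
    spki = float(head.max()) * 0.5 if head.size else float(mwi.max()) * 0.5
    npki = float(np.mean(head)) * 0.5 if head.size else 0.0

    accepted: list[int] = []
    rr_history: list[float] = []

    def _accept(i: int, value: float) -> None:
        nonlocal spki
        accepted.append(i)
        spki = 0.125 * value + 0.875 * spki
        if len(accepted) >= 2:
            rr_history.append((accepted[-1] - accepted[-2]) / fs)
            if len(rr_history) > 8:
                rr_history.pop(0)

    k = 0
    while k < cand.size:
        i = cand[k]
        v = mwi[i]
        thr1 = npki + cfg.threshold_fraction * (spki - npki)
        if v > thr1:
            _accept(i, v)
        else:
            npki = 0.125 * v + 0.875 * npki
            # search-back: if the expected beat is overdue, re-examine the
            # interval with the lower threshold
            if rr_history and accepted:
                mean_rr = float(np.mean(rr_history))
                overdue = (i - accepted[-1]) / fs > cfg.searchback_factor * mean_rr
                if overdue:
                    thr2 = 0.5 * thr1
                    window = [
                        j
                        for j in cand[: k + 1]
                        if accepted[-1] + refr < j <= i and mwi[j] > thr2
                    ]
                    if window:
                        best = max(window, key=lambda j: mwi[j])
                        _accept(best, mwi[best])
        k += 1

    if not accepted:
        warnings.warn("no beats above threshold", stacklevel=2)
        return BeatSeries(r_times=np.array([]))

    # refine each beat to the local raw-ECG maximum within +/- refine_window
    half = int(round(cfg.refine_window * fs))
    refined = []
    n_orig = ecg.samples.size
    folded = set()
    for i in accepted:
        # fold mirror-region detections back into the record
        if i < pad:
            i = 2 * pad - i
        elif i >= pad + n_orig:
            i = 2 * (pad + n_orig - 1) - i
        folded.add(i)
    for i in sorted(folded):
        # clamp the search window to the original record so boundary beats
        # refine to a real sample instead of a mirrored one
        lo = max(pad, i - half)
        hi = min(pad + ecg.samples.size, i + half + 1)
        if lo >= hi:
            continue
        refined.append(lo + int(np.argmax(padded[lo:hi])) - pad)
    refined = np.unique(refined)
    refined = refined[(refined >= 0) & (refined < ecg.samples.size)]
    if refined.size == 0:
        warnings.warn("no beats inside the record", stacklevel=2)
        return BeatSeries(r_times=np.array([]))
    # enforce refractory after refinement
    keep = [refined[0]]
    for i in refined[1:]:
        if i - keep[-1] >= refr:
            keep.append(i)
    return BeatSeries(r_times=ecg.t0 + np.asarray(keep) / fs)
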