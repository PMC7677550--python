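"""Cardiorespiratory signal generators with retained ground truth."""

from __future__ import annotations

import numpy as np

from ..core import EcgSignal, RespSignal
from ..errors import InvalidArgumentError
from .traits import TraitProfile

__all__ = ["simulate_rr_series", "synthesize_ecg", "simulate_respiration"]


def simulate_rr_series(
    profile: TraitProfile,
    duration: float = 90.0,
    seed: int | np.random.Generator = 0,
    ar_coef: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate beat times and the true NN series.

    ``NN_i = mean_nn + e_i + rsa_amplitude * sin(2*pi*f_resp*t_i)`` where
    ``e`` is a stationary AR(1) process with marginal SD ``nn_sd`` and lag-1
    coefficient ``ar_coef``; beat times are the cumulative sum.

    Returns
    -------
    beat_times : ndarray, seconds (first beat at 0)
    nn : ndarray, the true NN intervals in ms (len = len(beat_times) - 1)
    """
    if profile.mean_nn <= 0:
        raise InvalidArgumentError("mean_nn must be > 0")
    if duration <= 2.0 * profile.mean_nn / 1000.0:
        raise InvalidArgumentError("duration too short for two beats")
    if not -1.0 < ar_coef < 1.0:
        raise InvalidArgumentError("ar_coef must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    f_resp = profile.resp_rate / 60.0

    beat_times = [0.0]
    nn = []
    e = profile.nn_sd * rng.standard_normal()  # stationary start
    innov_sd = profile.nn_sd * np.sqrt(1.0 - ar_coef**2)
    t = 0.0
    while True:
        interval = profile.mean_nn + e + profile.rsa_amplitude * np.sin(
            2.0 * np.pi * f_resp * t
        )
        interval = max(interval, 250.0)  # physiological floor
        t_next = t + interval / 1000.0
        if t_next > duration:
            break
        nn.append(interval)
        beat_times.append(t_next)
        t = t_next
        e = ar_coef * e + innov_sd * rng.standard_normal()
    return np.asarray(beat_times), np.asarray(nn)


def _qrs_template(fs: float, width: float = 0.02) -> np.ndarray:
    """Mexican-hat (Ricker) wavelet used as a QRS-like template."""
    half = int(round(4 * width * fs))
    tt = np.arange(-half, half + 1) / fs
    a = tt / width
    return (1.0 - a**2) * np.exp(-0.5 * a**2)


def synthesize_ecg(
    beat_times: np.ndarray,
    fs: float = 500.0,
    snr_db: float = 20.0,
    seed: int | np.random.Generator = 0,
    duration: float | None = None,
) -> tuple[EcgSignal, np.ndarray]:
    """Place a QRS-like wavelet at each beat time, add wander and noise.

    ``snr_db`` is the signal-to-white-noise power ratio in decibels
    (``np.inf`` disables noise).  Returns the waveform and the true beat
    sample indices.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        raise InvalidArgumentError("beat_times must be non-empty")
    if fs < 250:
        raise InvalidArgumentError("fs must be >= 250 Hz")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = float(beat_times[-1]) + 1.0
    n = int(np.ceil(duration * fs))
    x = np.zeros(n)
    template = _qrs_template(fs)
    half = (template.size - 1) // 2
    idx = np.round(beat_times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    for i in idx:
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        x[lo:hi] += template[half - (i - lo) : half + (hi - i)]

    t = np.arange(n) / fs
    x = x + 0.08 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    if np.isfinite(snr_db):
        sig_power = np.mean(x**2)
        noise_sd = np.sqrt(sig_power / 10.0 ** (snr_db / 10.0))
        x = x + noise_sd * rng.standard_normal(n)
    return EcgSignal(samples=x, fs=fs), idx


def simulate_respiration(
    resp_rate: float,
    duration: float = 90.0,
    fs: float = 100.0,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> RespSignal:
    """Sinusoidal breathing trace at ``resp_rate`` breaths/min plus noise."""
    if resp_rate <= 0:
        raise InvalidArgumentError("resp_rate must be > 0")
    if fs < 25:
        raise InvalidArgumentError("fs must be >= 25 Hz")
    if duration <= 0:
        raise InvalidArgumentError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * (resp_rate / 60.0) * t)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return RespSignal(samples=x, fs=fs)
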