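"""Latent-trait profiles and the maps from trait to simulation parameters.

A single standard-normal ``vulnerability`` trait drives both exploratory
behavior (wall-hugging, center avoidance, gait variability, scanning) and —
scaled by a ``coupling`` effect size — the dark-maze cardiac parameters.
The maps are linear with small Gaussian perturbations and hard clipping to
the documented parameter ranges, so expected parameter values are monotone
in the trait and recoverable in closed form by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidArgumentError

__all__ = ["TraitProfile", "profile_from_vulnerability", "scenario3_cardiac_params"]

RESP_RATE_MIN = 10.2  # breaths/min, inside the 0.17–0.73 Hz analysis band
RESP_RATE_MAX = 43.8


@dataclass
class TraitProfile:
    """Per-subject simulation parameters.

    Parameters
    ----------
    vulnerability
        Latent trait on a standard-normal scale; higher means more
        stress-vulnerable.
    thigmotaxis_bias
        Probability mass of wall-adjacent waypoints, in [0, 1].
    center_avoidance
        Tendency to avoid exposed zones (room center / far alley), in [0, 1].
    gait_speed_cv
        Coefficient of variation of instantaneous walking speed, >= 0.
    mean_nn, nn_sd
        Mean and beat-to-beat SD of the normal-to-normal interval, ms.
    rsa_amplitude
        Respiratory sinus arrhythmia modulation depth, ms.
    resp_rate
        Breathing rate, breaths/min, inside [10.2, 43.8].
    scan_rate
        Head-scan excursions per minute of walking.
    walk_speed
        Median walking speed, m/s.
    """

    vulnerability: float
    thigmotaxis_bias: float
    center_avoidance: float
    gait_speed_cv: float
    mean_nn: float
    nn_sd: float
    rsa_amplitude: float
    resp_rate: float
    scan_rate: float = 6.0
    walk_speed: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.thigmotaxis_bias <= 1.0:
            raise InvalidArgumentError("thigmotaxis_bias must be in [0, 1]")
        if not 0.0 <= self.center_avoidance <= 1.0:
            raise InvalidArgumentError("center_avoidance must be in [0, 1]")
        if self.gait_speed_cv < 0:
            raise InvalidArgumentError("gait_speed_cv must be >= 0")
        if self.mean_nn <= 0:
            raise InvalidArgumentError("mean_nn must be > 0")
        if self.nn_sd < 0:
            raise InvalidArgumentError("nn_sd must be >= 0")
        if self.rsa_amplitude < 0:
            raise InvalidArgumentError("rsa_amplitude must be >= 0")
        if not RESP_RATE_MIN <= self.resp_rate <= RESP_RATE_MAX:
            raise InvalidArgumentError(
                f"resp_rate must be in [{RESP_RATE_MIN}, {RESP_RATE_MAX}]"
            )
        if self.scan_rate < 0:
            raise InvalidArgumentError("scan_rate must be >= 0")
        if self.walk_speed < 0:
            raise InvalidArgumentError("walk_speed must be >= 0")


# -------------------------------------------------------------- linear maps
# Behavioral maps (independent of coupling): slopes chosen so that one SD of
# the trait moves each parameter by roughly one noise SD times 4-6, keeping
# rank correlations between trait and parameters around 0.9.
_BEHAVIOR_MAP = {
    "thigmotaxis_bias": (0.50, 0.17, 0.04),   # intercept, slope, noise SD
    "center_avoidance": (0.50, 0.17, 0.04),
    "gait_speed_cv": (0.25, -0.07, 0.02),     # calmer gait in vulnerable subjects
    "scan_rate": (6.0, -1.8, 0.5),            # fewer scans when vulnerable
    "walk_speed": (0.60, -0.08, 0.03),
}

# Dark-maze cardiac maps, scaled by the coupling effect size beta.
_CARDIAC_MAP = {
    "mean_nn": (820.0, -70.0, 12.0),
    "nn_sd": (42.0, -13.0, 2.0),
    "rsa_amplitude": (22.0, -7.0, 1.5),
}

# Floors so physiology stays valid at extreme traits.
_CARDIAC_FLOOR = {"mean_nn": 450.0, "nn_sd": 2.0, "rsa_amplitude": 0.5}


def scenario3_cardiac_params(
    vulnerability: float, coupling: float, rng: np.random.Generator
) -> dict[str, float]:
    """Dark-maze cardiac parameters for one subject.

    ``mean_nn``, ``nn_sd`` and ``rsa_amplitude`` all decrease in
    ``coupling * vulnerability`` (parasympathetic withdrawal in vulnerable
    subjects), plus small independent noise.
    """
    out = {}
    for name, (b0, b1, sd) in _CARDIAC_MAP.items():
        val = b0 + b1 * coupling * vulnerability + sd * rng.standard_normal()
        out[name] = max(_CARDIAC_FLOOR[name], val)
    return out


def profile_from_vulnerability(
    vulnerability: float,
    coupling: float,
    rng: np.random.Generator,
) -> TraitProfile:
    """Draw a full TraitProfile given the latent trait.

    Behavioral parameters depend on the trait alone; cardiac parameters on
    ``coupling * vulnerability``; respiration rate is drawn independently of
    everything (it must not contaminate the cardiac axis).
    """
    if coupling < 0:
        raise InvalidArgumentError("coupling must be >= 0")
    beh = {}
    for name, (b0, b1, sd) in _BEHAVIOR_MAP.items():
        beh[name] = b0 + b1 * vulnerability + sd * rng.standard_normal()
    beh["thigmotaxis_bias"] = float(np.clip(beh["thigmotaxis_bias"], 0.0, 1.0))
    beh["center_avoidance"] = float(np.clip(beh["center_avoidance"], 0.0, 1.0))
    beh["gait_speed_cv"] = float(max(0.02, beh["gait_speed_cv"]))
    beh["scan_rate"] = float(max(0.0, beh["scan_rate"]))
    beh["walk_speed"] = float(max(0.15, beh["walk_speed"]))

    cardiac = scenario3_cardiac_params(vulnerability, coupling, rng)
    resp_rate = float(rng.uniform(12.0, 24.0))

    return TraitProfile(
        vulnerability=float(vulnerability),
        resp_rate=resp_rate,
        **beh,
        **cardiac,
    )
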