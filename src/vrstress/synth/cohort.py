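"""Whole-cohort synthesis: traits, sessions, and ground truth per subject."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import SessionRecording, SCENARIOS
from ..errors import InvalidArgumentError
from ..geometry import SceneGeometry, DEFAULT_GEOMETRY
from .gait import simulate_gait
from .physio import simulate_respiration, simulate_rr_series, synthesize_ecg
from .traits import TraitProfile, profile_from_vulnerability
from .trajectory import simulate_alley_trajectory, simulate_trajectory

__all__ = ["Subject", "generate_cohort"]

# Scenario 1/2 physiology is habituated and decoupled from the trait: the
# cardiac axis only engages in the dark maze.
_BASELINE_MEAN_NN = (850.0, 35.0)  # mean, SD across subjects
_BASELINE_NN_SD = (45.0, 8.0)
_BASELINE_RSA = (25.0, 5.0)


@dataclass
class Subject:
    """One synthetic participant with sessions and retained ground truth."""

    subject_id: str
    profile: TraitProfile
    stai_t: float
    sessions: dict[str, SessionRecording] = field(default_factory=dict)
    #: per-scenario latent truth: beat_times, nn, heel_strikes, n_scans, ...
    truth: dict[str, dict] = field(default_factory=dict)


def _physio_params(profile: TraitProfile, scenario: str, rng: np.random.Generator):
    """Cardiac parameters used for a given scenario's RR simulation."""
    if scenario == "dark_maze":
        return profile
    mean_nn = max(500.0, rng.normal(*_BASELINE_MEAN_NN))
    nn_sd = max(5.0, rng.normal(*_BASELINE_NN_SD))
    rsa = max(2.0, rng.normal(*_BASELINE_RSA))
    return TraitProfile(
        vulnerability=profile.vulnerability,
        thigmotaxis_bias=profile.thigmotaxis_bias,
        center_avoidance=profile.center_avoidance,
        gait_speed_cv=profile.gait_speed_cv,
        mean_nn=mean_nn,
        nn_sd=nn_sd,
        rsa_amplitude=rsa,
        resp_rate=profile.resp_rate,
        scan_rate=profile.scan_rate,
        walk_speed=profile.walk_speed,
    )


def generate_cohort(
    n: int,
    coupling: float = 1.0,
    seed: int = 0,
    geometry: SceneGeometry = DEFAULT_GEOMETRY,
    duration: float = 90.0,
    rate_track: float = 90.0,
    rate_mocap: float = 60.0,
    rate_ecg: float = 500.0,
    rate_resp: float = 100.0,
    snr_db: float = 20.0,
    scenarios: tuple[str, ...] = SCENARIOS,
    include_gait: bool = True,
    include_ecg: bool = True,
) -> list[Subject]:
    """Generate ``n`` synthetic subjects.

    ``coupling`` scales how strongly the latent vulnerability trait drives
    dark-maze cardiac parameters (0 decouples them entirely).  STAI-T is
    drawn uniformly over [20, 60], independent of the trait.  Fully
    reproducible given ``seed``.
    """
    if n < 2:
        raise InvalidArgumentError("n must be >= 2")
    if coupling < 0:
        raise InvalidArgumentError("coupling must be >= 0")
    ss = np.random.SeedSequence(seed)
    subjects: list[Subject] = []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        v = float(rng.standard_normal())
        profile = profile_from_vulnerability(v, coupling, rng)
        stai_t = float(rng.uniform(20.0, 60.0))
        subj = Subject(subject_id=f"S{i:04d}", profile=profile, stai_t=stai_t)
        for scenario in scenarios:
            truth: dict = {}
            if scenario == "elevated_alley":
                traj, traj_truth = simulate_alley_trajectory(
                    profile, geometry, duration, rate_track, rng
                )
            else:
                traj, traj_truth = simulate_trajectory(
                    profile, geometry, duration, rate_track, rng
                )
            truth.update(traj_truth)

            foot_tracks = None
            if include_gait and scenario in ("empty_room", "elevated_alley"):
                foot_tracks, gait_truth = simulate_gait(
                    traj, profile, rng, rate=rate_mocap
                )
                truth.update(gait_truth)

            phys = _physio_params(profile, scenario, rng)
            beat_times, nn = simulate_rr_series(phys, duration, rng)
            truth["beat_times"] = beat_times
            truth["nn"] = nn
            truth["cardiac_params"] = {
                "mean_nn": phys.mean_nn,
                "nn_sd": phys.nn_sd,
                "rsa_amplitude": phys.rsa_amplitude,
                "resp_rate": phys.resp_rate,
            }
            ecg = None
            if include_ecg:
                ecg, r_idx = synthesize_ecg(
                    beat_times, rate_ecg, snr_db, rng, duration=duration
                )
                truth["r_sample_indices"] = r_idx
            resp = simulate_respiration(
                phys.resp_rate, duration, rate_resp, seed=rng
            )
            subj.sessions[scenario] = SessionRecording(
                subject_id=subj.subject_id,
                scenario_id=scenario,
                head_track=traj,
                foot_tracks=foot_tracks,
                ecg=ecg,
                respiration=resp,
                duration=duration,
            )
            subj.truth[scenario] = truth
        subjects.append(subj)
    return subjects
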