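"""Subject x feature table with family and scenario tags.

The catalogue is a registry of extractor functions so additional features
can be added without touching the builder.  Every feature carries a family
tag in {position, gait, burst} and a scenario tag in {er, ea}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import SessionRecording
from ..errors import SchemaError
from ..geometry import SceneGeometry, DEFAULT_GEOMETRY
from .gait import detect_bursts, detect_gait_cycles, gait_features
from .kinematics import kinematics_features
from .position import position_features_ea, position_features_er
from .shape import head_scan_count, trajectory_shape_features

__all__ = ["FeatureTable", "build_feature_table", "FAMILIES"]

log = logging.getLogger(__name__)

FAMILIES = ("position", "gait", "burst")


@dataclass
class FeatureTable:
    """Feature matrix (rows: subjects) with per-column family/scenario tags."""

    data: pd.DataFrame
    families: dict[str, str]
    scenarios: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.data.columns) - set(self.families)
        if unknown:
            raise SchemaError(f"columns without family tag: {sorted(unknown)}")
        bad = {c: f for c, f in self.families.items() if f not in FAMILIES}
        if bad:
            raise SchemaError(f"invalid family tags: {bad}")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def family_columns(self, family: str) -> list[str]:
        return [c for c in self.data.columns if self.families[c] == family]

    def subset(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(
            data=self.data.loc[:, columns].copy(),
            families={c: self.families[c] for c in columns},
            scenarios={c: self.scenarios[c] for c in columns},
        )


def _er_features(session: SessionRecording, geometry: SceneGeometry):
    traj = session.head_track
    feats: dict[str, tuple[float, str]] = {}

    def put(d: dict[str, float], family: str):
        for k, v in d.items():
            feats[k] = (v, family)

    put(position_features_er(traj, geometry), "position")
    put(trajectory_shape_features(traj, geometry), "position")
    put(head_scan_count(traj), "position")
    put(kinematics_features(traj), "position")
    _put_gait_burst(feats, session, traj, put)
    return feats


def _put_gait_burst(feats, session, traj, put):
    events = detect_gait_cycles(session.foot_tracks)
    gait = gait_features(events)
    burst = detect_bursts(events, traj)
    if session.foot_tracks is None:
        # no mocap: the whole gait/burst families are missing, not zero
        gait = {k: float("nan") for k in gait}
        burst = {k: float("nan") for k in burst}
    put(gait, "gait")
    put(burst, "burst")


def _ea_features(session: SessionRecording, geometry: SceneGeometry):
    traj = session.head_track
    feats: dict[str, tuple[float, str]] = {}

    def put(d: dict[str, float], family: str):
        for k, v in d.items():
            feats[k] = (v, family)

    put(position_features_ea(traj, geometry), "position")
    put(kinematics_features(traj), "position")
    _put_gait_burst(feats, session, traj, put)
    return feats


_EXTRACTORS = {"empty_room": ("er", _er_features), "elevated_alley": ("ea", _ea_features)}


def build_feature_table(
    sessions: dict[str, dict[str, SessionRecording]],
    geometry: SceneGeometry = DEFAULT_GEOMETRY,
    max_missing_fraction: float = 0.5,
) -> FeatureTable:
    """Build the behavioral feature table from per-subject sessions.

    ``sessions`` maps subject_id -> {scenario_id -> SessionRecording} and
    must contain the two exploration scenarios per subject.  Subjects whose
    missing-feature fraction exceeds ``max_missing_fraction`` are excluded
    (logged).
    """
    ids = list(sessions)
    if len(ids) != len(set(ids)):
        raise SchemaError("duplicate subject ids")
    rows = {}
    families: dict[str, str] = {}
    scenarios: dict[str, str] = {}
    for sid, per_scenario in sessions.items():
        row: dict[str, float] = {}
        for scenario, (suffix, extractor) in _EXTRACTORS.items():
            session = per_scenario.get(scenario)
            if session is None:
                raise SchemaError(f"subject {sid} lacks scenario {scenario}")
            for name, (value, family) in extractor(session, geometry).items():
                col = f"{name}_{suffix}"
                row[col] = value
                families.setdefault(col, family)
                scenarios.setdefault(col, suffix)
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    # exclude subjects with excessive missingness
    frac_missing = df.isna().mean(axis=1)
    dropped = df.index[frac_missing > max_missing_fraction]
    for sid in dropped:
        log.warning("excluding subject %s: %.0f%% features missing", sid,
                    100 * frac_missing[sid])
    df = df.drop(index=dropped)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        log.warning("feature table has %d missing values", n_missing)
    return FeatureTable(data=df, families=families, scenarios=scenarios)
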