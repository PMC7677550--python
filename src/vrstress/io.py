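"""Text-format readers/writers for sessions, tables, and reports.

All tables are headered UTF-8 CSV with '.' decimals; physiology CSVs carry
the sampling rate in a ``# fs=`` comment line; models and reports are JSON.
Feature-table headers encode tags as ``name|family|scenario`` so round-trips
preserve them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior.table import FeatureTable
from .core import (
    EcgSignal,
    FootTracks,
    RespSignal,
    SessionRecording,
    TrajectorySeries,
    Waveform,
)
from .errors import ParseError

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_foot_tracks",
    "read_foot_tracks",
    "write_waveform",
    "read_waveform",
    "write_session",
    "read_session",
    "write_feature_table",
    "read_feature_table",
    "write_json",
    "read_json",
]


# ------------------------------------------------------------------- helpers
def _read_csv(path: Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", **kw)
    except (pd.errors.ParserError, FileNotFoundError, ValueError) as exc:
        raise ParseError(str(exc), path=str(path)) from exc


def _check_monotone_t(t: np.ndarray, path: Path) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ParseError("non-monotone timestamps", path=str(path), line=int(bad[0]) + 2)


# ---------------------------------------------------------------- trajectory
def write_trajectory(traj: TrajectorySeries, path: str | Path) -> None:
    df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y, "z": traj.z,
                       "yaw": traj.yaw})
    df.to_csv(path, index=False, float_format="%.9g")


def read_trajectory(path: str | Path) -> TrajectorySeries:
    path = Path(path)
    df = _read_csv(path)
    expected = ["t", "x", "y", "z", "yaw"]
    if list(df.columns) != expected:
        raise ParseError(f"expected columns {expected}, got {list(df.columns)}",
                         path=str(path))
    _check_monotone_t(df["t"].to_numpy(), path)
    return TrajectorySeries(**{c: df[c].to_numpy() for c in expected})


# --------------------------------------------------------------- foot tracks
def write_foot_tracks(tracks: FootTracks, path: str | Path) -> None:
    frames = []
    for name, pos in (("left", tracks.left), ("right", tracks.right)):
        frames.append(pd.DataFrame({
            "t": tracks.t, "foot": name,
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        }))
    pd.concat(frames).to_csv(path, index=False, float_format="%.9g")


def read_foot_tracks(path: str | Path) -> FootTracks:
    path = Path(path)
    df = _read_csv(path)
    expected = ["t", "foot", "x", "y", "z"]
    if list(df.columns) != expected:
        raise ParseError(f"expected columns {expected}, got {list(df.columns)}",
                         path=str(path))
    sides = {}
    t_ref = None
    for name, g in df.groupby("foot"):
        t = g["t"].to_numpy()
        _check_monotone_t(t, path)
        sides[name] = g[["x", "y", "z"]].to_numpy()
        t_ref = t
    if set(sides) != {"left", "right"}:
        raise ParseError(f"expected feet left/right, got {sorted(sides)}",
                         path=str(path))
    return FootTracks(t=t_ref, left=sides["left"], right=sides["right"])


# ---------------------------------------------------------------- physiology
def write_waveform(wave: Waveform, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={wave.fs:.9g}\n# t0={wave.t0:.9g}\n")
        pd.DataFrame({"t": wave.t, "value": wave.samples}).to_csv(
            fh, index=False, float_format="%.9g"
        )


def read_waveform(path: str | Path, cls=Waveform) -> Waveform:
    path = Path(path)
    fs = t0 = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "fs":
                fs = float(val)
            elif key.strip() == "t0":
                t0 = float(val)
    if fs is None:
        raise ParseError("missing '# fs=' header", path=str(path), line=1)
    df = _read_csv(path)
    return cls(samples=df["value"].to_numpy(), fs=fs, t0=t0 or 0.0)


# ------------------------------------------------------------------- session
def write_session(session: SessionRecording, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_trajectory(session.head_track, d / "trajectory.csv")
    if session.foot_tracks is not None:
        write_foot_tracks(session.foot_tracks, d / "foot_tracks.csv")
    if session.ecg is not None:
        write_waveform(session.ecg, d / "ecg.csv")
    if session.respiration is not None:
        write_waveform(session.respiration, d / "respiration.csv")
    meta = {
        "subject_id": session.subject_id,
        "scenario_id": session.scenario_id,
        "duration": session.duration,
    }
    (d / "session.json").write_text(json.dumps(meta, indent=2))


def read_session(directory: str | Path) -> SessionRecording:
    d = Path(directory)
    meta_path = d / "session.json"
    if not meta_path.exists():
        raise ParseError("missing session.json", path=str(meta_path))
    meta = json.loads(meta_path.read_text())
    foot = ecg = resp = None
    if (d / "foot_tracks.csv").exists():
        foot = read_foot_tracks(d / "foot_tracks.csv")
    if (d / "ecg.csv").exists():
        ecg = read_waveform(d / "ecg.csv", EcgSignal)
    if (d / "respiration.csv").exists():
        resp = read_waveform(d / "respiration.csv", RespSignal)
    return SessionRecording(
        subject_id=meta["subject_id"],
        scenario_id=meta["scenario_id"],
        head_track=read_trajectory(d / "trajectory.csv"),
        foot_tracks=foot,
        ecg=ecg,
        respiration=resp,
        duration=float(meta["duration"]),
    )


# ------------------------------------------------------------- feature table
def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.data.copy()
    df.columns = [
        f"{c}|{table.families[c]}|{table.scenarios[c]}" for c in df.columns
    ]
    df.to_csv(path, index=True, float_format="%.12g")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    df = _read_csv(path, index_col=0)
    families, scenarios, names = {}, {}, []
    for col in df.columns:
        parts = col.split("|")
        if len(parts) != 3:
            raise ParseError(f"feature column {col!r} lacks name|family|scenario tags",
                             path=str(path), line=1)
        name, family, scenario = parts
        names.append(name)
        families[name] = family
        scenarios[name] = scenario
    df.columns = names
    return FeatureTable(data=df, families=families, scenarios=scenarios)


# ---------------------------------------------------------------------- json
def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
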