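"""Declarative run configuration with documented defaults.

Every tunable threshold from the processing modules has a key here, so a
full run is re-derivable from the manifest (config + seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # simulation
    n_subjects: int = 140
    coupling: float = 1.0
    duration: float = 90.0
    rate_track: float = 90.0
    rate_mocap: float = 60.0
    rate_ecg: float = 500.0
    rate_resp: float = 100.0
    snr_db: float = 20.0

    # seeds (one per stochastic stage)
    seed: int = 0
    seed_selection: int | None = None
    seed_tuning: int | None = None
    seed_split: int | None = None

    # cardio
    segment_block: float = 30.0
    clean_n_sd: float = 3.0
    cardio_scenario: str = "dark_maze"

    # iHRV
    rr_bound: float = 0.2
    hrv_floor: float = 0.3

    # selection
    spearman_threshold: float = 0.1
    spearman_absolute: bool = True
    selection_folds: int = 10

    # split
    split_mode: str = "stai"  # "stai" or "even"
    stai_low_cut: float = 35.0
    stai_high_cut: float = 45.0

    # tuning
    n_trials: int = 100
    tuning_folds: int = 10
    eta_bounds: tuple[float, float] = (0.01, 0.3)
    max_depth_bounds: tuple[int, int] = (2, 8)
    min_child_weight_bounds: tuple[float, float] = (1.0, 10.0)
    nrounds_bounds: tuple[int, int] = (50, 1000)

    output_dir: str = "vrstress_run"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.split_mode not in ("stai", "even"):
            raise ConfigurationError("split_mode must be 'stai' or 'even'")
        if self.cardio_scenario not in ("empty_room", "elevated_alley", "dark_maze"):
            raise ConfigurationError(f"unknown scenario {self.cardio_scenario!r}")
        for name in ("seed_selection", "seed_tuning", "seed_split"):
            if getattr(self, name) is None:
                setattr(self, name, self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping: {path}")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("eta_bounds", "max_depth_bounds", "min_child_weight_bounds",
                "nrounds_bounds"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
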