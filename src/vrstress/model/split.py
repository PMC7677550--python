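"""Anxiety-stratified train/test splitting.

Training keeps the trait-anxiety extremes (score < 35 or > 45), testing the
moderate band; boundary scores (exactly 35 or 45) go to the test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ..errors import ConfigurationError

__all__ = ["SplitSpec", "stratified_split", "even_split"]

log = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    train_ids: list[str]
    test_ids: list[str]
    rule: dict

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ConfigurationError(f"train/test overlap: {sorted(overlap)}")


def stratified_split(
    stai: pd.Series, low_cut: float = 35.0, high_cut: float = 45.0
) -> SplitSpec:
    """Split subject ids by trait-anxiety score."""
    train = stai.index[(stai < low_cut) | (stai > high_cut)].tolist()
    test = stai.index[(stai >= low_cut) & (stai <= high_cut)].tolist()
    if not train or not test:
        raise ConfigurationError(
            f"empty stratum: {len(train)} train / {len(test)} test subjects"
        )
    log.info("stratified split: %d train, %d test", len(train), len(test))
    return SplitSpec(
        train_ids=train,
        test_ids=test,
        rule={"low_cut": low_cut, "high_cut": high_cut, "boundary": "test"},
    )


def even_split(ids: list[str], seed: int = 0) -> SplitSpec:
    """Seeded half/half split (used for synthetic recovery experiments)."""
    import numpy as np

    if len(ids) < 4:
        raise ConfigurationError("need >= 4 subjects for an even split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    return SplitSpec(
        train_ids=[ids[i] for i in perm[:half]],
        test_ids=[ids[i] for i in perm[half:]],
        rule={"mode": "even", "seed": seed},
    )
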