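"""Integrated HRV index: a constrained principal component of
{HR, RMSSD, SDNN, HRVTi, RR}.

PCA is performed on z-scored columns (correlation matrix).  Components are
oriented so the summed HRV loadings are positive; a candidate component must
load at least ``hrv_floor`` on each of RMSSD/SDNN/HRVTi, at most
``-hrv_floor`` on HR, and at most ``rr_bound`` in magnitude on RR.  Among
candidates the one explaining the most variance is selected; higher scores
mean greater vagal prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError, SelectionFailureError

__all__ = ["CARDIO_COLUMNS", "IHRVModel", "fit_ihrv", "score_ihrv", "cardio_matrix"]

CARDIO_COLUMNS = ("HR", "RMSSD", "SDNN", "HRVTi", "RR")


def cardio_matrix(rows: list[dict], index: list[str] | None = None) -> pd.DataFrame:
    """Assemble a subjects x 5 cardio matrix with the canonical column order."""
    df = pd.DataFrame(rows, index=index)
    missing = set(CARDIO_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cardio matrix missing columns: {sorted(missing)}")
    return df.loc[:, list(CARDIO_COLUMNS)].astype(float)


@dataclass
class IHRVModel:
    """Fitted index: unit-norm loadings plus the column standardization."""

    loadings: np.ndarray  # aligned with CARDIO_COLUMNS
    explained_variance_fraction: float
    column_means: np.ndarray
    column_sds: np.ndarray
    selected_component_index: int
    all_loadings: np.ndarray = field(repr=False, default=None)
    all_explained: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "columns": list(CARDIO_COLUMNS),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction,
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "selected_component_index": self.selected_component_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IHRVModel":
        return cls(
            loadings=np.asarray(d["loadings"], dtype=float),
            explained_variance_fraction=float(d["explained_variance_fraction"]),
            column_means=np.asarray(d["column_means"], dtype=float),
            column_sds=np.asarray(d["column_sds"], dtype=float),
            selected_component_index=int(d["selected_component_index"]),
        )


def _validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if list(matrix.columns) != list(CARDIO_COLUMNS):
        raise SchemaError(
            f"expected columns {CARDIO_COLUMNS}, got {list(matrix.columns)}"
        )
    if matrix.isna().any().any():
        raise InvalidArgumentError("cardio matrix contains missing values")
    return matrix


def fit_ihrv(
    matrix: pd.DataFrame, rr_bound: float = 0.2, hrv_floor: float = 0.3
) -> IHRVModel:
    """Fit the index on a subjects x {HR,RMSSD,SDNN,HRVTi,RR} matrix."""
    matrix = _validate_matrix(matrix)
    if len(matrix) < 6:
        raise InvalidArgumentError("need >= 6 rows to fit the index")
    X = matrix.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = [c for c, s in zip(CARDIO_COLUMNS, sds) if s <= 0]
        raise InvalidArgumentError(f"constant cardio columns: {bad}")
    Z = (X - means) / sds
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    explained = evals / evals.sum()

    i_hr, i_rmssd, i_sdnn, i_hrvti, i_rr = range(5)
    hrv_idx = [i_rmssd, i_sdnn, i_hrvti]
    candidates = []
    near_miss = None
    for k in range(5):
        w = evecs[:, k].copy()
        if w[hrv_idx].sum() < 0:
            w = -w
        evecs[:, k] = w
        ok = (
            np.all(w[hrv_idx] >= hrv_floor)
            and w[i_hr] <= -hrv_floor
            and abs(w[i_rr]) <= rr_bound
        )
        if ok:
            candidates.append(k)
        else:
            score = min(w[hrv_idx].min(), -w[i_hr]) - max(0.0, abs(w[i_rr]) - rr_bound)
            if near_miss is None or score > near_miss[1]:
                near_miss = (k, score, w)
    if not candidates:
        k, _, w = near_miss
        raise SelectionFailureError(
            "no component satisfies the loading constraints; best near-miss is "
            f"component {k} with loadings "
            + ", ".join(f"{c}={v:+.3f}" for c, v in zip(CARDIO_COLUMNS, w))
        )
    best = max(candidates, key=lambda k: explained[k])
    return IHRVModel(
        loadings=evecs[:, best],
        explained_variance_fraction=float(explained[best]),
        column_means=means,
        column_sds=sds,
        selected_component_index=int(best),
        all_loadings=evecs,
        all_explained=explained,
    )


def score_ihrv(model: IHRVModel, matrix: pd.DataFrame) -> pd.Series:
    """Project rows onto the selected component (z-scored row dot loadings)."""
    matrix = _validate_matrix(matrix)
    Z = (matrix.to_numpy(dtype=float) - model.column_means) / model.column_sds
    return pd.Series(Z @ model.loadings, index=matrix.index, name="ihrv")
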