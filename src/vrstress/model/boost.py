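"""Gradient-boosted regression-tree fitting and correlation evaluation.

The ensemble is scikit-learn's ``GradientBoostingRegressor`` with squared
error loss.  The tuned hyperparameters map onto it as: ``eta`` ->
``learning_rate``, ``max_depth`` -> ``max_depth``, ``min_child_weight`` ->
``min_samples_leaf`` (for squared error the hessian per sample is 1, so the
minimum child weight equals a minimum leaf size), ``nrounds`` ->
``n_estimators``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor

from ..errors import InvalidArgumentError, SchemaError

__all__ = ["TrainedModel", "fit_model", "evaluate", "DEFAULT_PARAMS"]

DEFAULT_PARAMS = {
    "eta": 0.1,
    "max_depth": 3,
    "min_child_weight": 1,
    "nrounds": 200,
}


@dataclass
class TrainedModel:
    estimator: GradientBoostingRegressor
    feature_names: list[str]
    params: dict
    seed: int
    train_predictions: np.ndarray = field(repr=False, default=None)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.feature_names:
            raise SchemaError(
                f"feature columns {list(features.columns)} do not match the "
                f"model schema {self.feature_names}"
            )
        return self.estimator.predict(features.to_numpy(dtype=float))


def fit_model(
    features: pd.DataFrame,
    target: pd.Series,
    params: dict | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the boosted ensemble with squared-error loss."""
    if len(features) < 2:
        raise InvalidArgumentError("need >= 2 training rows")
    if features.isna().any().any():
        raise InvalidArgumentError("features contain missing values; impute or drop")
    if not features.index.equals(target.index):
        raise SchemaError("feature rows do not align with target")
    p = dict(DEFAULT_PARAMS, **(params or {}))
    est = GradientBoostingRegressor(
        loss="squared_error",
        learning_rate=float(p["eta"]),
        max_depth=int(p["max_depth"]),
        min_samples_leaf=max(1, int(round(p["min_child_weight"]))),
        n_estimators=int(p["nrounds"]),
        random_state=seed,
    )
    X = features.to_numpy(dtype=float)
    y = target.to_numpy(dtype=float)
    est.fit(X, y)
    return TrainedModel(
        estimator=est,
        feature_names=list(features.columns),
        params=p,
        seed=seed,
        train_predictions=est.predict(X),
    )


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n < 4 or not np.isfinite(r) or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + level / 2.0)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> dict:
    """Pearson and Spearman correlations with two-sided p and Fisher-z CIs."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.size != truth.size:
        raise SchemaError("prediction/truth length mismatch")
    n = predictions.size
    if n < 3:
        raise InvalidArgumentError("need >= 3 pairs to correlate")
    out: dict = {"n": int(n)}
    if np.std(predictions) == 0 or np.std(truth) == 0:
        warnings.warn("zero-variance input; correlations undefined", stacklevel=2)
        out.update(
            pearson_r=float("nan"), pearson_p=float("nan"),
            spearman_rho=float("nan"), spearman_p=float("nan"),
            pearson_ci=(float("nan"), float("nan")),
            spearman_ci=(float("nan"), float("nan")),
        )
        return out
    pr = stats.pearsonr(predictions, truth)
    sr = stats.spearmanr(predictions, truth)
    out["pearson_r"] = float(pr.statistic)
    out["pearson_p"] = float(pr.pvalue)
    out["spearman_rho"] = float(sr.statistic)
    out["spearman_p"] = float(sr.pvalue)
    out["pearson_ci"] = _fisher_ci(out["pearson_r"], n)
    out["spearman_ci"] = _fisher_ci(out["spearman_rho"], n)
    return out
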