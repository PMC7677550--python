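"""Tree-structured Parzen estimator (TPE) hyperparameter search.

A compact, seeded TPE: after a random start-up phase, observed trials are
split at the objective's lower quantile into "good" and "bad" sets; per
dimension a Gaussian KDE models each set, candidates are sampled from the
good density and the candidate maximizing the density ratio l(x)/g(x) is
evaluated next.  The objective is mean k-fold cross-validated squared error
of the boosted ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold, cross_val_score

from ..errors import InvalidArgumentError

__all__ = ["HyperparamSpace", "Trial", "tune_hyperparameters"]

GAMMA = 0.25  # fraction of trials treated as "good"
N_STARTUP = 15
N_CANDIDATES = 24


@dataclass(frozen=True)
class HyperparamSpace:
    """Search bounds for the four tuned parameters."""

    eta: tuple[float, float] = (0.01, 0.3)  # log-uniform
    max_depth: tuple[int, int] = (2, 8)
    min_child_weight: tuple[float, float] = (1.0, 10.0)
    nrounds: tuple[int, int] = (50, 1000)
    n_trials: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eta", "max_depth", "min_child_weight", "nrounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidArgumentError(f"{name} bounds must be ordered")
        if self.eta[0] <= 0:
            raise InvalidArgumentError("eta must be positive (log-uniform)")
        if self.n_trials < 1:
            raise InvalidArgumentError("n_trials must be >= 1")


@dataclass
class Trial:
    params: dict
    loss: float


# internal coordinates: eta in log space, integers as floats
_DIMS = ("eta", "max_depth", "min_child_weight", "nrounds")


def _to_unit(space: HyperparamSpace, params: dict) -> np.ndarray:
    out = []
    for name in _DIMS:
        lo, hi = getattr(space, name)
        v = params[name]
        if name == "eta":
            out.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
        else:
            out.append((v - lo) / (hi - lo))
    return np.asarray(out)


def _from_unit(space: HyperparamSpace, u: np.ndarray) -> dict:
    u = np.clip(u, 0.0, 1.0)
    params = {}
    for name, ui in zip(_DIMS, u):
        lo, hi = getattr(space, name)
        if name == "eta":
            params[name] = float(np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo))))
        elif name in ("max_depth", "nrounds"):
            params[name] = int(round(lo + ui * (hi - lo)))
        else:
            params[name] = float(lo + ui * (hi - lo))
    return params


def _kde_or_uniform(points: np.ndarray):
    """1-D KDE; falls back to a flat density for degenerate samples."""
    pts = np.asarray(points)
    if pts.size < 2 or np.std(pts) < 1e-12:
        return None
    try:
        return gaussian_kde(pts)
    except np.linalg.LinAlgError:
        return None


def _log_density(kde, x: np.ndarray) -> np.ndarray:
    if kde is None:
        return np.zeros(x.shape[0])
    return np.log(np.maximum(kde(x), 1e-300))


def cv_objective(
    features: pd.DataFrame,
    target: pd.Series,
    params: dict,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean k-fold CV squared error for one parameter setting."""
    est = GradientBoostingRegressor(
        loss="squared_error",
        learning_rate=float(params["eta"]),
        max_depth=int(params["max_depth"]),
        min_samples_leaf=max(1, int(round(params["min_child_weight"]))),
        n_estimators=int(params["nrounds"]),
        random_state=seed,
    )
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(
        est,
        features.to_numpy(dtype=float),
        target.to_numpy(dtype=float),
        cv=cv,
        scoring="neg_mean_squared_error",
    )
    return float(-scores.mean())


def tune_hyperparameters(
    features: pd.DataFrame,
    target: pd.Series,
    space: HyperparamSpace | None = None,
    folds: int = 10,
) -> tuple[dict, list[Trial]]:
    """Seeded TPE search; returns (best params, full trial history)."""
    space = space or HyperparamSpace()
    if len(features) < 20:
        raise InvalidArgumentError("need >= 20 training subjects to tune")
    rng = np.random.default_rng(space.seed)
    trials: list[Trial] = []

    for trial_idx in range(space.n_trials):
        if trial_idx < N_STARTUP or len(trials) < 2:
            u = rng.uniform(size=len(_DIMS))
        else:
            losses = np.array([t.loss for t in trials])
            coords = np.array([_to_unit(space, t.params) for t in trials])
            n_good = max(2, int(np.ceil(GAMMA * len(trials))))
            order = np.argsort(losses)
            good = coords[order[:n_good]]
            bad = coords[order[n_good:]]
            best_score = -np.inf
            u = rng.uniform(size=len(_DIMS))
            cand = np.empty((N_CANDIDATES, len(_DIMS)))
            for d in range(len(_DIMS)):
                kde_l = _kde_or_uniform(good[:, d])
                if kde_l is None:
                    cand[:, d] = rng.uniform(size=N_CANDIDATES)
                else:
                    cand[:, d] = np.clip(
                        kde_l.resample(N_CANDIDATES, seed=rng)[0], 0.0, 1.0
                    )
            score = np.zeros(N_CANDIDATES)
            for d in range(len(_DIMS)):
                kde_l = _kde_or_uniform(good[:, d])
                kde_g = _kde_or_uniform(bad[:, d])
                score += _log_density(kde_l, cand[:, d])
                score -= _log_density(kde_g, cand[:, d])
            u = cand[int(np.argmax(score))]
        params = _from_unit(space, u)
        loss = cv_objective(features, target, params, folds=folds, seed=space.seed)
        trials.append(Trial(params=params, loss=loss))

    best = min(trials, key=lambda t: t.loss)
    return dict(best.params), trials
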