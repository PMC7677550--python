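"""Exact path-dependent SHAP attributions for tree ensembles.

Implements the polynomial-time TreeSHAP recursion (EXTEND/UNWIND over the
feature path, with conditional expectations weighted by node cover) for
scikit-learn decision trees, summed across a gradient-boosted ensemble.
Attributions satisfy additivity: base value + row sum equals the model
prediction.

``brute_force_shap`` computes the same quantity by enumerating feature
subsets; it is exponential in the feature count and exists as an
independent oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from ..errors import SchemaError
from .boost import TrainedModel

__all__ = ["ShapMatrix", "shap_attributions", "tree_shap_values", "brute_force_shap"]


@dataclass
class ShapMatrix:
    values: np.ndarray  # (n_rows, n_features)
    base_value: float
    feature_names: list[str]
    predictions: np.ndarray

    def additivity_error(self) -> float:
        return float(
            np.max(np.abs(self.base_value + self.values.sum(axis=1) - self.predictions))
        )

    def mean_abs(self) -> pd.Series:
        return pd.Series(
            np.abs(self.values).mean(axis=0), index=self.feature_names
        ).sort_values(ascending=False)


class _Tree:
    """Flat view of a fitted sklearn tree."""

    def __init__(self, sk_tree):
        t = sk_tree.tree_
        self.left = t.children_left
        self.right = t.children_right
        self.feature = t.feature
        self.threshold = t.threshold
        self.value = t.value[:, 0, 0]
        self.cover = t.weighted_n_node_samples


def _extend(m: list, pz: float, po: float, pi: int) -> list:
    l = len(m)
    m = [list(e) for e in m]
    m.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l - 1, -1, -1):
        m[i + 1][3] += po * m[i][3] * (i + 1) / (l + 1)
        m[i][3] = pz * m[i][3] * (l - i) / (l + 1)
    return m


def _unwind(m: list, i: int) -> list:
    l = len(m) - 1
    o_i, z_i = m[i][2], m[i][1]
    n = m[l][3]
    out = [list(e) for e in m[:-1]]
    for j in range(l - 1, -1, -1):
        if o_i != 0:
            t = out[j][3]
            out[j][3] = n * (l + 1) / ((j + 1) * o_i)
            n = t - out[j][3] * z_i * (l - j) / (l + 1)
        else:
            out[j][3] = out[j][3] * (l + 1) / (z_i * (l - j))
    for j in range(i, l):
        out[j][0], out[j][1], out[j][2] = m[j + 1][0], m[j + 1][1], m[j + 1][2]
    return out


def _unwound_sum(m: list, i: int) -> float:
    l = len(m) - 1
    o_i, z_i = m[i][2], m[i][1]
    n = m[l][3]
    total = 0.0
    for j in range(l - 1, -1, -1):
        if o_i != 0:
            t = n * (l + 1) / ((j + 1) * o_i)
            total += t
            n = m[j][3] - t * z_i * (l - j) / (l + 1)
        else:
            total += m[j][3] * (l + 1) / (z_i * (l - j))
    return total


def tree_shap_values(sk_tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Path-dependent SHAP values of one fitted sklearn tree for row x."""
    tree = _Tree(sk_tree)
    # sklearn casts inputs to float32 before threshold comparisons; mirror
    # that so ties resolve identically to estimator.predict
    x = np.asarray(x, dtype=np.float32).astype(np.float64)
    phi = np.zeros(n_features)

    def recurse(j: int, m: list, pz: float, po: float, pi: int) -> None:
        m = _extend(m, pz, po, pi)
        if tree.left[j] < 0:  # leaf
            for i in range(1, len(m)):
                w = _unwound_sum(m, i)
                phi[m[i][0]] += w * (m[i][2] - m[i][1]) * tree.value[j]
            return
        split = tree.feature[j]
        if x[split] <= tree.threshold[j]:
            hot, cold = tree.left[j], tree.right[j]
        else:
            hot, cold = tree.right[j], tree.left[j]
        iz = io = 1.0
        k = next((idx for idx in range(1, len(m)) if m[idx][0] == split), None)
        if k is not None:
            iz, io = m[k][1], m[k][2]
            m = _unwind(m, k)
        cov = tree.cover
        recurse(hot, m, iz * cov[hot] / cov[j], io, split)
        recurse(cold, m, iz * cov[cold] / cov[j], 0.0, split)

    recurse(0, [], 1.0, 1.0, -1)
    return phi


def _expected_value(sk_tree) -> float:
    return float(sk_tree.tree_.value[0, 0, 0])


def shap_attributions(model: TrainedModel, features: pd.DataFrame) -> ShapMatrix:
    """Per-row, per-feature attributions for the boosted ensemble."""
    if list(features.columns) != model.feature_names:
        raise SchemaError(
            f"feature columns {list(features.columns)} do not match the "
            f"model schema {model.feature_names}"
        )
    X = features.to_numpy(dtype=float)
    est = model.estimator
    lr = est.learning_rate
    n, p = X.shape
    values = np.zeros((n, p))
    base = float(est._raw_predict_init(X[:1])[0, 0])
    for stage in est.estimators_[:, 0]:
        base += lr * _expected_value(stage)
        for r in range(n):
            values[r] += lr * tree_shap_values(stage, X[r], p)
    return ShapMatrix(
        values=values,
        base_value=base,
        feature_names=model.feature_names,
        predictions=est.predict(X),
    )


# --------------------------------------------------------------- test oracle
def _expvalue_subset(tree: _Tree, j: int, x: np.ndarray, subset: frozenset) -> float:
    if tree.left[j] < 0:
        return float(tree.value[j])
    f = tree.feature[j]
    if f in subset:
        child = tree.left[j] if x[f] <= tree.threshold[j] else tree.right[j]
        return _expvalue_subset(tree, child, x, subset)
    l, r = tree.left[j], tree.right[j]
    return (
        tree.cover[l] * _expvalue_subset(tree, l, x, subset)
        + tree.cover[r] * _expvalue_subset(tree, r, x, subset)
    ) / tree.cover[j]


def brute_force_shap(sk_tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exponential-time Shapley values over the tree's used features."""
    tree = _Tree(sk_tree)
    x = np.asarray(x, dtype=np.float32).astype(np.float64)
    used = sorted({f for f in tree.feature if f >= 0})
    m = len(used)
    phi = np.zeros(n_features)
    for i in used:
        others = [f for f in used if f != i]
        for mask in range(2 ** len(others)):
            subset = frozenset(f for b, f in enumerate(others) if mask >> b & 1)
            w = factorial(len(subset)) * factorial(m - len(subset) - 1) / factorial(m)
            phi[i] += w * (
                _expvalue_subset(tree, 0, x, subset | {i})
                - _expvalue_subset(tree, 0, x, subset)
            )
    return phi
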