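"""Three-stage feature-selection cascade.

Order is fixed: zero-variance removal, a Spearman screen against the target
index (absolute rho >= 0.1 by default), then per-family cross-validated
Lasso; the final set is the union of the per-family non-zero supports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .behavior.table import FAMILIES, FeatureTable
from .errors import InvalidArgumentError, SchemaError

__all__ = [
    "SelectionReport",
    "drop_zero_variance",
    "spearman_screen",
    "lasso_select_per_family",
    "select_features",
]

log = logging.getLogger(__name__)

VARIANCE_TOL = 1e-12
SPEARMAN_THRESHOLD = 0.1


@dataclass
class SelectionReport:
    dropped_zero_variance: list[str] = field(default_factory=list)
    dropped_spearman: dict[str, float] = field(default_factory=dict)
    per_family_selected: dict[str, dict[str, float]] = field(default_factory=dict)
    final_selected: list[str] = field(default_factory=list)
    cv_settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dropped_zero_variance": self.dropped_zero_variance,
            "dropped_spearman": self.dropped_spearman,
            "per_family_selected": self.per_family_selected,
            "final_selected": self.final_selected,
            "cv_settings": self.cv_settings,
        }


def drop_zero_variance(
    table: FeatureTable, report: SelectionReport | None = None
) -> FeatureTable:
    """Remove columns whose variance (over non-missing rows) is <= 1e-12."""
    if len(table.data) < 2:
        raise InvalidArgumentError("need >= 2 rows")
    report = report if report is not None else SelectionReport()
    keep, drop = [], []
    for col in table.columns:
        x = table.data[col].dropna()
        if x.size < 2 or float(np.var(x.to_numpy(), ddof=0)) <= VARIANCE_TOL:
            drop.append(col)
        else:
            keep.append(col)
    if not keep:
        raise InvalidArgumentError("all columns are zero-variance")
    report.dropped_zero_variance = drop
    return table.subset(keep)


def spearman_screen(
    table: FeatureTable,
    target: pd.Series,
    threshold: float = SPEARMAN_THRESHOLD,
    absolute: bool = True,
    report: SelectionReport | None = None,
) -> FeatureTable:
    """Keep columns whose Spearman rho with the target clears the threshold.

    Missing values are handled pairwise-complete.
    """
    if not table.data.index.equals(target.index):
        raise SchemaError("feature table rows do not align with target")
    report = report if report is not None else SelectionReport()
    keep = []
    for col in table.columns:
        x = table.data[col]
        ok = x.notna() & target.notna()
        if ok.sum() < 3:
            report.dropped_spearman[col] = float("nan")
            continue
        rho = stats.spearmanr(x[ok], target[ok]).statistic
        stat = abs(rho) if absolute else rho
        if np.isnan(stat) or stat < threshold:
            report.dropped_spearman[col] = float(rho)
        else:
            keep.append(col)
    if not keep:
        raise InvalidArgumentError("Spearman screen removed every column")
    return table.subset(keep)


def lasso_select_per_family(
    table: FeatureTable,
    target: pd.Series,
    folds: int = 10,
    seed: int = 0,
    report: SelectionReport | None = None,
) -> SelectionReport:
    """Per-family cross-validated Lasso; union of non-zero supports.

    Columns are z-scored; the penalty minimizes CV squared error over the
    default path; rows with any missing value in a family are excluded for
    that family's fit.
    """
    if not table.data.index.equals(target.index):
        raise SchemaError("feature table rows do not align with target")
    report = report if report is not None else SelectionReport()
    final: list[str] = []
    for family in FAMILIES:
        cols = table.family_columns(family)
        if not cols:
            log.warning("family %r has no surviving columns; skipped", family)
            continue
        sub = table.data[cols]
        ok = sub.notna().all(axis=1) & target.notna()
        if ok.sum() < folds:
            log.warning("family %r has too few complete rows; skipped", family)
            continue
        X = sub[ok].to_numpy(dtype=float)
        y = target[ok].to_numpy(dtype=float)
        Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        model = LassoCV(cv=cv, alphas=100, max_iter=50_000, random_state=seed)
        model.fit(Xz, y)
        selected = {
            c: float(w) for c, w in zip(cols, model.coef_) if abs(w) > 1e-10
        }
        report.per_family_selected[family] = selected
        final.extend(selected)
    report.final_selected = final
    report.cv_settings = {"folds": folds, "seed": seed, "penalty_rule": "min-cv-error"}
    return report


def select_features(
    table: FeatureTable,
    target: pd.Series,
    threshold: float = SPEARMAN_THRESHOLD,
    absolute: bool = True,
    folds: int = 10,
    seed: int = 0,
) -> tuple[FeatureTable, SelectionReport]:
    """Run the full cascade and return (selected table, report)."""
    report = SelectionReport()
    t1 = drop_zero_variance(table, report)
    t2 = spearman_screen(t1, target, threshold, absolute, report)
    lasso_select_per_family(t2, target, folds, seed, report)
    return table.subset(report.final_selected), report
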