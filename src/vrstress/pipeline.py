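"""End-to-end orchestration of the analysis stages.

Fixed stage order: simulate (or load) sessions -> cardio preprocessing and
summaries -> iHRV fit/score -> behavioral feature table -> split ->
selection (training rows only) -> hyperparameter tuning -> model fit ->
evaluation -> SHAP attribution.  Every artifact is written with a manifest
recording the config hash and seeds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior.table import FeatureTable, build_feature_table
from .cardio import (
    clean_rr,
    decimate_signal,
    default_segments,
    detect_r_peaks,
    respiration_rate,
    segment_summary,
)
from .config import RunConfig
from .core import SessionRecording
from .errors import ConfigurationError
from .ihrv import IHRVModel, cardio_matrix, fit_ihrv, score_ihrv
from .io import write_feature_table, write_json
from .model import (
    HyperparamSpace,
    ShapMatrix,
    SplitSpec,
    TrainedModel,
    evaluate,
    even_split,
    fit_model,
    shap_attributions,
    stratified_split,
    tune_hyperparameters,
)
from .selection import SelectionReport, select_features
from .synth import Subject, generate_cohort

__all__ = ["RunResult", "run_pipeline", "cardio_row_from_session"]

log = logging.getLogger(__name__)


def cardio_row_from_session(session: SessionRecording, config: RunConfig) -> dict:
    """Whole-recording {HR, RMSSD, SDNN, HRVTi, RR} from one session."""
    if session.ecg is None:
        raise ConfigurationError(
            f"session {session.subject_id}/{session.scenario_id} has no ECG channel"
        )
    ecg = session.ecg
    if ecg.fs > config.rate_ecg:
        factor = int(round(ecg.fs / config.rate_ecg))
        ecg = decimate_signal(ecg, factor)
    resp = session.respiration
    if resp is not None and resp.fs > config.rate_resp:
        resp = decimate_signal(resp, int(round(resp.fs / config.rate_resp)))
    beats = detect_r_peaks(ecg)
    nn = clean_rr(beats, n_sd=config.clean_n_sd)
    [summary] = segment_summary(nn, resp, [(0.0, session.duration)])
    return {
        "HR": summary.hr,
        "RMSSD": summary.rmssd,
        "SDNN": summary.sdnn,
        "HRVTi": summary.hrvti,
        "RR": summary.rr,
        "n_beats": summary.n_beats,
        "missing": summary.missing,
    }


@dataclass
class RunResult:
    config: RunConfig
    cardio: pd.DataFrame
    ihrv_model: IHRVModel
    ihrv_scores: pd.Series
    feature_table: FeatureTable
    split: SplitSpec
    selection_report: SelectionReport
    tuned_params: dict
    model: TrainedModel
    evaluation: dict
    shap: ShapMatrix
    stai: pd.Series
    subjects: list[Subject] = field(repr=False, default=None)


def _impute_train_median(df: pd.DataFrame, train_ids: list[str]) -> pd.DataFrame:
    med = df.loc[train_ids].median()
    return df.fillna(med)


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    subjects: list[Subject] | None = None,
) -> RunResult:
    """Run all stages; ``subjects`` may be supplied to skip simulation."""
    if subjects is None:
        log.info("simulating cohort: n=%d coupling=%.2f seed=%d",
                 config.n_subjects, config.coupling, config.seed)
        subjects = generate_cohort(
            n=config.n_subjects,
            coupling=config.coupling,
            seed=config.seed,
            duration=config.duration,
            rate_track=config.rate_track,
            rate_mocap=config.rate_mocap,
            rate_ecg=config.rate_ecg,
            rate_resp=config.rate_resp,
            snr_db=config.snr_db,
        )

    # ---- cardio summaries for the configured scenario
    rows, ids = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for subj in subjects:
            session = subj.sessions.get(config.cardio_scenario)
            if session is None:
                raise ConfigurationError(
                    f"subject {subj.subject_id} lacks scenario {config.cardio_scenario}"
                )
            rows.append(cardio_row_from_session(session, config))
            ids.append(subj.subject_id)
    cardio = pd.DataFrame(rows, index=ids)
    usable = ~cardio["missing"] & cardio[["HR", "RMSSD", "SDNN", "HRVTi", "RR"]].notna().all(axis=1)
    excluded = cardio.index[~usable].tolist()
    if excluded:
        log.warning("excluding %d subjects with unusable cardio: %s",
                    len(excluded), excluded)
    cardio = cardio[usable]

    # ---- iHRV
    matrix = cardio_matrix(
        cardio[["HR", "RMSSD", "SDNN", "HRVTi", "RR"]].to_dict("records"),
        index=list(cardio.index),
    )
    ihrv_model = fit_ihrv(matrix, rr_bound=config.rr_bound, hrv_floor=config.hrv_floor)
    scores = score_ihrv(ihrv_model, matrix)
    log.info("iHRV loadings: %s (explained %.1f%%)",
             np.round(ihrv_model.loadings, 3),
             100 * ihrv_model.explained_variance_fraction)

    # ---- behavioral features
    sessions = {
        s.subject_id: {k: v for k, v in s.sessions.items()}
        for s in subjects
        if s.subject_id in scores.index
    }
    table = build_feature_table(sessions)
    table = table.subset(table.columns)
    common = [i for i in table.data.index if i in scores.index]
    table.data = table.data.loc[common]
    scores = scores.loc[common]
    stai = pd.Series({s.subject_id: s.stai_t for s in subjects}).loc[common]
    log.info("feature table: %d subjects x %d features", *table.data.shape)

    # ---- split
    if config.split_mode == "stai":
        split = stratified_split(stai, config.stai_low_cut, config.stai_high_cut)
    else:
        split = even_split(common, seed=config.seed_split)

    # ---- selection on training rows only
    train_table = FeatureTable(
        data=table.data.loc[split.train_ids],
        families=table.families,
        scenarios=table.scenarios,
    )
    selected_train, report = select_features(
        train_table,
        scores.loc[split.train_ids],
        threshold=config.spearman_threshold,
        absolute=config.spearman_absolute,
        folds=config.selection_folds,
        seed=config.seed_selection,
    )
    log.info("selection: %d -> %d features", len(table.columns),
             len(report.final_selected))

    features = _impute_train_median(
        table.data[report.final_selected], split.train_ids
    )
    X_train = features.loc[split.train_ids]
    X_test = features.loc[split.test_ids]
    y_train = scores.loc[split.train_ids]
    y_test = scores.loc[split.test_ids]

    # ---- tuning + fit
    space = HyperparamSpace(
        eta=config.eta_bounds,
        max_depth=config.max_depth_bounds,
        min_child_weight=config.min_child_weight_bounds,
        nrounds=config.nrounds_bounds,
        n_trials=config.n_trials,
        seed=config.seed_tuning,
    )
    tuned, trials = tune_hyperparameters(
        X_train, y_train, space, folds=config.tuning_folds
    )
    log.info("tuned params: %s (cv loss %.4f)", tuned,
             min(t.loss for t in trials))
    model = fit_model(X_train, y_train, tuned, seed=config.seed_tuning)

    # ---- evaluation
    pred_train = model.predict(X_train)
    pred_test = model.predict(X_test)
    pred_all = np.concatenate([pred_train, pred_test])
    true_all = np.concatenate([y_train.to_numpy(), y_test.to_numpy()])
    evaluation = {
        "train": evaluate(pred_train, y_train.to_numpy()),
        "test": evaluate(pred_test, y_test.to_numpy()),
        "pooled": evaluate(pred_all, true_all),
        "test_vs_stai": evaluate(pred_test, stai.loc[split.test_ids].to_numpy()),
        "counts": {
            "n_subjects": len(subjects),
            "n_usable": len(common),
            "n_train": len(split.train_ids),
            "n_test": len(split.test_ids),
            "n_features_in": len(table.columns),
            "n_features_selected": len(report.final_selected),
            "n_excluded_cardio": len(excluded),
        },
        "tuned_params": tuned,
    }

    shap = shap_attributions(model, X_test)

    result = RunResult(
        config=config,
        cardio=cardio,
        ihrv_model=ihrv_model,
        ihrv_scores=scores,
        feature_table=table,
        split=split,
        selection_report=report,
        tuned_params=tuned,
        model=model,
        evaluation=evaluation,
        shap=shap,
        stai=stai,
        subjects=subjects,
    )
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def write_artifacts(result: RunResult, out_dir: str | Path) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": result.config.to_dict(),
        "config_hash": result.config.config_hash(),
        "package_version": __version__,
        "counts": result.evaluation["counts"],
    }
    write_json(manifest, d / "manifest.json")
    result.cardio.to_csv(d / "cardio_summaries.csv", float_format="%.12g")
    write_json(result.ihrv_model.to_dict(), d / "ihrv_model.json")
    result.ihrv_scores.to_csv(d / "ihrv_scores.csv", float_format="%.12g")
    write_feature_table(result.feature_table, d / "feature_table.csv")
    write_json(result.selection_report.to_dict(), d / "selection_report.json")
    write_json(
        {"train_ids": result.split.train_ids, "test_ids": result.split.test_ids,
         "rule": result.split.rule},
        d / "split.json",
    )
    write_json({"params": result.tuned_params}, d / "model_params.json")
    pd.DataFrame(
        result.shap.values,
        columns=result.shap.feature_names,
        index=result.split.test_ids,
    ).to_csv(d / "shap_values.csv", float_format="%.12g")
    write_json(result.evaluation, d / "evaluation.json")
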