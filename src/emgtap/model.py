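"""Leave-one-subject-out random-forest regression of MDS-UPDRS III scores.

Each cross-validation fold holds out every row of one subject (both the OFF
and ON condition), standardizes the feature columns on the training rows
only, fits a random-forest regressor, and predicts the held-out rows.  The
pooled out-of-fold predictions are correlated with the clinician scores; the
"standard" (Hudgins + Du) and "extended" (plus MAV1/MAV2/ApEn/SampEn and the
activation-peak features) banks are compared per task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.ensemble import RandomForestRegressor

from emgtap.features import FeatureTable, apply_standardization, standardize


@dataclass(frozen=True)
class LosoFold:
    test_subject: str
    train_rows: tuple
    test_rows: tuple


@dataclass(frozen=True)
class ModelConfig:
    n_trees: int = 100
    seed: int = 42
    target: str = "total_part3"  # or "upper_limb_subtotal" or an item key


@dataclass
class CvPredictions:
    """Pooled out-of-fold predictions, one per feature-table row."""

    frame: pd.DataFrame  # columns: subject_id, condition, task, true, predicted, fold
    feature_set: str
    config: ModelConfig


def make_loso_folds(row_index: pd.MultiIndex) -> list[LosoFold]:
    """One fold per subject; the fold's test rows are all that subject's rows."""
    subjects = list(dict.fromkeys(row_index.get_level_values("subject_id")))
    if len(subjects) < 2:
        raise ValueError("need at least two subjects for LOSO")
    folds = []
    for s in subjects:
        mask = row_index.get_level_values("subject_id") == s
        folds.append(
            LosoFold(
                test_subject=s,
                train_rows=tuple(row_index[~mask]),
                test_rows=tuple(row_index[mask]),
            )
        )
    return folds


def _target_vector(rows: pd.MultiIndex, scores, target: str) -> np.ndarray:
    by_key = {}
    for s in scores:
        if target == "total_part3":
            value = s.total_part3
        elif target == "upper_limb_subtotal":
            value = s.upper_limb_subtotal
        else:
            value = s.items[target]
        by_key[(s.subject_id, s.condition)] = float(value)
    y = []
    for subject_id, condition, _task in rows:
        key = (subject_id, condition)
        if key not in by_key:
            raise ValueError(f"no clinical score for {key}")
        y.append(by_key[key])
    return np.asarray(y)


def run_loso(
    table: FeatureTable, scores, config: ModelConfig | None = None
) -> CvPredictions:
    """LOSO regression with leakage-free per-fold standardization."""
    config = config or ModelConfig()
    df = table.data
    y_all = _target_vector(df.index, scores, config.target)  # validates coverage
    folds = make_loso_folds(df.index)
    records = []
    for fold_id, fold in enumerate(folds):
        train_rows = list(fold.train_rows)
        test_rows = list(fold.test_rows)
        fitted = standardize(table, fit_rows=train_rows)
        x_train = fitted.data.loc[train_rows].to_numpy()
        x_test = apply_standardization(
            FeatureTable(df.loc[test_rows], table.feature_set), fitted.scaler
        ).to_numpy()
        y_train = _target_vector(pd.MultiIndex.from_tuples(
            train_rows, names=df.index.names), scores, config.target)
        rf = RandomForestRegressor(
            n_estimators=config.n_trees, random_state=config.seed
        )
        rf.fit(x_train, y_train)
        y_pred = rf.predict(x_test)
        y_true = _target_vector(pd.MultiIndex.from_tuples(
            test_rows, names=df.index.names), scores, config.target)
        for row, yt, yp in zip(test_rows, y_true, y_pred):
            records.append(
                {
                    "subject_id": row[0],
                    "condition": row[1],
                    "task": row[2],
                    "true": yt,
                    "predicted": float(yp),
                    "fold": fold_id,
                }
            )
    frame = pd.DataFrame(records)
    if not np.all(np.isfinite(frame["predicted"])):
        raise ValueError("non-finite predictions")
    assert len(frame) == len(df), "every row must be predicted exactly once"
    del y_all
    return CvPredictions(frame=frame, feature_set=table.feature_set, config=config)


def evaluate(preds: CvPredictions, method: str = "pearson") -> float:
    """Pooled correlation between out-of-fold predictions and true scores."""
    t = preds.frame["true"].to_numpy()
    p = preds.frame["predicted"].to_numpy()
    if len(t) < 3:
        raise ValueError("need at least 3 prediction pairs")
    if np.std(t) == 0 or np.std(p) == 0:
        raise ValueError("zero-variance predictions or targets")
    if method == "pearson":
        return float(spstats.pearsonr(t, p).statistic)
    if method == "spearman":
        return float(spstats.spearmanr(t, p).statistic)
    raise ValueError(f"unknown method {method!r}")


def compare_models(
    table_standard: FeatureTable,
    table_extended: FeatureTable,
    scores,
    config: ModelConfig | None = None,
    method: str = "pearson",
) -> dict:
    """Per-task standard-vs-extended comparison of pooled LOSO correlations."""
    if not table_standard.data.index.equals(table_extended.data.index):
        raise ValueError("tables must share the same rows")
    config = config or ModelConfig()
    report: dict = {"tasks": {}, "config": {
        "n_trees": config.n_trees, "seed": config.seed, "target": config.target,
        "method": method,
    }}
    tasks = sorted(set(table_standard.data.index.get_level_values("task")))
    for task in tasks:
        out = {}
        preds = {}
        for name, table in (("standard", table_standard), ("extended", table_extended)):
            sub = FeatureTable(
                table.data.xs(task, level="task", drop_level=False),
                table.feature_set,
            )
            cv = run_loso(sub, scores, config)
            out[f"r_{name}"] = evaluate(cv, method)
            preds[name] = cv.frame
        out["delta_r"] = out["r_extended"] - out["r_standard"]
        report["tasks"][task] = out
        report.setdefault("predictions", {})[task] = preds
    return report
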