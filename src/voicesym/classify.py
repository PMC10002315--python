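"""Symptom-group prediction from feature vectors.

A gradient-boosted decision-tree ensemble (LightGBM) is trained under
stratified five-fold cross-validation.  For each fold the decision cutoff
on the predicted probability is the threshold maximizing the Youden index
(sensitivity + specificity - 1) on the *training* split's scores; test
predictions are thresholded into a fold confusion matrix, the five fold
matrices are summed cell-wise into the overall matrix, and sensitivity,
specificity and accuracy are computed from the pooled counts.  The
positive class is group 1 (the inactivity group under the canonical
labeling).

LightGBM consumes missing (NaN) feature values natively; a median-imputation
fallback is available for learners without native support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


@dataclass
class ConfusionMatrix:
    """Counts with group 1 as the positive class."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp, fn=self.fn + other.fn,
            fp=self.fp + other.fp, tn=self.tn + other.tn,
        )

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


def confusion_stats(m: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity tp/(tp+fn), specificity tn/(tn+fp), accuracy (tp+tn)/total."""
    if m.total == 0:
        raise ValueError("empty confusion matrix")
    sens = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else np.nan
    spec = m.tn / (m.tn + m.fp) if (m.tn + m.fp) else np.nan
    return {
        "sensitivity": float(sens),
        "specificity": float(spec),
        "accuracy": float((m.tp + m.tn) / m.total),
    }


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing the Youden index J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive sorted unique scores
    plus sentinels below and above the score range; a score >= threshold
    predicts positive.  Ties in J break toward the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        ([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0])
    )
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


DEFAULT_LEARNER_CONFIG: dict = {
    # shallow trees and conservative leaf counts guard against overfitting
    # the small cohorts this pipeline targets
    "n_estimators": 80,
    "learning_rate": 0.1,
    "num_leaves": 7,
    "max_depth": 3,
    "min_child_samples": 5,
    "subsample": 1.0,
    "colsample_bytree": 0.7,
    "reg_lambda": 1.0,
}


def _fit_lgbm(
    X: np.ndarray, y: np.ndarray, seed: int, learner_config: dict | None
) -> lgb.LGBMClassifier:
    cfg = dict(DEFAULT_LEARNER_CONFIG)
    if learner_config:
        cfg.update(learner_config)
    model = lgb.LGBMClassifier(
        objective="binary",
        random_state=seed,
        deterministic=True,
        force_col_wise=True,
        n_jobs=1,
        verbose=-1,
        **cfg,
    )
    model.fit(X, y)
    return model


@dataclass
class CvResult:
    """Five-fold CV output: per-fold cutoffs and confusions, pooled matrix
    and metrics, and the features any fold's model actually split on."""

    fold_cutoffs: list[float]
    fold_confusions: list[ConfusionMatrix]
    overall: ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    model_features: list[str]
    feature_importance: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "fold_cutoffs": self.fold_cutoffs,
            "fold_confusions": [m.as_dict() for m in self.fold_confusions],
            "overall": self.overall.as_dict(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "model_features": self.model_features,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def crossvalidate(
    features: pd.DataFrame,
    labels: dict[str, int] | pd.Series,
    n_folds: int = 5,
    seed: int = 0,
    learner_config: dict | None = None,
    cutoff_on: str = "train",
) -> CvResult:
    """Stratified k-fold CV of group prediction from the feature table.

    Parameters
    ----------
    features:
        One row per subject with a ``subject_id`` column; remaining columns
        are feature values (NaN allowed).
    labels:
        subject -> group in {1, 2}.  Group 1 is the positive class.
    cutoff_on:
        ``"train"`` (default) picks each fold's Youden cutoff on the
        training split's scores; ``"test"`` exposes the alternative reading
        where the cutoff is chosen on the fold's own test scores.
    """
    if cutoff_on not in ("train", "test"):
        raise ValueError("cutoff_on must be 'train' or 'test'")
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    df = features[features["subject_id"].astype(str).map(labels.__contains__)]
    sids = df["subject_id"].astype(str).to_numpy()
    X = df.drop(columns=["subject_id"]).to_numpy(dtype=float)
    y = np.array([1 if labels[s] == 1 else 0 for s in sids])
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds subjects")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_cutoffs: list[float] = []
    fold_confusions: list[ConfusionMatrix] = []
    importance: dict[str, float] = {}
    feature_names = [c for c in df.columns if c != "subject_id"]
    Xdf = pd.DataFrame(X, columns=feature_names)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = _fit_lgbm(
            Xdf.iloc[tr], y[tr], seed=seed * 1000 + fold, learner_config=learner_config
        )
        if cutoff_on == "train":
            cut = youden_cutoff(model.predict_proba(Xdf.iloc[tr])[:, 1], y[tr])
        else:
            cut = youden_cutoff(model.predict_proba(Xdf.iloc[te])[:, 1], y[te])
        s_te = model.predict_proba(Xdf.iloc[te])[:, 1]
        pred = s_te >= cut
        cm = ConfusionMatrix(
            tp=int(np.sum(pred & (y[te] == 1))),
            fn=int(np.sum(~pred & (y[te] == 1))),
            fp=int(np.sum(pred & (y[te] == 0))),
            tn=int(np.sum(~pred & (y[te] == 0))),
        )
        fold_cutoffs.append(float(cut))
        fold_confusions.append(cm)
        for name, imp in zip(feature_names, model.booster_.feature_importance("gain")):
            if imp > 0:
                importance[name] = importance.get(name, 0.0) + float(imp)

    overall = ConfusionMatrix()
    for cm in fold_confusions:
        overall = overall + cm
    stats = confusion_stats(overall)
    return CvResult(
        fold_cutoffs=fold_cutoffs,
        fold_confusions=fold_confusions,
        overall=overall,
        sensitivity=stats["sensitivity"],
        specificity=stats["specificity"],
        accuracy=stats["accuracy"],
        model_features=sorted(importance, key=importance.get, reverse=True),
        feature_importance=importance,
        seed=seed,
    )


def feature_report(cv: CvResult) -> pd.DataFrame:
    """Features with nonzero split gain in any fold, ranked by total gain.

    Columns mirror the study's feature summary: feature name, statistic,
    phrase number, aggregate importance.  Column names of the form
    ``feature__stat__phraseNN`` are split into their parts; other names
    pass through with empty statistic/phrase.
    """
    rows = []
    for name in cv.model_features:
        parts = name.split("__")
        if len(parts) == 3 and parts[2].startswith("phrase"):
            feat, stat, phrase = parts[0], parts[1], int(parts[2][6:])
        else:
            feat, stat, phrase = name, "", -1
        rows.append(
            {
                "feature": feat,
                "statistic": stat,
                "phrase": phrase,
                "importance": cv.feature_importance[name],
            }
        )
    return pd.DataFrame(rows, columns=["feature", "statistic", "phrase", "importance"])
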