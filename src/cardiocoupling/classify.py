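"""Feature selection and pairwise-group classification.

Protocol per pairwise task (severe vs mild-moderate, severe vs CPNCA,
mild-moderate vs CPNCA): stratified 70/30 train/test split; features
z-scored on training statistics; SVM-RFE ranking on the training split only;
the retained-feature count chosen by cross-validation (or fixed); a
gradient-boosted tree classifier with minority-class sample weighting tuned
by five-fold CV on the training split; evaluation on the held-out test
split.  The positive class is always the more-stenosed group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .synthetic import GROUPS

__all__ = [
    "ClassifierConfig",
    "ClassificationReport",
    "PAIRWISE_TASKS",
    "svm_rfe_rank",
    "train_weighted_model",
    "evaluate",
    "run_pairwise_tasks",
]

logger = logging.getLogger(__name__)

#: The three pairwise tasks; the first (more severe) group is the positive
#: class of each task.
PAIRWISE_TASKS = (
    ("severe", "mild-moderate"),
    ("severe", "cpnca"),
    ("mild-moderate", "cpnca"),
)

_DEFAULT_GRID: dict[str, tuple] = {
    "max_depth": (2, 3),
    "n_estimators": (100,),
    "learning_rate": (0.1, 0.3),
}


@dataclass
class ClassifierConfig:
    """Knobs of the classification protocol.

    ``w`` is the sample-weight multiplier applied to minority-class training
    samples (default 2.5, suited to roughly 3:1 imbalance); ``k`` is the
    number of SVM-RFE-ranked features to retain, or ``"cv"`` to pick it by
    cross-validated accuracy over ``k_grid``; ``param_grid`` is the boosting
    hyperparameter search space explored by ``cv_folds``-fold CV;
    ``n_repeats`` stratified splits are averaged for stable estimates.
    """

    w: float = 2.5
    test_fraction: float = 0.30
    cv_folds: int = 5
    param_grid: Mapping[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_GRID))
    k: int | str = "cv"
    k_grid: tuple[int, ...] = (8, 16, 24)
    n_repeats: int = 10

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("weight coefficient w must be positive")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class ClassificationReport:
    """Held-out metrics for one pairwise task (one split).

    ``confusion`` rows are true (positive, negative), columns predicted
    (positive, negative); sensitivity is the positive-class recall and
    specificity the negative-class recall.  F1 is the harmonic mean of
    sensitivity and precision.
    """

    task: tuple[str, str]
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: np.ndarray
    selected_features: tuple[str, ...]
    n_test: int

    def as_dict(self) -> dict:
        return {
            "task": " vs ".join(self.task),
            "accuracy": self.accuracy,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "selected_features": list(self.selected_features),
            "n_test": self.n_test,
        }


def svm_rfe_rank(X, y, C: float = 1.0) -> np.ndarray:
    """SVM recursive feature elimination ranking.

    Repeatedly fits a linear max-margin classifier and removes the feature
    with the smallest squared weight, one per iteration (ties broken by
    column order).  Returns an array of ranks, 1 = last survivor (most
    useful).  Expects standardized features and binary labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature")
    if len(np.unique(y)) != 2:
        raise ValueError("SVM-RFE requires exactly two classes")
    rfe = RFE(SVC(kernel="linear", C=C), n_features_to_select=1, step=1)
    rfe.fit(X, y)
    return rfe.ranking_.astype(int)


def _sample_weights(y: np.ndarray, w: float) -> np.ndarray:
    """Weight ``w`` on the minority class, 1 elsewhere."""
    classes, counts = np.unique(y, return_counts=True)
    minority = classes[np.argmin(counts)]
    return np.where(y == minority, w, 1.0)


class _LabelledXGB:
    """XGBClassifier accepting arbitrary (e.g. string) class labels."""

    def __init__(self, params: Mapping, seed: int) -> None:
        self._model = XGBClassifier(random_state=seed, n_jobs=1,
                                    eval_metric="logloss", **params)

    def fit(self, X, y, sample_weight=None) -> "_LabelledXGB":
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self._model.fit(X, y_enc, sample_weight=sample_weight)
        return self

    def predict(self, X):
        return self.classes_[self._model.predict(X)]

    def predict_proba(self, X):
        return self._model.predict_proba(X)


def _make_xgb(params: Mapping, seed: int) -> _LabelledXGB:
    return _LabelledXGB(params, seed)


def _cv_accuracy(X, y, w, params, folds, seed) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, val_idx in skf.split(X, y):
        model = _make_xgb(params, seed)
        model.fit(X[train_idx], y[train_idx],
                  sample_weight=w[train_idx])
        scores.append(float(np.mean(model.predict(X[val_idx]) == y[val_idx])))
    return float(np.mean(scores))


def train_weighted_model(X, y, cfg: ClassifierConfig = ClassifierConfig(),
                         seed: int = 0) -> XGBClassifier:
    """Fit the weighted gradient-boosted classifier on a training split.

    Minority-class samples get weight ``cfg.w``.  Hyperparameters are chosen
    from ``cfg.param_grid`` by ``cfg.cv_folds``-fold stratified CV accuracy
    on the training data (grid iterated in a fixed order, first best kept,
    so the result is deterministic under ``seed``), then the model is refit
    on the full training split.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    weights = _sample_weights(y, cfg.w)
    keys = list(cfg.param_grid)
    best_params, best_score = None, -np.inf
    for combo in product(*(cfg.param_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        score = _cv_accuracy(X, y, weights, params, cfg.cv_folds, seed)
        if score > best_score:
            best_params, best_score = params, score
    model = _make_xgb(best_params, seed)
    model.fit(X, y, sample_weight=weights)
    return model


def evaluate(model, X_test, y_test, positive_label,
             selected_features: Sequence[str] = (),
             task: tuple[str, str] | None = None) -> ClassificationReport:
    """Compute held-out metrics with the given positive class.

    Requires both classes present in the test split (otherwise sensitivity
    or specificity is undefined).  AUC uses the predicted positive-class
    probability.
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    labels = np.unique(y_test)
    if len(labels) != 2:
        raise ValueError("test split must contain exactly two classes")
    y_pred = model.predict(X_test)
    y_true_pos = (y_test == positive_label)
    negative_label = labels[labels != positive_label][0]
    cm = confusion_matrix(y_test, y_pred,
                          labels=[positive_label, negative_label])
    tp, fn, fp, tn = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (2 * sensitivity * precision / (sensitivity + precision)
          if (sensitivity + precision) else 0.0)
    accuracy = (tp + tn) / cm.sum()
    proba = model.predict_proba(X_test)
    pos_col = int(np.where(model.classes_ == positive_label)[0][0])
    auc = float(roc_auc_score(y_true_pos, proba[:, pos_col]))
    return ClassificationReport(
        task=task or (str(positive_label), str(negative_label)),
        accuracy=float(accuracy), f1=float(f1),
        sensitivity=float(sensitivity), specificity=float(specificity),
        auc=auc, confusion=cm, selected_features=tuple(selected_features),
        n_test=int(len(y_test)))


def _choose_k(X, y, w, order, cfg, seed) -> int:
    """Pick the retained-feature count by CV accuracy over ``cfg.k_grid``
    (default boosting parameters; smallest k wins ties)."""
    default_params = {k: v[0] for k, v in cfg.param_grid.items()}
    best_k, best_score = None, -np.inf
    for k in cfg.k_grid:
        k = min(k, X.shape[1])
        score = _cv_accuracy(X[:, order[:k]], y, w, default_params,
                             cfg.cv_folds, seed)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def _run_single_split(X, y, names, positive, task, cfg, seed):
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=cfg.test_fraction, stratify=y, random_state=seed)
    mu, sd = X_train.mean(axis=0), X_train.std(axis=0)
    sd[sd == 0] = 1.0
    X_train = (X_train - mu) / sd
    X_test = (X_test - mu) / sd

    ranking = svm_rfe_rank(X_train, y_train)
    order = np.argsort(ranking, kind="stable")
    weights = _sample_weights(y_train, cfg.w)
    k = cfg.k if isinstance(cfg.k, int) else _choose_k(
        X_train, y_train, weights, order, cfg, seed)
    k = min(k, X.shape[1])
    keep = order[:k]

    model = train_weighted_model(X_train[:, keep], y_train, cfg, seed=seed)
    return evaluate(model, X_test[:, keep], y_test, positive,
                    selected_features=tuple(np.asarray(names)[keep]),
                    task=task)


def run_pairwise_tasks(
    features: pd.DataFrame,
    cfg: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
) -> dict[str, list[ClassificationReport]]:
    """Run the full protocol for each pairwise group task.

    ``features`` must carry a ``group`` column plus feature columns
    (restrictable via ``feature_columns``, e.g. the 24 entropy features).
    Each task is repeated over ``cfg.n_repeats`` seeded stratified splits;
    the returned dict maps ``"severe vs cpnca"``-style task names to the
    per-split reports.  Tasks whose smaller group has fewer than 10
    subjects are skipped with a warning.
    """
    if "group" not in features.columns:
        raise ValueError("features frame must carry a 'group' column")
    if feature_columns is None:
        feature_columns = [c for c in features.columns
                           if c not in ("subject_id", "group")]
    present = set(features["group"])
    if len(present & set(GROUPS)) < 2:
        raise ValueError("need at least two groups present")
    rng = np.random.SeedSequence(seed)
    results: dict[str, list[ClassificationReport]] = {}
    for task in PAIRWISE_TASKS:
        name = " vs ".join(task)
        sub = features[features["group"].isin(task)]
        counts = sub["group"].value_counts()
        if len(counts) < 2 or counts.min() < 10:
            warnings.warn(f"task {name!r}: a group has fewer than 10 "
                          "subjects; skipped")
            continue
        X = sub[list(feature_columns)].to_numpy(dtype=float)
        y = sub["group"].to_numpy()
        split_seeds = [int(s.generate_state(1)[0] % (2**31))
                       for s in rng.spawn(cfg.n_repeats)]
        results[name] = [
            _run_single_split(X, y, feature_columns, task[0], task, cfg, s)
            for s in split_seeds]
    return results


def summarize_reports(
    results: Mapping[str, Sequence[ClassificationReport]]) -> pd.DataFrame:
    """Mean metrics per task across repeated splits."""
    rows = []
    for name, reports in results.items():
        rows.append({
            "task": name,
            "n_splits": len(reports),
            "accuracy": float(np.mean([r.accuracy for r in reports])),
            "f1": float(np.mean([r.f1 for r in reports])),
            "sensitivity": float(np.mean([r.sensitivity for r in reports])),
            "specificity": float(np.mean([r.specificity for r in reports])),
            "auc": float(np.mean([r.auc for r in reports])),
        })
    return pd.DataFrame(rows)
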