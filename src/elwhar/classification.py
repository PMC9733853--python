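"""Classifier tuning and subject-wise evaluation protocols.

Three classifier families are supported — k-nearest neighbors, support vector
machines (one-vs-rest), and random forests — each tuned by exhaustive grid
search with 10-fold cross-validation over its standard grid:

* k-NN: neighbors 1 to 28 in steps of 3, Euclidean/Manhattan metric,
  uniform/distance weighting;
* SVM: regularization C in {0.01, 0.1, 1, 10, 50} with linear, polynomial,
  RBF and sigmoid kernels;
* RF: maximum depth in {5, 10, 20, 30, 40} and max features per split in
  {20, 30, 40, 50, 60} (candidates exceeding the feature dimension are
  skipped with a warning).

Features are z-scored inside the pipeline for the distance/kernel methods
(k-NN, SVM); random forests consume raw features.

Two deployment scenarios are evaluated: **intra-subject** (stratified 80/20
split within each subject, metrics averaged over subjects) and
**inter-subject** (subjects partitioned into five folds; models never see
test subjects during training or tuning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix
from .tasks import TASKS

logger = logging.getLogger(__name__)

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {
        "n_neighbors": list(range(1, 29, 3)),  # 1, 4, ..., 28 (10 values)
        "metric": ["euclidean", "manhattan"],
        "weights": ["uniform", "distance"],
    },
    "svm": {
        "C": [0.01, 0.1, 1.0, 10.0, 50.0],
        "kernel": ["linear", "poly", "rbf", "sigmoid"],
    },
    "rf": {
        "max_depth": [5, 10, 20, 30, 40],
        "max_features": [20, 30, 40, 50, 60],
    },
}


@dataclass
class ModelConfig:
    """Classifier kind, hyperparameter grid, CV fold count and seed.

    ``fixed_params`` are passed to the estimator outside the grid (e.g.
    ``n_estimators`` for the forest).
    """

    kind: str
    grid: dict[str, list] | None = None
    cv_folds: int = 10
    seed: int = 0
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.kind].items()}


def _make_pipeline(cfg: ModelConfig):
    """Estimator pipeline + mapping from grid keys to pipeline parameters."""
    if cfg.kind == "knn":
        est = Pipeline(
            [("scale", StandardScaler()), ("clf", KNeighborsClassifier(**cfg.fixed_params))]
        )
        prefix = "clf__"
    elif cfg.kind == "svm":
        svc = SVC(random_state=cfg.seed, **cfg.fixed_params)
        est = Pipeline(
            [("scale", StandardScaler()), ("clf", OneVsRestClassifier(svc))]
        )
        prefix = "clf__estimator__"
    else:  # rf
        rf = RandomForestClassifier(random_state=cfg.seed, **cfg.fixed_params)
        est = Pipeline([("clf", rf)])
        prefix = "clf__"
    return est, prefix


def _feasible_grid(cfg: ModelConfig, n_features: int) -> dict[str, list]:
    grid = {k: list(v) for k, v in cfg.grid.items()}
    if cfg.kind == "rf" and "max_features" in grid:
        keep = [m for m in grid["max_features"] if not (isinstance(m, int) and m > n_features)]
        dropped = [m for m in grid["max_features"] if m not in keep]
        if dropped:
            logger.warning(
                "skipping infeasible rf max_features candidates %s for "
                "%d-dimensional features", dropped, n_features,
            )
        if not keep:
            keep = [n_features]
        grid["max_features"] = keep
    return grid


@dataclass
class TunedModel:
    estimator: object
    params: dict
    cv_accuracy: float
    cv_folds_used: int


def tune(train: FeatureMatrix, cfg: ModelConfig) -> TunedModel:
    """Exhaustive grid search by mean CV accuracy; ties go to the first
    candidate in grid order; the winner is refit on all training rows.

    If the rarest class has fewer members than ``cfg.cv_folds``, the fold
    count is reduced to that class count (with a warning) so stratified CV
    remains valid.
    """
    y = train.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training set contains a single class; cannot tune")
    folds = int(min(cfg.cv_folds, counts.min()))
    if folds < cfg.cv_folds:
        logger.warning(
            "reducing CV folds from %d to %d (rarest class has %d rows)",
            cfg.cv_folds, folds, counts.min(),
        )
    folds = max(folds, 2)
    est, prefix = _make_pipeline(cfg)
    grid = {prefix + k: v for k, v in _feasible_grid(cfg, train.values.shape[1]).items()}
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    search = GridSearchCV(est, grid, scoring="accuracy", cv=cv, n_jobs=None, refit=True)
    search.fit(train.values, y)
    params = {k.removeprefix(prefix): v for k, v in search.best_params_.items()}
    return TunedModel(
        estimator=search.best_estimator_,
        params=params,
        cv_accuracy=float(search.best_score_),
        cv_folds_used=folds,
    )


@dataclass
class Evaluation:
    """Metrics of one fitted model on one test partition."""

    per_class: pd.DataFrame  # index = the 10 labels; precision, recall, f1, absent
    accuracy: float
    confusion: np.ndarray  # (10, 10), rows = truth, cols = prediction
    n_test: int

    def __post_init__(self) -> None:
        # overall accuracy is, by construction, the micro-averaged recall
        micro = np.trace(self.confusion) / self.confusion.sum()
        assert abs(micro - self.accuracy) < 1e-12


def evaluate(model, test: FeatureMatrix) -> Evaluation:
    """Per-class precision/recall/F1 and overall accuracy over the 10-task
    label set.  Classes absent from both truth and prediction are flagged and
    reported as 0."""
    if test.values.shape[0] == 0:
        raise ValueError("empty test set")
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and test.values.shape[1] != n_expected:
        raise ValueError(
            f"test dimension {test.values.shape[1]} does not match the "
            f"model's {n_expected}"
        )
    y_true = test.labels
    y_pred = model.predict(test.values)
    labels = list(TASKS)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    absent = np.array(
        [(l not in set(y_true)) and (l not in set(y_pred)) for l in labels]
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "absent": absent}, index=labels
    )
    acc = float(np.trace(conf) / conf.sum())
    return Evaluation(per_class=per_class, accuracy=acc, confusion=conf, n_test=len(y_true))


@dataclass
class EvaluationReport:
    """Aggregated metrics for one (protocol, window, domain, model) cell.

    ``accuracy`` is the unweighted mean over evaluation units (subjects for
    the intra protocol, fold repetitions for inter); ``accuracy_sd`` its
    dispersion; ``unit_accuracies`` the per-unit values; ``confusion`` the
    element-wise sum over units.
    """

    protocol: str
    window_s: float
    domain: str
    model_kind: str
    per_class: pd.DataFrame
    accuracy: float
    accuracy_sd: float
    unit_accuracies: list[float]
    confusion: np.ndarray
    chosen_params: list[dict]
    units: list[str]

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "window_s": self.window_s,
            "domain": self.domain,
            "model": self.model_kind,
            "accuracy": self.accuracy,
            "accuracy_sd": self.accuracy_sd,
            "unit_accuracies": self.unit_accuracies,
            "per_class": self.per_class.to_dict(orient="index"),
            "chosen_params": self.chosen_params,
            "units": self.units,
        }


def _aggregate(
    protocol: str,
    matrix_like: FeatureMatrix,
    evals: list[Evaluation],
    params: list[dict],
    units: list[str],
    model_kind: str,
) -> EvaluationReport:
    per_class = sum(e.per_class[["precision", "recall", "f1"]] for e in evals) / len(evals)
    accs = [e.accuracy for e in evals]
    return EvaluationReport(
        protocol=protocol,
        window_s=matrix_like.window_s,
        domain=matrix_like.domain,
        model_kind=model_kind,
        per_class=per_class,
        accuracy=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        unit_accuracies=[float(a) for a in accs],
        confusion=sum(e.confusion for e in evals),
        chosen_params=params,
        units=units,
    )


def stratified_split_indices(
    labels: np.ndarray, test_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per class: shuffle, hold out round(test_frac * n) rows (at least 1)."""
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_frac * idx.size)))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def intra_subject_eval(
    matrix: FeatureMatrix,
    cfg: ModelConfig,
    split_seed: int = 0,
    min_per_class: int = 5,
    test_frac: float = 0.2,
) -> EvaluationReport:
    """Individualized models: per subject, stratified 80/20 split, tune on
    the 80%, test on the 20%; metrics averaged (unweighted) over subjects."""
    evals, params, units = [], [], []
    rng = np.random.default_rng(split_seed)
    for sid, sub in matrix.by_subject().items():
        _, counts = np.unique(sub.labels, return_counts=True)
        if counts.min() < min_per_class:
            logger.warning(
                "skipping subject %s: only %d windows in rarest class",
                sid, counts.min(),
            )
            continue
        tr_idx, te_idx = stratified_split_indices(sub.labels, test_frac, rng)
        tuned = tune(sub.subset(tr_idx), cfg)
        evals.append(evaluate(tuned.estimator, sub.subset(te_idx)))
        params.append(tuned.params)
        units.append(sid)
    if not evals:
        raise ValueError("no subject had enough windows per class")
    return _aggregate("intra", matrix, evals, params, units, cfg.kind)


def subject_folds(
    subject_ids: list[str], n_folds: int, rng: np.random.Generator
) -> list[list[str]]:
    """Balanced random partition of subjects into folds (sizes differ by at
    most one)."""
    order = rng.permutation(sorted(subject_ids))
    return [list(chunk) for chunk in np.array_split(order, n_folds)]


def inter_subject_eval(
    matrix: FeatureMatrix,
    cfg: ModelConfig,
    fold_seed: int = 0,
    n_folds: int = 5,
) -> EvaluationReport:
    """Generalized models: subjects split into five folds; each fold serves
    once as the test set while the pooled remaining subjects are used for
    tuning and training.  No test subject's data enters training."""
    sids = sorted(set(matrix.subject_ids))
    if len(sids) < n_folds:
        raise ValueError(
            f"inter-subject protocol needs at least {n_folds} subjects, got {len(sids)}"
        )
    rng = np.random.default_rng(fold_seed)
    folds = subject_folds(sids, n_folds, rng)
    evals, params, units = [], [], []
    for k, test_sids in enumerate(folds):
        test_mask = np.isin(matrix.subject_ids, test_sids)
        train = matrix.subset(~test_mask)
        test = matrix.subset(test_mask)
        assert not set(train.subject_ids) & set(test.subject_ids)
        tuned = tune(train, cfg)
        evals.append(evaluate(tuned.estimator, test))
        params.append(tuned.params)
        units.append(f"fold{k + 1}:" + "+".join(test_sids))
    return _aggregate("inter", matrix, evals, params, units, cfg.kind)
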