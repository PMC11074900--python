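"""Depression detection from z-scored dietary features with an RBF-SVM.

Stratified 5-fold cross-validation (train:validation 4:1 per fold) around a
support vector machine with a radial basis function kernel, C = 0.1 and
gamma = 0.001 by default.  Reported metrics are accuracy, macro precision,
macro recall, macro F1 and one-vs-rest macro AUC computed from decision
scores, averaged over folds.  Tasks are three-class (HC / mild /
moderate-severe) or binary (HC / moderate-severe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass
class ClassifierConfig:
    C: float = 0.1
    gamma: float = 0.001
    n_folds: int = 5
    seed: int = 0
    class_weight: str | None = None      # None (default) or "balanced"
    average: str = "macro"               # macro (default) or weighted

    def validate(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class MetricsReport:
    accuracy: float
    f1: float
    precision: float
    recall: float
    auc: float
    per_fold: pd.DataFrame = field(repr=False, default=None)
    n_dropped: int = 0

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1,
                "precision": self.precision, "recall": self.recall, "auc": self.auc}


def _drop_missing(X: pd.DataFrame, y: np.ndarray):
    X = pd.DataFrame(X)
    mask = ~X.isna().any(axis=1).to_numpy()
    return X.loc[mask].to_numpy(float), np.asarray(y, object)[mask], int((~mask).sum())


def crossval_svm(X, y, config: ClassifierConfig | None = None) -> MetricsReport:
    """Stratified k-fold cross-validated RBF-SVM metrics.

    Rows with any missing feature are dropped (count reported); each class
    must have at least ``n_folds`` members so that every training fold sees
    every class.
    """
    config = config or ClassifierConfig()
    config.validate()
    Xa, ya, n_dropped = _drop_missing(X, y)
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"stratification error: class {classes[counts.argmin()]!r} has "
            f"{counts.min()} members, fewer than n_folds={config.n_folds}")

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    rows = []
    avg = config.average
    for fold, (tr, te) in enumerate(skf.split(Xa, ya)):
        clf = SVC(C=config.C, gamma=config.gamma, kernel="rbf",
                  class_weight=config.class_weight,
                  decision_function_shape="ovr")
        clf.fit(Xa[tr], ya[tr])
        pred = clf.predict(Xa[te])
        scores = clf.decision_function(Xa[te])
        if len(classes) == 2:
            pos = clf.classes_[1]
            auc = skm.roc_auc_score((ya[te] == pos).astype(int), scores)
        else:
            # one-vs-rest AUC from raw decision scores, averaged over classes
            per_class = [
                skm.roc_auc_score((ya[te] == c).astype(int), scores[:, k])
                for k, c in enumerate(clf.classes_)
            ]
            if avg == "weighted":
                w = np.array([(ya[te] == c).sum() for c in clf.classes_], float)
                auc = float(np.average(per_class, weights=w))
            else:
                auc = float(np.mean(per_class))
        rows.append({
            "fold": fold,
            "accuracy": skm.accuracy_score(ya[te], pred),
            "f1": skm.f1_score(ya[te], pred, average=avg, zero_division=0),
            "precision": skm.precision_score(ya[te], pred, average=avg, zero_division=0),
            "recall": skm.recall_score(ya[te], pred, average=avg, zero_division=0),
            "auc": auc,
        })
    per_fold = pd.DataFrame(rows)
    means = per_fold.drop(columns="fold").mean()
    return MetricsReport(accuracy=float(means["accuracy"]), f1=float(means["f1"]),
                         precision=float(means["precision"]), recall=float(means["recall"]),
                         auc=float(means["auc"]), per_fold=per_fold, n_dropped=n_dropped)


def grid_search(X, y, grid_C, grid_gamma, config: ClassifierConfig | None = None):
    """Best (C, gamma) by mean cross-validated accuracy.

    Ties break toward smaller C then smaller gamma.  The search folds are
    seeded independently of the final evaluation folds (derived seed) so the
    selection does not peek at the evaluation split.
    """
    config = config or ClassifierConfig()
    grid_C, grid_gamma = sorted(set(grid_C)), sorted(set(grid_gamma))
    if not grid_C or not grid_gamma:
        raise ValueError("grid must be non-empty")
    search_cfg_seed = (config.seed * 2654435761 + 1) % (2**31)
    best, best_acc = None, -np.inf
    for C in grid_C:
        for gamma in grid_gamma:
            cfg = ClassifierConfig(C=C, gamma=gamma, n_folds=config.n_folds,
                                   seed=search_cfg_seed, class_weight=config.class_weight,
                                   average=config.average)
            acc = crossval_svm(X, y, cfg).accuracy
            if acc > best_acc:  # strict: earlier (smaller C, gamma) wins ties
                best, best_acc = (C, gamma), acc
    return best


@dataclass
class DepressionDetector:
    """sklearn-style estimator wrapping the cross-validation harness.

    ``fit`` trains the final SVM on all rows; :meth:`cross_validate` runs the
    stratified 5-fold evaluation and stores the report in ``cv_report_``.
    """

    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params):
        for k, v in params.items():
            if k != "config":
                raise ValueError(f"unknown parameter {k!r}")
            self.config = v
        return self

    def fit(self, X, y):
        Xa, ya, self.n_dropped_ = _drop_missing(X, y)
        self.config.validate()
        self.svm_ = SVC(C=self.config.C, gamma=self.config.gamma, kernel="rbf",
                        class_weight=self.config.class_weight,
                        decision_function_shape="ovr")
        self.svm_.fit(Xa, ya)
        self.classes_ = self.svm_.classes_
        return self

    def predict(self, X):
        return self.svm_.predict(np.asarray(pd.DataFrame(X), float))

    def decision_function(self, X):
        return self.svm_.decision_function(np.asarray(pd.DataFrame(X), float))

    def cross_validate(self, X, y) -> MetricsReport:
        self.cv_report_ = crossval_svm(X, y, self.config)
        return self.cv_report_
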