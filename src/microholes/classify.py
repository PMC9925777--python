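"""Patch-level classification of test (KO) versus control (WT) patches.

An RBF-kernel support vector classifier (C = 3, scale-heuristic kernel
width) is trained on a subset of the persistence statistics.  Features are
standardised with parameters estimated on the training folds only, since an
RBF SVC on raw heterogeneous feature scales is degenerate.  Evaluation uses
stratified 10-fold cross-validation re-randomised over repeats, reporting
mean accuracy, precision, recall and F1 (KO as the positive class), with
metrics averaged over folds and then over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PANEL10",
    "PANEL20",
    "MicroholeClassifier",
    "ClassifierReport",
    "evaluate_classifier",
    "fit_predict",
]

_TEN = [
    "n_points", "entropy",
    "mean_birth", "median_birth", "sd_birth", "p25_birth",
    "mean_death", "median_death", "sd_death", "p75_death",
]

#: ten H0-quadrant-2 statistics: counts, entropy, birth/death location and
#: spread.  IQRs, the 25th death percentile and the radius-thresholded counts
#: are excluded (each is redundant with or weaker than the included features).
PANEL10 = [f"h0q2_{s}" for s in _TEN]

#: PANEL10 plus the same ten statistics from H1 quadrant 1
PANEL20 = PANEL10 + [f"h1q1_{s}" for s in _TEN]

_FEATURE_SETS = {"panel10": PANEL10, "panel20": PANEL20}


def resolve_features(feature_set) -> list[str]:
    if isinstance(feature_set, str):
        if feature_set not in _FEATURE_SETS:
            raise ValueError(f"unknown feature set {feature_set!r}; choose from {list(_FEATURE_SETS)}")
        return list(_FEATURE_SETS[feature_set])
    return list(feature_set)


class MicroholeClassifier(BaseEstimator, ClassifierMixin):
    """Standardised RBF-SVC over a named persistence-statistic feature set.

    Accepts a panel DataFrame (feature columns selected by name) or a plain
    array.  Rows with missing feature values are dropped at fit time with a
    warning; at predict time they raise, since silently dropping test rows
    would desynchronise predictions from inputs.
    """

    def __init__(self, feature_set="panel10", C: float = 3.0, gamma="scale",
                 positive_label: str = "KO"):
        self.feature_set = feature_set
        self.C = C
        self.gamma = gamma
        self.positive_label = positive_label

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            features = resolve_features(self.feature_set)
            missing = [f for f in features if f not in X.columns]
            if missing:
                raise ValueError(f"unseen feature names: {missing}")
            return X[features].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y):
        M = self._matrix(X)
        y = np.asarray(y)
        keep = ~np.isnan(M).any(axis=1)
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} rows with missing feature values")
            M, y = M[keep], y[keep]
        if np.unique(y).size < 2:
            raise ValueError("training data must cover both classes")
        self.pipeline_ = Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(C=self.C, kernel="rbf", gamma=self.gamma))]
        )
        self.pipeline_.fit(M, y)
        self.classes_ = self.pipeline_.classes_
        self.n_features_in_ = M.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        M = self._matrix(X)
        if np.isnan(M).any():
            raise ValueError("missing feature values in prediction input")
        return self.pipeline_.predict(M)

    def decision_function(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.decision_function(self._matrix(X))


@dataclass
class ClassifierReport:
    modality: str
    sex: str
    feature_set: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    folds: int
    repeats: int
    seed: int | None
    per_repeat: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "modality": self.modality, "sex": self.sex, "feature_set": self.feature_set,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "folds": self.folds, "repeats": self.repeats, "seed": self.seed,
        }


def evaluate_classifier(
    panel: pd.DataFrame,
    modality: str | None = None,
    sex: str | None = None,
    feature_set="panel10",
    C: float = 3.0,
    folds: int = 10,
    repeats: int = 100,
    seed: int | None = None,
    label_column: str = "genotype",
) -> ClassifierReport:
    """Repeated stratified k-fold evaluation of the patch classifier.

    Filters the panel to one modality and sex, then runs ``repeats`` full
    stratified ``folds``-fold cross-validations, re-randomising fold
    assignment each repeat.  Standardisation is fitted inside each training
    fold (no leakage).  Patches with missing feature values are dropped with
    a warning before splitting.
    """
    sub = panel
    if modality is not None and "modality" in sub.columns:
        sub = sub[sub["modality"] == modality]
    if sex is not None and "sex" in sub.columns:
        sub = sub[sub["sex"] == sex]
    features = resolve_features(feature_set)
    missing_cols = [f for f in features if f not in sub.columns]
    if missing_cols:
        raise ValueError(f"panel lacks feature columns: {missing_cols}")
    M = sub[features].to_numpy(dtype=float)
    y = sub[label_column].to_numpy()
    keep = ~np.isnan(M).any(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} patches with missing feature values")
        M, y = M[keep], y[keep]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"expected 2 classes, got {list(classes)}")
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} patches < {folds} folds; "
            "use fewer folds"
        )
    pos = "KO" if "KO" in classes else classes[0]

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        fold_metrics = []
        for train, test in skf.split(M, y):
            clf = MicroholeClassifier(feature_set=None, C=C)  # plain-array input
            clf.fit(M[train], y[train])
            pred = clf.predict(M[test])
            fold_metrics.append((
                accuracy_score(y[test], pred),
                precision_score(y[test], pred, pos_label=pos, zero_division=0),
                recall_score(y[test], pred, pos_label=pos, zero_division=0),
                f1_score(y[test], pred, pos_label=pos, zero_division=0),
            ))
        rows.append(np.mean(fold_metrics, axis=0))
    per_repeat = pd.DataFrame(rows, columns=["accuracy", "precision", "recall", "f1"])
    mean = per_repeat.mean()
    return ClassifierReport(
        modality=modality or "all", sex=sex or "all",
        feature_set=feature_set if isinstance(feature_set, str) else "custom",
        accuracy=float(mean["accuracy"]), precision=float(mean["precision"]),
        recall=float(mean["recall"]), f1=float(mean["f1"]),
        folds=folds, repeats=repeats,
        seed=int(seed) if seed is not None else None,
        per_repeat=per_repeat,
    )


def fit_predict(
    train_panel: pd.DataFrame,
    test_panel: pd.DataFrame,
    feature_set="panel10",
    C: float = 3.0,
    label_column: str = "genotype",
):
    """Single-split entry point: fit on one panel, score another.

    Returns (predicted labels, decision values) for the test panel.
    """
    clf = MicroholeClassifier(feature_set=feature_set, C=C)
    clf.fit(train_panel, train_panel[label_column].to_numpy())
    return clf.predict(test_panel), clf.decision_function(test_panel)
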