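"""Linear-SVM classification of subjects from community-matrix features.

Features are the community-matrix values at the selected connections, all in
[0, 1], so no standardisation is applied.  The classifier is a linear-kernel
maximum-margin SVM with regularisation constant C = 1 and unweighted hinge
loss.  Patients are the positive class: sensitivity is the true-positive
rate among patients, specificity the true-negative rate among controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .selection import ConnectionSet, DiscriminantEdgeSelector, _as_K_stack

POSITIVE_LABEL = "patient"
NEGATIVE_LABEL = "control"

__all__ = [
    "FeatureTable",
    "ClassifierReport",
    "build_features",
    "train_and_evaluate",
    "CommunityNetworkClassifier",
]


@dataclass
class FeatureTable:
    """Subjects-by-edges feature matrix with its label vector."""

    X: np.ndarray
    y: np.ndarray | None
    edge_list: ConnectionSet


@dataclass
class ClassifierReport:
    """Held-out confusion counts and the derived rates."""

    tp: int
    tn: int
    fp: int
    fn: int
    n_train: int
    n_test: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def build_features(subjects, edges: ConnectionSet, y=None) -> FeatureTable:
    """X[s, e] = K_s(i_e, j_e) for each subject s and selected edge e."""
    K = _as_K_stack(subjects)
    N = K.shape[1]
    for i, j in edges.edges:
        if not (0 <= i < N and 0 <= j < N):
            raise ValueError(f"edge ({i}, {j}) out of range for {N} regions")
    ii = np.array([e[0] for e in edges.edges])
    jj = np.array([e[1] for e in edges.edges])
    X = K[:, ii, jj]
    return FeatureTable(X=X, y=None if y is None else np.asarray(y), edge_list=edges)


def train_and_evaluate(
    train: FeatureTable,
    test: FeatureTable,
    C: float = 1.0,
    positive_label: str = POSITIVE_LABEL,
) -> ClassifierReport:
    """Fit a linear-kernel SVM on ``train`` and score ``test``."""
    if train.y is None or test.y is None:
        raise ValueError("feature tables must carry labels")
    if len(set(train.y)) < 2:
        raise ValueError("training set contains a single class")
    clf = SVC(kernel="linear", C=C)
    clf.fit(train.X, train.y)
    pred = clf.predict(test.X)
    pos = test.y == positive_label
    hit = pred == test.y
    return ClassifierReport(
        tp=int(np.sum(pos & hit)),
        tn=int(np.sum(~pos & hit)),
        fp=int(np.sum(~pos & ~hit)),
        fn=int(np.sum(pos & ~hit)),
        n_train=len(train.y),
        n_test=len(test.y),
    )


class CommunityNetworkClassifier(ClassifierMixin, BaseEstimator):
    """Edge selection + linear SVM as one sklearn estimator.

    ``fit(X, y)`` expects an (n_subjects, n_edges) matrix of community
    values — columns are upper-triangle edges — and binary labels.  The h
    columns with largest absolute between-group mean difference are kept
    and a linear-kernel SVM (C fixed) is trained on them.
    """

    def __init__(self, h: int = 10, C: float = 1.0):
        self.h = h
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.pipeline_ = Pipeline(
            [
                ("select", DiscriminantEdgeSelector(h=self.h)),
                ("svm", SVC(kernel="linear", C=self.C)),
            ]
        )
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.named_steps["svm"].classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(np.asarray(X, float))

    def decision_function(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.decision_function(np.asarray(X, float))
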