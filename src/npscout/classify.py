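"""Random-forest NP/SM classifier, evaluation metrics and cross-validation.

The classifier is a random forest with 100 trees, ``max_features = sqrt``
and balanced class weights, trained on binary fingerprints (or the
16-descriptor physicochemical matrix).  NP-likeness is reported as the NP
class probability — the mean of the per-tree class distributions (soft
voting), which yields the fine-grained probability histograms used for
library profiling.  A molecule is called NP iff its probability strictly
exceeds 0.5; ties classify as SM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .datasets import NP, SM, TrainingMatrix
from .features import (
    FingerprintKind,
    PHYSCHEM_FIELDS,
    maccs_key_names,
)

DECISION_THRESHOLD = 0.5
MODEL_SCHEMA_VERSION = 1


class NPClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest natural-product-likeness classifier.

    Parameters
    ----------
    feature_set : {"maccs", "morgan2", "physchem"}
        Which descriptor family the model expects.  MACCS is the default
        flavor (low complexity, interpretable keys); similarity maps require
        a ``"morgan2"`` model.
    n_estimators : int, default 100
        Number of trees.
    random_state : int, default 0
        Forest seed; fixed for reproducible probabilities.

    The forest always uses ``max_features="sqrt"`` and
    ``class_weight="balanced"`` (weights inversely proportional to class
    frequencies).

    Attributes
    ----------
    forest_ : fitted ``RandomForestClassifier``
    classes_ : ``[0, 1]`` (SM, NP)
    feature_importances_ : impurity-based importances, summing to 1
    metadata_ : dict of hyperparameters and training provenance
    """

    def __init__(
        self,
        feature_set: str = "maccs",
        n_estimators: int = 100,
        random_state: int = 0,
    ):
        self.feature_set = feature_set
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _expected_width(self) -> Optional[int]:
        return {"maccs": 166, "morgan2": 1024, "physchem": len(PHYSCHEM_FIELDS)}.get(
            self.feature_set
        )

    def fit(self, X, y=None) -> "NPClassifier":
        if isinstance(X, TrainingMatrix):
            if y is not None:
                raise ValueError("pass either a TrainingMatrix or (X, y), not both")
            y = X.y
            provenance = dict(X.provenance)
            X = X.X
        else:
            provenance = {}
        X = np.asarray(X)
        y = np.asarray(y, dtype=int)
        if X.shape[0] == 0:
            raise ValueError("empty training matrix")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        width = self._expected_width()
        if width is not None and X.shape[1] != width:
            raise ValueError(
                f"feature_set={self.feature_set!r} expects {width} columns, got {X.shape[1]}"
            )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features="sqrt",
            class_weight="balanced",
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        self.metadata_ = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "feature_set": self.feature_set,
            "n_estimators": self.n_estimators,
            "max_features": "sqrt",
            "class_weight": "balanced",
            "random_state": self.random_state,
            "n_training_rows": int(X.shape[0]),
            "training_provenance": provenance,
        }
        return self

    @property
    def feature_importances_(self) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.feature_importances_

    def predict_np_probability(self, X) -> np.ndarray:
        """NP class probability: mean of per-tree leaf class distributions."""
        check_is_fitted(self, "forest_")
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[None, :]
        col = int(np.flatnonzero(self.forest_.classes_ == NP)[0])
        return self.forest_.predict_proba(X)[:, col]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X))

    def predict(self, X) -> np.ndarray:
        """NP iff probability strictly exceeds 0.5; ties classify as SM."""
        p = self.predict_np_probability(X)
        return np.where(p > DECISION_THRESHOLD, NP, SM)

    def feature_importances(
        self, feature_names: Optional[Sequence[str]] = None
    ) -> list[tuple[str, float]]:
        """Importances sorted descending, paired with feature names.

        For MACCS models the default names carry the 1-based key index and
        its SMARTS pattern; for the physicochemical model the descriptor
        names; otherwise the bit index.
        """
        imp = self.feature_importances_
        if feature_names is None:
            if self.feature_set == "maccs":
                feature_names = maccs_key_names()
            elif self.feature_set == "physchem":
                feature_names = list(PHYSCHEM_FIELDS)
            else:
                feature_names = [f"morgan2_{i}" for i in range(len(imp))]
        if len(feature_names) != len(imp):
            raise ValueError("feature_names length mismatch")
        ranked = sorted(zip(feature_names, imp), key=lambda t: (-t[1], t[0]))
        return [(name, float(v)) for name, v in ranked]

    def save(self, path: str) -> None:
        check_is_fitted(self, "forest_")
        joblib.dump({"model": self, "metadata": self.metadata_}, path)

    @staticmethod
    def load(path: str) -> "NPClassifier":
        payload = joblib.load(path)
        return payload["model"]


def train_rf(
    matrix: TrainingMatrix, n_trees: int = 100, seed: int = 0
) -> NPClassifier:
    """Train an :class:`NPClassifier` on a prepared training matrix."""
    feature_set = (
        "maccs"
        if matrix.fingerprint_kind is FingerprintKind.MACCS166
        else "morgan2"
    )
    clf = NPClassifier(
        feature_set=feature_set, n_estimators=n_trees, random_state=seed
    )
    return clf.fit(matrix)


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    Returns 0 when any marginal (TP+FP, TP+FN, TN+FP, TN+FN) is zero, the
    standard convention for degenerate confusion matrices.
    """
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with NP=1 as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == NP) & (y_pred == NP)))
    fp = int(np.sum((y_true == SM) & (y_pred == NP)))
    tn = int(np.sum((y_true == SM) & (y_pred == SM)))
    fn = int(np.sum((y_true == NP) & (y_pred == SM)))
    return tp, fp, tn, fn


def mcc_from_labels(y_true, y_pred) -> float:
    return mcc(*confusion_counts(y_true, y_pred))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve for NP=1 positives.

    Equals the normalized Mann-Whitney U statistic; tied scores contribute
    one half.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class EvalReport:
    """Per-fold and pooled evaluation results."""

    tp: int
    fp: int
    tn: int
    fn: int
    mcc: float
    auc: float
    fold_mccs: list[float] = field(default_factory=list)
    fold_aucs: list[float] = field(default_factory=list)

    @property
    def mean_fold_mcc(self) -> float:
        return float(np.mean(self.fold_mccs)) if self.fold_mccs else self.mcc

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs)) if self.fold_aucs else self.auc

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "mcc": self.mcc,
            "auc": self.auc,
            "fold_mccs": self.fold_mccs,
            "fold_aucs": self.fold_aucs,
            "mean_fold_mcc": self.mean_fold_mcc,
            "mean_fold_auc": self.mean_fold_auc,
        }


def evaluate(model: NPClassifier, X, y) -> EvalReport:
    """Confusion counts, MCC and AUC of a fitted model on held-out data."""
    p = model.predict_np_probability(np.asarray(X))
    pred = np.where(p > DECISION_THRESHOLD, NP, SM)
    tp, fp, tn, fn = confusion_counts(y, pred)
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn, mcc=mcc(tp, fp, tn, fn), auc=roc_auc(p, y)
    )


def k_fold_cv(
    matrix_or_X,
    y=None,
    k: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
    feature_set: Optional[str] = None,
) -> EvalReport:
    """Stratified k-fold cross-validation of the random forest.

    Folds are disjoint and exhaustive; each fold's model is seeded from
    ``seed`` so the report is deterministic.  Pooled confusion counts and
    pooled AUC are reported alongside the per-fold values.
    """
    if isinstance(matrix_or_X, TrainingMatrix):
        X, y = matrix_or_X.X, matrix_or_X.y
        if feature_set is None:
            feature_set = (
                "maccs"
                if matrix_or_X.fingerprint_kind is FingerprintKind.MACCS166
                else "morgan2"
            )
    else:
        X = np.asarray(matrix_or_X)
        y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    # stratified folds by default; plain folds when k exceeds the minority
    # class count (e.g. leave-one-out), where stratification is impossible
    min_class = int(np.bincount(y).min())
    if k <= min_class:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_mccs, fold_aucs = [], []
    pooled_p = np.zeros(len(y))
    pooled_pred = np.zeros(len(y), dtype=int)
    for train_idx, test_idx in splitter.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training fold lost one class; reduce k")
        clf = NPClassifier(
            feature_set=feature_set or "custom",
            n_estimators=n_estimators,
            random_state=seed,
        )
        clf.fit(X[train_idx], y[train_idx])
        p = clf.predict_np_probability(X[test_idx])
        pred = np.where(p > DECISION_THRESHOLD, NP, SM)
        fold_mccs.append(mcc_from_labels(y[test_idx], pred))
        if len(np.unique(y[test_idx])) == 2:
            fold_aucs.append(roc_auc(p, y[test_idx]))
        pooled_p[test_idx] = p
        pooled_pred[test_idx] = pred
    tp, fp, tn, fn = confusion_counts(y, pooled_pred)
    return EvalReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        mcc=mcc(tp, fp, tn, fn),
        auc=roc_auc(pooled_p, y),
        fold_mccs=fold_mccs,
        fold_aucs=fold_aucs,
    )
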