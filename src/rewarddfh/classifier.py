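"""Linear max-margin classifier of reward vs punishment condition rows.

The hyperplane is a soft-margin linear SVM minimizing
``0.5 * ||w||^2 + C * sum(hinge losses)`` on the standardized, selected
training features. The orientation convention is enforced after every fit:
the mean signed distance of the training reward observations is positive,
so "toward/below the hyperplane" always means a weaker reward response.

``grouped_cv_evaluate`` estimates out-of-subject performance: subjects are
partitioned into k folds, and within each fold's training split the full
preprocessing chain (standardizer, lasso selection, SVM) is refit from
scratch, so no statistic computed on held-out subjects ever informs the
model that classifies them. Confusion counts are pooled over folds with
reward as the positive class.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ConvergenceError, DegenerateDataError, ValidationError
from . import features as feat
from .synthetic import REWARD

__all__ = ["Hyperplane", "CVResult", "fit_hyperplane", "grouped_cv_evaluate"]


@dataclass
class Hyperplane:
    """Linear decision boundary {x : w.x + b = 0} over the selected regions,
    in standardized-feature units, oriented so the reward side is positive."""

    weights: np.ndarray
    intercept: float
    region_ids: list[str]
    C: float
    orientation_flipped: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.weights.shape[0] != len(self.region_ids):
            raise ValidationError("weight/region length mismatch")
        if not np.linalg.norm(self.weights) > 0:
            raise DegenerateDataError("zero weight vector")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.weights))

    def decision_values(self, X) -> np.ndarray:
        """Raw w.x + b for rows of X (array or frame over region_ids)."""
        if isinstance(X, pd.DataFrame):
            missing = [r for r in self.region_ids if r not in X.columns]
            if missing:
                raise ValidationError(f"missing selected regions: {missing[:10]}")
            X = X[self.region_ids].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.region_ids):
            raise ValidationError(
                f"expected {len(self.region_ids)} features, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite feature values")
        return X @ self.weights + self.intercept

    def predict(self, X) -> np.ndarray:
        """+1 (reward side) / -1 (punishment side); on-plane points -> -1."""
        return np.where(self.decision_values(X) > 0, 1, -1)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "region_ids": self.region_ids,
            "C": self.C,
            "orientation_flipped": self.orientation_flipped,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperplane":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            region_ids=list(d["region_ids"]),
            C=float(d["C"]),
            orientation_flipped=bool(d.get("orientation_flipped", False)),
        )


def fit_hyperplane(
    standardized: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    region_ids: list[str] | None = None,
) -> Hyperplane:
    """Fit the soft-margin linear SVM and enforce orientation.

    ``labels`` are +1 (reward) / -1 (punishment). The fitted (w, b) are
    negated if needed so that the mean decision value of the reward rows
    is positive.
    """
    if C <= 0:
        raise ValidationError(f"C must be > 0, got {C}")
    if isinstance(standardized, pd.DataFrame):
        region_ids = list(standardized.columns)
        X = standardized.to_numpy(dtype=float)
    else:
        X = np.asarray(standardized, dtype=float)
        if region_ids is None:
            region_ids = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("single-class input: both labels required")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite feature values")

    model = SVC(kernel="linear", C=C, tol=1e-6, max_iter=2_000_000)
    model.fit(X, y)
    if model.n_iter_ is not None and np.any(np.asarray(model.n_iter_) >= 2_000_000):
        raise ConvergenceError("SVM optimizer hit its iteration budget")
    w = model.coef_.ravel().astype(float)
    b = float(model.intercept_[0])
    # sklearn's decision_function is positive for classes_[1]; re-express in
    # our +1=reward convention, then enforce the orientation invariant
    if model.classes_[1] != 1:
        w, b = -w, -b
    flipped = False
    reward_mean = np.mean(X[y == 1] @ w + b)
    if reward_mean < 0:
        w, b, flipped = -w, -b, True
    return Hyperplane(
        weights=w, intercept=b, region_ids=region_ids, C=C,
        orientation_flipped=flipped,
    )


@dataclass
class CVResult:
    """Pooled grouped-CV confusion counts and metrics, reward = positive."""

    tp: int
    fp: int
    tn: int
    fn: int
    folds: int
    seed: int
    C: float
    fold_subjects: list[list[str]]
    positive_class: str = REWARD

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def to_dict(self) -> dict:
        return {
            "confusion": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "folds": self.folds,
            "seed": self.seed,
            "C": self.C,
            "positive_class": self.positive_class,
            "fold_subjects": self.fold_subjects,
        }


def grouped_cv_evaluate(
    features_table: pd.DataFrame,
    training_ids,
    k: int = 10,
    C: float = 1.0,
    seed: int = 0,
    selection_kwargs: dict | None = None,
) -> CVResult:
    """Subject-grouped k-fold CV with full nested preprocessing.

    Within each fold: standardizer fit on the fold's training subjects,
    lasso selection on those standardized rows, SVM on the selected
    features; the held-out subjects' rows are then scored. Counts are
    pooled over folds.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    # sorted so fold assignment depends only on the subject set + seed,
    # never on row order in the input table
    ids = sorted(set(training_ids))
    if len(ids) < k:
        raise DegenerateDataError(f"{len(ids)} subjects < {k} folds")
    selection_kwargs = dict(selection_kwargs or {})

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_subjects: list[list[str]] = [[] for _ in range(k)]
    for pos, subj_i in enumerate(order):
        fold_subjects[pos % k].append(ids[subj_i])

    tp = fp = tn = fn = 0
    for fold in range(k):
        held = set(fold_subjects[fold])
        train_ids = [s for s in ids if s not in held]
        std = feat.fit_standardizer(features_table, train_ids)
        Xtr, ytr, gtr = feat.training_matrix(std.transform(features_table), train_ids)
        if len(np.unique(ytr)) < 2:
            raise DegenerateDataError(f"fold {fold}: single class after split")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = feat.select_features(
                Xtr, ytr, gtr,
                seed=seed + 1 + fold,
                **selection_kwargs,
            )
        Xte, yte, _ = feat.training_matrix(std.transform(features_table), held)
        if sel.empty:
            # no discriminative signal in this fold's training split: score
            # the held-out rows with the intercept-only rule (training
            # majority class; the balanced paired design ties -> punishment)
            majority = 1 if np.sum(ytr == 1) > np.sum(ytr == -1) else -1
            pred = np.full(len(yte), majority)
        else:
            plane = fit_hyperplane(Xtr[sel.region_ids], ytr, C=C)
            pred = plane.predict(Xte[sel.region_ids])
        tp += int(np.sum((pred == 1) & (yte == 1)))
        fp += int(np.sum((pred == 1) & (yte == -1)))
        tn += int(np.sum((pred == -1) & (yte == -1)))
        fn += int(np.sum((pred == -1) & (yte == 1)))

    return CVResult(
        tp=tp, fp=fp, tn=tn, fn=fn, folds=k, seed=seed, C=C,
        fold_subjects=fold_subjects,
    )
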