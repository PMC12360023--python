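"""Prediction functions over descriptor vectors, and their evaluation.

Four learner families are supported: Lasso linear regression (LLR),
decision trees (DT), random forests (RF) and single-hidden-layer neural
networks (ANN), all via scikit-learn.  Evaluation follows the repeated
cross-validation protocol of the descriptor-comparison experiments:
10 repetitions of 5-fold CV with balanced fold sizes, scored by the
coefficient of determination R^2 (regression) or balanced accuracy
BACC (classification), summarised by the median of the 50 fold values.

For classification with LLR the real-valued score is thresholded at
theta, chosen on the training set to maximise the tilde-BACC criterion
in which a molecule scoring exactly theta counts as correct for *both*
classes (TP uses score >= r, TN uses score <= r); prediction is positive
iff theta <= score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.metrics import balanced_accuracy_score, r2_score
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

LEARNERS = ("llr", "dt", "rf", "ann")
TASKS = ("regression", "classification")

#: LLR penalty grid searched by inner 5-fold CV.  The grid reaches down
#: to 2^-20 so that (near-)noiseless linear data is fit essentially
#: exactly rather than visibly shrunk.
LLR_ALPHA_GRID = tuple(float(2.0 ** k) for k in range(-20, 3))


def r_squared(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Coefficient of determination: 1 - RSS / TSS about the mean."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need matching y_true/y_pred with at least 2 points")
    if np.allclose(y_true, y_true[0]):
        raise ValueError("zero total variance: R^2 undefined")
    return float(r2_score(y_true, y_pred))


def balanced_accuracy(labels: Sequence[int], predictions: Sequence[int]) -> float:
    """Mean of sensitivity and specificity over 0/1 labels."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes must be present in labels")
    return float(balanced_accuracy_score(labels, predictions))


def select_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Training-set threshold theta maximising the tilde-BACC criterion.

    Candidates are the training scores themselves; for a candidate r,
    TP~ counts positives with score >= r and TN~ counts negatives with
    score <= r (a point at r counts for both sides).  Ties are broken to
    the smallest maximising r.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    c1 = int(np.sum(labels == 1))
    c0 = int(np.sum(labels == 0))
    if c1 == 0 or c0 == 0:
        raise ValueError("training set must contain both classes")
    best_r, best_v = None, -1.0
    for r in sorted(set(scores.tolist())):
        tp = np.sum((labels == 1) & (scores >= r))
        tn = np.sum((labels == 0) & (scores <= r))
        v = 0.5 * (tp / c1 + tn / c0)
        if v > best_v + 1e-12:
            best_v, best_r = v, r
    assert best_r is not None
    return float(best_r)


@dataclass
class Hyperplane:
    """Linear prediction function eta(x) = w . x + b over named columns."""

    columns: list[str]
    w: np.ndarray
    b: float
    theta: float | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.columns),):
            raise ValueError("weight length must equal the column count")

    def score(self, X) -> np.ndarray:
        X = self._as_matrix(X)
        return X @ self.w + self.b

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.columns if c not in X.columns]
            if missing:
                raise ValueError(f"feature matrix lacks columns: {missing}")
            X = X[self.columns].to_numpy(dtype=float)
        return np.atleast_2d(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        s = self.score(X)
        if self.theta is None:
            return s
        return (s >= self.theta).astype(int)

    def to_json(self) -> str:
        return json.dumps({
            "kind": "llr",
            "columns": self.columns,
            "w": self.w.tolist(),
            "b": self.b,
            "theta": self.theta,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Hyperplane":
        raw = json.loads(text)
        return cls(columns=list(raw["columns"]), w=np.asarray(raw["w"], dtype=float),
                   b=float(raw["b"]),
                   theta=None if raw.get("theta") is None else float(raw["theta"]))


@dataclass
class TrainedModel:
    """A fitted prediction function; LLR models also expose a hyperplane."""

    kind: str
    task: str
    columns: list[str]
    estimator: object
    hyperplane: Hyperplane | None = None

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.columns].to_numpy(dtype=float)
        return np.atleast_2d(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        if self.kind == "llr":
            return self.hyperplane.predict(self._matrix(X))
        return self.estimator.predict(self._matrix(X))


def train(features: pd.DataFrame, targets: Sequence[float], learner: str,
          task: str, hyperparams: dict | None = None, seed: int = 0) -> TrainedModel:
    """Fit one prediction function on a feature matrix.

    ``learner`` is one of llr/dt/rf/ann; ``task`` regression or
    classification.  LLR always fits a linear score by lasso (penalty
    chosen by inner 5-fold CV over :data:`LLR_ALPHA_GRID`); for
    classification its threshold theta is then selected on the training
    scores with :func:`select_threshold`.
    """
    if learner not in LEARNERS:
        raise ValueError(f"unknown learner {learner!r}; choose from {LEARNERS}")
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {TASKS}")
    hp = dict(hyperparams or {})
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    y = np.asarray(targets, dtype=float)
    columns = list(features.columns)

    if learner == "llr":
        alphas = np.asarray(hp.pop("alphas", LLR_ALPHA_GRID), dtype=float)
        inner_cv = int(hp.pop("cv", 5))
        est = LassoCV(alphas=alphas, cv=min(inner_cv, len(y)), max_iter=200000,
                      tol=1e-8, random_state=seed, **hp)
        est.fit(X, y)
        plane = Hyperplane(columns, est.coef_.copy(), float(est.intercept_))
        if task == "classification":
            plane.theta = select_threshold(plane.score(X), y.astype(int))
        return TrainedModel("llr", task, columns, est, plane)

    if learner == "dt":
        cls = DecisionTreeRegressor if task == "regression" else DecisionTreeClassifier
        est = cls(random_state=seed, **hp)
    elif learner == "rf":
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        est = cls(n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp)
    else:  # ann
        cls = MLPRegressor if task == "regression" else MLPClassifier
        est = cls(hidden_layer_sizes=hp.pop("hidden_layer_sizes", (64,)),
                  early_stopping=True, max_iter=2000, random_state=seed, **hp)
    est.fit(X, y.astype(int) if task == "classification" else y)
    return TrainedModel(learner, task, columns, est)


@dataclass
class EvalProtocol:
    """Repeated k-fold protocol: 10 x 5-fold CV, scored by R^2 or BACC."""

    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0
    metric: str = "auto"  # R2 for regression, BACC for classification


def fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into folds whose sizes differ by at most one."""
    perm = rng.permutation(n)
    return [np.asarray(f) for f in np.array_split(perm, n_folds)]


@dataclass
class CVSummary:
    values: list[float] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def median(self) -> float:
        ok = [v for v in self.values if not np.isnan(v)]
        return float(np.median(ok)) if ok else float("nan")


def cross_validate(features: pd.DataFrame, targets: Sequence[float], learner: str,
                   task: str, protocol: EvalProtocol = EvalProtocol(),
                   hyperparams: dict | None = None) -> CVSummary:
    """All n_repeats x n_folds fold scores and their median.

    Folds are random but reproducible from the protocol seed.  A fold on
    which the metric's precondition fails (constant test targets for
    R^2, a single-class test fold for BACC) contributes NaN and is
    reported in ``errors``; the median is taken over the valid values.
    """
    y = np.asarray(targets, dtype=float)
    n = len(y)
    if n < protocol.n_folds:
        raise ValueError("data set smaller than the number of folds")
    rng = np.random.default_rng(protocol.seed)
    out = CVSummary()
    for rep in range(protocol.n_repeats):
        folds = fold_indices(n, protocol.n_folds, rng)
        for i, test_idx in enumerate(folds):
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
            model = train(features.iloc[train_idx], y[train_idx], learner, task,
                          hyperparams, seed=protocol.seed + rep)
            pred = model.predict(features.iloc[test_idx])
            try:
                if task == "regression":
                    v = r_squared(y[test_idx], pred)
                else:
                    v = balanced_accuracy(y[test_idx].astype(int), pred)
            except ValueError as exc:
                out.values.append(float("nan"))
                out.errors.append(f"repeat {rep} fold {i}: {exc}")
                continue
            out.values.append(v)
    return out
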