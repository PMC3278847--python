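"""Weighted soft-margin RBF-kernel classification of feature vectors.

The classifier is a support vector machine with a radial-basis kernel,
C = 10, gamma = 1 / number-of-feature-elements, and class weights that
rebalance the heavy excess of non-binding residues: the positive class
weight defaults to n_neg / n_pos while the negative class weight is 1.
Evaluation uses stratified k-fold cross-validation with a pooled
(micro-averaged) confusion over all held-out predictions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .metrics import ConfusionCounts, MetricsReport, confusion, report
from .redundancy import DedupedDataset

__all__ = ["TrainedModel", "train", "predict", "cross_validate",
           "save_model", "load_model"]

FORMAT_VERSION = 1


@dataclass
class TrainedModel:
    estimator: SVC
    c: float
    gamma: float
    w_plus: float
    w_minus: float
    n_features: int
    n_pos: int
    n_neg: int
    schema_hash: str = ""

    @property
    def hyperparams(self) -> dict:
        return {"C": self.c, "gamma": self.gamma, "w_plus": self.w_plus,
                "w_minus": self.w_minus, "kernel": "rbf"}


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, DedupedDataset):
        vectors = dataset.vectors
    else:
        vectors = list(dataset)
    if not vectors:
        raise ValueError("empty training dataset")
    X = np.vstack([v.values for v in vectors])
    y = np.array([v.label for v in vectors], dtype=int)
    return X, y


def train(dataset, c: float = 10.0, gamma: float | str = "auto",
          weights: dict[int, float] | str = "auto", seed: int = 0) -> TrainedModel:
    """Fit the weighted RBF-kernel SVM.

    ``gamma='auto'`` resolves to 1/#features; ``weights='auto'`` resolves to
    {+1: n_neg/n_pos, -1: 1}.  Training is deterministic given the input
    order and seed.
    """
    X, y = _as_arrays(dataset)
    if not np.all(np.isfinite(X)):
        raise ValueError("training data contains non-finite values")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training data must contain both classes")

    gamma_val = 1.0 / X.shape[1] if gamma == "auto" else float(gamma)
    if weights == "auto":
        weights = {1: n_neg / n_pos, -1: 1.0}
    est = SVC(C=c, kernel="rbf", gamma=gamma_val, class_weight=weights,
              random_state=seed)
    est.fit(X, y)
    return TrainedModel(estimator=est, c=c, gamma=gamma_val,
                        w_plus=weights[1], w_minus=weights[-1],
                        n_features=X.shape[1], n_pos=n_pos, n_neg=n_neg)


def predict(model: TrainedModel, vectors) -> np.ndarray:
    """Hard +/-1 labels for feature vectors matching the model schema."""
    if isinstance(vectors, np.ndarray):
        X = np.atleast_2d(vectors)
    else:
        vectors = list(vectors)
        if not vectors:
            return np.array([], dtype=int)
        X = np.vstack([v.values for v in vectors])
    if X.shape[1] != model.n_features:
        raise ValueError(f"vector length {X.shape[1]} does not match "
                         f"model schema ({model.n_features} features)")
    return model.estimator.predict(X).astype(int)


def cross_validate(dataset, k: int = 5, seed: int = 0, c: float = 10.0,
                   gamma: float | str = "auto",
                   weights: dict[int, float] | str = "auto",
                   ) -> tuple[list[ConfusionCounts], ConfusionCounts, MetricsReport]:
    """Stratified k-fold cross-validation with pooled held-out confusion.

    Returns (per-fold confusions, pooled confusion, pooled metrics).  Every
    vector is held out exactly once; folds are label-stratified with sizes
    differing by at most one.
    """
    X, y = _as_arrays(dataset)
    if k < 2:
        raise ValueError("k must be at least 2")
    for cls in (1, -1):
        if int(np.sum(y == cls)) < k:
            raise ValueError(f"class {cls:+d} has fewer than k={k} members")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_counts: list[ConfusionCounts] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for train_idx, test_idx in skf.split(X, y):
        y_tr = y[train_idx]
        gamma_val = 1.0 / X.shape[1] if gamma == "auto" else float(gamma)
        if weights == "auto":
            w = {1: int(np.sum(y_tr == -1)) / int(np.sum(y_tr == 1)), -1: 1.0}
        else:
            w = weights
        est = SVC(C=c, kernel="rbf", gamma=gamma_val, class_weight=w,
                  random_state=seed)
        est.fit(X[train_idx], y_tr)
        counts = confusion(y[test_idx], est.predict(X[test_idx]).astype(int))
        fold_counts.append(counts)
        pooled = pooled + counts
    return fold_counts, pooled, report(pooled)


def save_model(model: TrainedModel, path, schema_hash: str = "") -> None:
    payload = {"format_version": FORMAT_VERSION, "estimator": model.estimator,
               "hyperparams": model.hyperparams, "n_features": model.n_features,
               "n_pos": model.n_pos, "n_neg": model.n_neg,
               "schema_hash": schema_hash or model.schema_hash}
    joblib.dump(payload, path)


def load_model(path, expect_schema_hash: str | None = None) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    if expect_schema_hash is not None and payload["schema_hash"] != expect_schema_hash:
        raise ValueError("model schema hash does not match the provided schema")
    hp = payload["hyperparams"]
    return TrainedModel(estimator=payload["estimator"], c=hp["C"], gamma=hp["gamma"],
                        w_plus=hp["w_plus"], w_minus=hp["w_minus"],
                        n_features=payload["n_features"], n_pos=payload["n_pos"],
                        n_neg=payload["n_neg"], schema_hash=payload["schema_hash"])


def schema_hash(schema) -> str:
    """Stable hash of a feature schema layout, for model/vector compatibility."""
    text = repr(sorted(schema.to_dict().items()))
    return hashlib.sha256(text.encode()).hexdigest()[:16]
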