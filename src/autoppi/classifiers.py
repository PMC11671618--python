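"""The three model families and the training protocol.

:class:`BinnedNaiveBayes`, :class:`GiniDecisionTree` and
:class:`StandardizedKNN` are scikit-learn-compatible estimators
(``fit`` / ``predict_proba`` / ``predict``, ``get_params`` /
``set_params``, trailing-underscore fitted attributes) so they compose
with sklearn pipelines and model selection.  Their internals are spelled
out exactly so every prediction is reproducible against a brute-force
oracle:

* NB is categorical on binned features with Laplace smoothing
  ``(count + alpha) / (class_total + alpha * n_bins)``;
* the tree is CART-style with Gini impurity, ties between splits broken
  by lowest feature index then lowest threshold;
* KNN uses Euclidean distance on z-standardized features, odd ``k``,
  exact distance ties broken by training-row order, and handles missing
  values by training-median imputation plus a missingness indicator.

A model is *accepted* when both its training and testing
misclassification rates (at score threshold 0.5) are at or below the
error ceiling of 0.15.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold, train_test_split

log = logging.getLogger("autoppi")

ERROR_CEILING = 0.15


# ----------------------------------------------------------------------
# naive Bayes
# ----------------------------------------------------------------------

class BinnedNaiveBayes(BaseEstimator, ClassifierMixin):
    """Categorical naive Bayes over binned features.

    Parameters
    ----------
    alpha : float
        Laplace pseudocount.  ``alpha=0`` permits zero conditionals.
    n_categories : sequence of int, optional
        Number of bin values per feature (e.g. value bins + missing bin
        from a :class:`~autoppi.features.BinningScheme`).  When omitted,
        the category set of each feature is the set of distinct values
        seen in training, and the smoothing denominator uses its size.
    """

    def __init__(self, alpha: float = 1.0, n_categories=None):
        self.alpha = alpha
        self.n_categories = n_categories

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y).astype(int)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("both classes must be present")
        n, f = X.shape
        if self.n_categories is None:
            self.categories_ = [np.unique(X[:, j]) for j in range(f)]
        else:
            if len(self.n_categories) != f:
                raise ValueError("n_categories length must equal n_features")
            self.categories_ = [np.arange(c) for c in self.n_categories]
        self.class_count_ = np.array([(y == c).sum() for c in self.classes_], dtype=float)
        self.class_prior_ = self.class_count_ / n
        # conditional_[j][i, b] = P(feature j in bin b | class i)
        self.conditional_ = []
        for j, cats in enumerate(self.categories_):
            lookup = {v: i for i, v in enumerate(cats)}
            table = np.zeros((2, len(cats)))
            col = X[:, j]
            for ci, c in enumerate(self.classes_):
                vals = col[y == c]
                for v in vals:
                    if v not in lookup:
                        raise ValueError(f"feature {j}: bin value {v!r} outside the "
                                         f"declared categories")
                    table[ci, lookup[v]] += 1
                denom = self.class_count_[ci] + self.alpha * len(cats)
                table[ci] = (table[ci] + self.alpha) / denom
            self.conditional_.append(table)
        return self

    def _joint(self, X):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != len(self.categories_):
            raise ValueError("X has the wrong number of features")
        joint = np.tile(self.class_prior_, (X.shape[0], 1))
        for j, cats in enumerate(self.categories_):
            lookup = {v: i for i, v in enumerate(cats)}
            idx = np.empty(X.shape[0], dtype=int)
            for r, v in enumerate(X[:, j]):
                if v not in lookup:
                    raise ValueError(f"feature {j}: unseen bin value {v!r}")
                idx[r] = lookup[v]
            joint *= self.conditional_[j][:, idx].T
        return joint

    def predict_proba(self, X):
        joint = self._joint(X)
        total = joint.sum(axis=1, keepdims=True)
        proba = np.tile(self.class_prior_, (joint.shape[0], 1))
        ok = total[:, 0] > 0
        proba[ok] = joint[ok] / total[ok]
        return proba

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]


# ----------------------------------------------------------------------
# decision tree
# ----------------------------------------------------------------------

def gini_impurity(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    p = y.mean()
    return float(2.0 * p * (1.0 - p))


def best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Exhaustive (feature, threshold) search maximizing Gini decrease.

    Candidate thresholds are midpoints between consecutive distinct
    sorted values; the left child takes ``x <= threshold``.  Ties are
    broken toward the lowest feature index, then the lowest threshold.
    Returns ``(feature, threshold, decrease)`` or ``None``.
    """
    n, f = X.shape
    parent = gini_impurity(y)
    best = None
    for j in range(f):
        vals = np.unique(X[:, j])
        if vals.size < 2:
            continue
        for t in (vals[:-1] + vals[1:]) / 2.0:
            mask = X[:, j] <= t
            nl = int(mask.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            dec = parent - (nl * gini_impurity(y[mask])
                            + (n - nl) * gini_impurity(y[~mask])) / n
            if best is None or dec > best[2] + 1e-12:
                best = (j, float(t), float(dec))
    if best is None or best[2] <= 1e-12:
        return None
    return best


class GiniDecisionTree(BaseEstimator, ClassifierMixin):
    """CART-style binary tree; leaf score = positive-class fraction."""

    def __init__(self, max_depth: int = 6, min_leaf: int = 5):
        self.max_depth = max_depth
        self.min_leaf = min_leaf

    def _grow(self, X, y, depth):
        node = {"n": int(y.size), "value": float(y.mean())}
        if depth >= self.max_depth or y.size < 2 * self.min_leaf or len(np.unique(y)) < 2:
            return node
        split = best_split(X, y, self.min_leaf)
        if split is None:
            return node
        j, t, dec = split
        mask = X[:, j] <= t
        node.update(feature=j, threshold=t, decrease=dec,
                    left=self._grow(X[mask], y[mask], depth + 1),
                    right=self._grow(X[~mask], y[~mask], depth + 1))
        return node

    def fit(self, X, y):
        if self.max_depth < 1:
            raise ValueError(f"max_depth must be >= 1, got {self.max_depth}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        self.tree_ = self._grow(X, y, 0)
        return self

    def _score_one(self, x):
        node = self.tree_
        while "feature" in node:
            node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
        return node["value"]

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        pos = np.array([self._score_one(x) for x in X])
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ----------------------------------------------------------------------
# k-nearest neighbors
# ----------------------------------------------------------------------

class StandardizedKNN(BaseEstimator, ClassifierMixin):
    """k-NN with z-standardization, median imputation and miss indicators.

    Score = fraction of positives among the ``k`` nearest training rows
    by Euclidean distance; exact distance ties are broken by
    training-row order (stable sort).
    """

    def __init__(self, k: int = 5):
        self.k = k

    def _prepare(self, X):
        X = np.asarray(X, dtype=float)
        miss = np.isnan(X)
        filled = np.where(miss, self.medians_, X)
        z = (filled - self.means_) / self.scales_
        return np.hstack([z, miss.astype(float)])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.size == 0:
            raise ValueError("empty training set")
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError(f"k must be an odd positive integer, got {self.k}")
        if self.k > len(y):
            raise ValueError(f"k={self.k} exceeds training size {len(y)}")
        self.classes_ = np.unique(y)
        with np.errstate(all="ignore"):
            med = np.nanmedian(X, axis=0)
        self.medians_ = np.where(np.isnan(med), 0.0, med)
        filled = np.where(np.isnan(X), self.medians_, X)
        self.means_ = filled.mean(axis=0)
        scales = filled.std(axis=0)
        self.scales_ = np.where(scales == 0, 1.0, scales)
        self._train = self._prepare(X)
        self._y = y
        return self

    def neighbor_indices(self, X) -> np.ndarray:
        """Indices of the k nearest training rows per query row."""
        Z = self._prepare(X)
        d2 = ((Z[:, None, :] - self._train[None, :, :]) ** 2).sum(axis=2)
        order = np.argsort(d2, axis=1, kind="stable")
        return order[:, : self.k]

    def predict_proba(self, X):
        nn = self.neighbor_indices(X)
        pos = self._y[nn].mean(axis=1)
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ----------------------------------------------------------------------
# protocol: split, cross-validation, learning curve, acceptance
# ----------------------------------------------------------------------

def stratified_split(table: pd.DataFrame, train_fraction: float, seed: int,
                     label_col: str = "label") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test partition (default protocol: 7:3)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    y = table[label_col]
    if y.value_counts().min() < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    train, test = train_test_split(table, train_size=train_fraction,
                                   stratify=y, random_state=seed)
    return train.reset_index(drop=True), test.reset_index(drop=True)


def misclassification(model, X, y) -> float:
    return float((model.predict(X) != np.asarray(y)).mean())


def kfold_cv(make_model, X, y, k_folds: int = 10, seed: int = 0) -> tuple[float, float]:
    """Stratified k-fold CV; returns (mean, sd) of per-fold error."""
    y = np.asarray(y).astype(int)
    counts = np.bincount(y)
    if k_folds < 2 or k_folds > counts[counts > 0].min():
        raise ValueError(f"k_folds={k_folds} infeasible for class counts {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    X = np.asarray(X, dtype=float)
    errors = []
    for tr, te in skf.split(X, y):
        model = make_model() if callable(make_model) else clone(make_model)
        model.fit(X[tr], y[tr])
        errors.append(misclassification(model, X[te], y[te]))
    return float(np.mean(errors)), float(np.std(errors))


def _stratified_subsample(X, y, fraction: float, seed: int):
    if fraction >= 1.0:
        return X, y
    sub, _ = train_test_split(np.arange(len(y)), train_size=fraction,
                              stratify=y, random_state=seed)
    sub = np.sort(sub)
    return X[sub], y[sub]


def learning_curve(make_model, X, y, fractions, seed: int = 0,
                   k_folds: int = 10) -> list[dict]:
    """Train/validation accuracy at growing training-set sizes.

    The validation accuracy at fraction f is 1 minus the stratified
    k-fold CV error on a stratified subsample of size f*n, so the point
    at f = 1.0 coincides with :func:`kfold_cv` on the full table.
    Fractions whose subsample cannot sustain the CV protocol are skipped
    with a warning; duplicates are collapsed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    points = []
    for frac in sorted(set(float(f) for f in fractions)):
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"fraction {frac} outside (0, 1]")
        Xs, ys = _stratified_subsample(X, y, frac, seed)
        counts = np.bincount(ys)
        if counts[counts > 0].min() < max(2, k_folds):
            log.warning("learning_curve: fraction %.3g leaves too few samples per "
                        "class; skipped", frac)
            continue
        cv_mean, _ = kfold_cv(make_model, Xs, ys, k_folds=k_folds, seed=seed)
        model = make_model() if callable(make_model) else clone(make_model)
        model.fit(Xs, ys)
        points.append({"fraction": frac, "n_train": int(len(ys)),
                       "train_accuracy": 1.0 - misclassification(model, Xs, ys),
                       "validation_accuracy": 1.0 - cv_mean})
    return points


@dataclass
class FitReport:
    """Training summary and the error-ceiling acceptance decision."""

    model_name: str
    training_error: float
    testing_error: float
    cv_mean_error: float
    cv_sd_error: float
    error_ceiling: float = ERROR_CEILING
    learning_curve: list[dict] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return (self.training_error <= self.error_ceiling
                and self.testing_error <= self.error_ceiling)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["accepted"] = self.accepted
        return d


def fit_and_report(model, name: str, X_train, y_train, X_test, y_test,
                   k_folds: int = 10, seed: int = 0,
                   error_ceiling: float = ERROR_CEILING) -> FitReport:
    """Fit under the split/CV protocol and apply the acceptance rule."""
    model.fit(X_train, y_train)
    cv_mean, cv_sd = kfold_cv(lambda: clone(model), X_train, y_train,
                              k_folds=k_folds, seed=seed)
    report = FitReport(
        model_name=name,
        training_error=misclassification(model, X_train, y_train),
        testing_error=misclassification(model, X_test, y_test),
        cv_mean_error=cv_mean,
        cv_sd_error=cv_sd,
        error_ceiling=error_ceiling,
    )
    log.info("%s: training_error=%.3f testing_error=%.3f cv=%.3f±%.3f accepted=%s",
             name, report.training_error, report.testing_error,
             cv_mean, cv_sd, report.accepted)
    return report


# ----------------------------------------------------------------------
# model serialization (versioned JSON)
# ----------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model, path: str | Path) -> None:
    payload = {"format_version": _FORMAT_VERSION,
               "class": type(model).__name__,
               "params": model.get_params()}
    if isinstance(model, BinnedNaiveBayes):
        payload["state"] = {
            "classes": model.classes_.tolist(),
            "class_prior": model.class_prior_.tolist(),
            "class_count": model.class_count_.tolist(),
            "categories": [c.tolist() for c in model.categories_],
            "conditional": [t.tolist() for t in model.conditional_],
        }
    elif isinstance(model, GiniDecisionTree):
        payload["state"] = {"classes": model.classes_.tolist(),
                            "n_features": model.n_features_in_,
                            "tree": model.tree_}
    elif isinstance(model, StandardizedKNN):
        payload["state"] = {
            "classes": model.classes_.tolist(),
            "medians": model.medians_.tolist(),
            "means": model.means_.tolist(),
            "scales": model.scales_.tolist(),
            "train": model._train.tolist(),
            "y": model._y.tolist(),
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('format_version')}")
    cls = {"BinnedNaiveBayes": BinnedNaiveBayes,
           "GiniDecisionTree": GiniDecisionTree,
           "StandardizedKNN": StandardizedKNN}[payload["class"]]
    model = cls(**payload["params"])
    s = payload["state"]
    model.classes_ = np.array(s["classes"])
    if cls is BinnedNaiveBayes:
        model.class_prior_ = np.array(s["class_prior"])
        model.class_count_ = np.array(s["class_count"])
        model.categories_ = [np.array(c) for c in s["categories"]]
        model.conditional_ = [np.array(t) for t in s["conditional"]]
    elif cls is GiniDecisionTree:
        model.n_features_in_ = s["n_features"]
        model.tree_ = s["tree"]
    else:
        model.medians_ = np.array(s["medians"])
        model.means_ = np.array(s["means"])
        model.scales_ = np.array(s["scales"])
        model._train = np.array(s["train"])
        model._y = np.array(s["y"])
    return model
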