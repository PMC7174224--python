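"""The 22-classifier benchmark suite and the repeated stratified CV engine.

The suite reproduces a classification-toolbox preset collection: 3 decision
trees, 2 discriminants, 6 SVMs, 6 nearest-neighbor variants and 5 ensembles,
each frozen to a documented hyperparameter preset. Evaluation is k-fold
stratified cross-validation repeated with independent random partitions;
each repetition reports the pooled out-of-fold accuracy, and mean +- SD over
repetitions summarizes a classifier.

Distance/kernel-based models see z-scored features; the scaler is fit on
the training folds only (no test-set leakage). Tree-based models use raw
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelSpec",
    "CvConfig",
    "CvResult",
    "RusBoostClassifier",
    "model_suite",
    "stratified_folds",
    "run_cv",
]

FAMILIES = ("tree", "discriminant", "svm", "knn", "ensemble")


@dataclass(frozen=True)
class ModelSpec:
    """One preset: a display name, its family, and an estimator factory.

    ``factory(n_features, random_state)`` returns an unfitted scikit-learn
    estimator. ``standardize`` controls whether a z-score scaler (fit on
    training folds) is prepended.
    """

    id: str
    family: str
    name: str
    factory: Callable[[int, int], BaseEstimator]
    standardize: bool = True

    def build(self, n_features: int, random_state: int = 0) -> BaseEstimator:
        est = self.factory(n_features, random_state)
        if self.standardize:
            return Pipeline([("scale", StandardScaler()), ("model", est)])
        return est


@dataclass(frozen=True)
class CvConfig:
    k: int = 5
    repetitions: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not self.stratified:
            raise ValueError("only stratified CV is supported")


@dataclass
class CvResult:
    """Repeated-CV outcome for one classifier."""

    spec_id: str
    accuracies: list[float]  # per repetition, percent
    oof_predictions: list[np.ndarray] = field(default_factory=list)
    oof_scores: list[np.ndarray] = field(default_factory=list)
    classes: np.ndarray | None = None
    failures: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


class RusBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosted shallow trees with random undersampling at every round.

    SAMME-style multiclass boosting in which each round's tree is fit on a
    class-balanced random undersample (all classes cut to the minority
    count) of the weighted training set. Undersampling makes boosting
    robust to class imbalance at the cost of discarding majority-class
    examples each round.
    """

    def __init__(self, n_estimators: int = 30, learning_rate: float = 0.1,
                 max_leaf_nodes: int = 21, random_state: int = 0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_leaf_nodes = max_leaf_nodes
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, k = len(y), len(self.classes_)
        rng = np.random.default_rng(self.random_state)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        n_min = np.bincount(y_idx, minlength=k).min()
        for _ in range(self.n_estimators):
            idx = []
            for c in range(k):
                members = np.flatnonzero(y_idx == c)
                take = min(n_min, members.size)
                pw = w[members] / w[members].sum()
                idx.append(rng.choice(members, size=take, replace=False, p=pw))
            idx = np.concatenate(idx)
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes,
                random_state=int(rng.integers(2**31)),
            ).fit(X[idx], y_idx[idx])
            pred = tree.predict(X)
            err = float(w[pred != y_idx].sum())
            if err >= 1.0 - 1.0 / k:
                continue
            err = max(err, 1e-12)
            alpha = self.learning_rate * (np.log((1 - err) / err) + np.log(k - 1))
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            w *= np.exp(alpha * (pred != y_idx))
            w /= w.sum()
            if err < 1e-10:
                break
        if not self.estimators_:  # fall back to a single stump
            tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y_idx)
            self.estimators_, self.alphas_ = [tree], [1.0]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        k = len(self.classes_)
        votes = np.zeros((X.shape[0], k))
        for tree, alpha in zip(self.estimators_, self.alphas_):
            pred = tree.predict(X)
            votes[np.arange(X.shape[0]), pred] += alpha
        return votes

    def predict_proba(self, X):
        votes = self.decision_function(X)
        e = np.exp(votes - votes.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class GaussianQuadraticDiscriminant(BaseEstimator, ClassifierMixin):
    """Quadratic discriminant with shrinkage-regularized class covariances.

    Each class k gets a Gaussian with its own covariance
    ``(1 - reg) * S_k + reg * (trace(S_k)/p) * I``, which stays full rank
    even when a class has fewer samples than features — the usual regime
    for a 120-feature table at desk-scale sample sizes.
    """

    def __init__(self, reg_param: float = 1e-3):
        self.reg_param = reg_param

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        p = X.shape[1]
        self.means_, self.precisions_, self.logdets_, self.priors_ = [], [], [], []
        for c in range(len(self.classes_)):
            Xc = X[y_idx == c]
            mu = Xc.mean(axis=0)
            diff = Xc - mu
            S = diff.T @ diff / Xc.shape[0]
            scale = max(np.trace(S) / p, 1e-12)
            cov = (1.0 - self.reg_param) * S + self.reg_param * scale * np.eye(p)
            self.means_.append(mu)
            self.precisions_.append(np.linalg.inv(cov))
            self.logdets_.append(np.linalg.slogdet(cov)[1])
            self.priors_.append(Xc.shape[0] / X.shape[0])
        return self

    def _log_posteriors(self, X):
        X = np.asarray(X, dtype=np.float64)
        out = np.empty((X.shape[0], len(self.classes_)))
        for c in range(len(self.classes_)):
            d = X - self.means_[c]
            maha = np.einsum("ij,jk,ik->i", d, self.precisions_[c], d)
            out[:, c] = np.log(self.priors_[c]) - 0.5 * (self.logdets_[c] + maha)
        return out

    def predict_proba(self, X):
        lp = self._log_posteriors(X)
        e = np.exp(lp - lp.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        check_is_fitted(self, "means_")
        return self.classes_[np.argmax(self._log_posteriors(X), axis=1)]


def _squared_inverse(distances: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        w = 1.0 / (distances**2)
    # exact matches get full weight
    inf = np.isinf(w)
    if inf.any():
        w[inf.any(axis=1)] = 0.0
        w[inf] = 1.0
    return w


def model_suite() -> list[ModelSpec]:
    """The 22 frozen presets: 3 trees, 2 discriminants, 6 SVMs, 6 KNNs, 5 ensembles.

    Gaussian-SVM kernel scales follow the fine/medium/coarse convention
    sqrt(P)/4, sqrt(P), 4 sqrt(P) (P = number of features), mapped to the
    RBF via gamma = 1/scale^2. Subspace ensembles draw ceil(P/2) features
    per learner; all ensembles use 30 learners.
    """
    specs: list[ModelSpec] = []

    def tree(leaves):
        return lambda P, rs: DecisionTreeClassifier(max_leaf_nodes=leaves, random_state=rs)

    specs += [
        ModelSpec("fine_tree", "tree", "Fine Tree", tree(101), standardize=False),
        ModelSpec("medium_tree", "tree", "Medium Tree", tree(21), standardize=False),
        ModelSpec("coarse_tree", "tree", "Coarse Tree", tree(5), standardize=False),
        ModelSpec("linear_discriminant", "discriminant", "Linear Discriminant",
                  lambda P, rs: LinearDiscriminantAnalysis()),
        ModelSpec("quadratic_discriminant", "discriminant", "Quadratic Discriminant",
                  lambda P, rs: GaussianQuadraticDiscriminant()),
    ]

    # SVC trains one-vs-one internally; class scores come from the
    # per-class ('ovr'-shaped) decision values, softmaxed downstream.
    def svc(**kw):
        return lambda P, rs: SVC(C=1.0, decision_function_shape="ovr", **kw)

    def gauss_svc(scale_of_p):
        def f(P, rs):
            gamma = 1.0 / scale_of_p(P) ** 2
            return SVC(C=1.0, kernel="rbf", gamma=gamma,
                       decision_function_shape="ovr")
        return f

    specs += [
        ModelSpec("linear_svm", "svm", "Linear SVM", svc(kernel="linear")),
        ModelSpec("quadratic_svm", "svm", "Quadratic SVM",
                  svc(kernel="poly", degree=2, coef0=1.0, gamma="scale")),
        ModelSpec("cubic_svm", "svm", "Cubic SVM",
                  svc(kernel="poly", degree=3, coef0=1.0, gamma="scale")),
        ModelSpec("fine_gaussian_svm", "svm", "Fine Gaussian SVM",
                  gauss_svc(lambda P: np.sqrt(P) / 4.0)),
        ModelSpec("medium_gaussian_svm", "svm", "Medium Gaussian SVM",
                  gauss_svc(lambda P: np.sqrt(P))),
        ModelSpec("coarse_gaussian_svm", "svm", "Coarse Gaussian SVM",
                  gauss_svc(lambda P: 4.0 * np.sqrt(P))),
    ]

    def knn(**kw):
        return lambda P, rs: KNeighborsClassifier(**kw)

    specs += [
        ModelSpec("fine_knn", "knn", "Fine KNN", knn(n_neighbors=1)),
        ModelSpec("medium_knn", "knn", "Medium KNN", knn(n_neighbors=10)),
        ModelSpec("coarse_knn", "knn", "Coarse KNN", knn(n_neighbors=100)),
        ModelSpec("cosine_knn", "knn", "Cosine KNN", knn(n_neighbors=10, metric="cosine")),
        ModelSpec("cubic_knn", "knn", "Cubic KNN", knn(n_neighbors=10, p=3)),
        ModelSpec("weighted_knn", "knn", "Weighted KNN",
                  knn(n_neighbors=10, weights=_squared_inverse)),
    ]

    half = lambda P: int(np.ceil(P / 2))
    specs += [
        ModelSpec("boosted_trees", "ensemble", "Boosted Trees",
                  lambda P, rs: AdaBoostClassifier(
                      estimator=DecisionTreeClassifier(max_leaf_nodes=21),
                      n_estimators=30, learning_rate=0.1, random_state=rs),
                  standardize=False),
        ModelSpec("bagged_trees", "ensemble", "Bagged Trees",
                  lambda P, rs: RandomForestClassifier(n_estimators=30, random_state=rs),
                  standardize=False),
        ModelSpec("subspace_discriminant", "ensemble", "Subspace Discriminant",
                  lambda P, rs: BaggingClassifier(
                      estimator=LinearDiscriminantAnalysis(),
                      n_estimators=30, bootstrap=False, max_features=half(P),
                      random_state=rs)),
        ModelSpec("subspace_knn", "ensemble", "Subspace KNN",
                  lambda P, rs: BaggingClassifier(
                      estimator=KNeighborsClassifier(n_neighbors=1),
                      n_estimators=30, bootstrap=False, max_features=half(P),
                      random_state=rs)),
        ModelSpec("rusboost_trees", "ensemble", "RUSBoost Trees",
                  lambda P, rs: RusBoostClassifier(n_estimators=30, random_state=rs),
                  standardize=False),
    ]

    assert len(specs) == 22 and len({s.id for s in specs}) == 22
    return specs


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Fold index (0..k-1) per sample; per-class counts differ by at most 1."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = fold
    return assignment


def _clamp_knn(estimator, n_train: int):
    """Cap n_neighbors at the training-fold size (coarse presets on small data)."""
    model = estimator.named_steps["model"] if isinstance(estimator, Pipeline) else estimator
    if isinstance(model, KNeighborsClassifier) and model.n_neighbors > n_train:
        model.set_params(n_neighbors=n_train)


def run_cv(features, labels, spec: ModelSpec, config: CvConfig = CvConfig()) -> CvResult:
    """Repeated stratified k-fold CV of one preset on a feature table.

    ``features`` is an (n, P) array or DataFrame with no missing values.
    Each repetition uses an independent partition (seed + repetition
    index); its accuracy is the pooled out-of-fold correct fraction in
    percent. Out-of-fold predictions and class-membership scores are kept
    per repetition for confusion/ROC analysis.
    """
    X = features.to_numpy(dtype=np.float64) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("features must be (n_samples, n_features) matching labels")
    if not np.isfinite(X).all():
        raise ValueError("feature table contains missing or non-finite values")
    classes = np.unique(y)
    result = CvResult(spec_id=spec.id, accuracies=[], classes=classes)
    for rep in range(config.repetitions):
        rep_seed = (config.seed + 7919 * rep) % (2**31)
        assignment = stratified_folds(y, config.k, rep_seed)
        pred = np.empty(len(y), dtype=object)
        scores = np.zeros((len(y), len(classes)))
        failed = False
        for fold in range(config.k):
            test = assignment == fold
            train = ~test
            est = spec.build(X.shape[1], random_state=rep_seed)
            _clamp_knn(est, int(train.sum()))
            try:
                est.fit(X[train], y[train])
                p = est.predict(X[test])
            except Exception as exc:  # surfaced, repetition dropped
                result.failures.append(f"rep {rep} fold {fold}: {exc}")
                failed = True
                break
            pred[test] = p
            scores[test] = _class_scores(est, X[test], classes)
        if failed:
            continue
        acc = 100.0 * float(np.mean(pred == y))
        result.accuracies.append(acc)
        result.oof_predictions.append(pred.astype(classes.dtype, copy=False))
        result.oof_scores.append(scores)
    if not result.accuracies:
        raise RuntimeError(f"{spec.id}: every repetition failed: {result.failures}")
    return result


def _class_scores(estimator, X, classes) -> np.ndarray:
    """Class-membership scores aligned to ``classes`` (probabilities when
    the model defines them, otherwise softmaxed decision values)."""
    model = estimator
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        fitted = model.classes_ if hasattr(model, "classes_") else model[-1].classes_
    else:
        dec = model.decision_function(X)
        if dec.ndim == 1:
            dec = np.column_stack([-dec, dec])
        e = np.exp(dec - dec.max(axis=1, keepdims=True))
        proba = e / e.sum(axis=1, keepdims=True)
        fitted = model.classes_ if hasattr(model, "classes_") else model[-1].classes_
    out = np.zeros((X.shape[0], len(classes)))
    pos = {c: i for i, c in enumerate(classes)}
    for j, c in enumerate(fitted):
        out[:, pos[c]] = proba[:, j]
    return out
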