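"""Six classifier families with a uniform per-gene importance adapter.

Families and their raw importance definitions:

============== =======================================================
lasso          L1-penalized logistic regression; coefficient at the
               CV-selected penalty (signed).
svm_linear     linear-kernel SVM, cost tuned on a 1..20 grid by CV;
               primal hyperplane weight per feature (signed).
decision_tree  CART with a small complexity floor; total impurity
               decrease accumulated over that feature's splits
               (unused features are exactly 0).
random_forest  up to 500 trees, tree count at the OOB-error minimum;
               mean impurity-decrease importance.
gbm            gradient-boosted trees (200 trees, learning rate 0.001,
               subsample 0.9, Bernoulli loss); relative influence
               (summed gain).
neural_net     multilayer perceptron with three hidden layers
               (default 8-5-3), squared-error loss and linear output,
               thresholded at 0.5; Garson-style absolute
               connection-weight contribution (Olden's signed variant
               behind a flag).
============== =======================================================

Every family is fit on per-gene z-scored training data (training moments
only; test data reuses them) and returns an ImportanceVector covering
every input gene — genes absent from the fitted model get exactly 0 —
so downstream weight fusion can rely on aligned gene sets. A model whose
weights are all zero is flagged degenerate instead of raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

FAMILIES = ("lasso", "svm_linear", "decision_tree",
            "random_forest", "gbm", "neural_net")

SIGNED_FAMILIES = frozenset({"lasso", "svm_linear"})


@dataclass(frozen=True)
class ModelSpec:
    family: str
    seed: int = 0
    hyperparameters: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"choose from {FAMILIES}")


@dataclass
class ImportanceVector:
    """One family's raw per-gene weights (signed for lasso/svm_linear)."""
    family: str
    weights: pd.Series
    degenerate: bool = False


@dataclass
class ModelPerformance:
    family: str
    cv_accuracy: float
    train_accuracy: float
    test_accuracy: float


@dataclass
class FittedModel:
    spec: ModelSpec
    genes: tuple
    scaler: StandardScaler
    estimator: object


class SquaredErrorNet(BaseEstimator, ClassifierMixin):
    """MLP trained with squared error on 0/1 labels and linear output,
    predicting by thresholding the network output at 0.5."""

    def __init__(self, hidden_layer_sizes=(8, 5, 3), max_iter=2000,
                 random_state=0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.net_ = MLPRegressor(
            hidden_layer_sizes=self.hidden_layer_sizes,
            activation="logistic", solver="lbfgs",
            max_iter=self.max_iter, random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.net_.fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        return (self.net_.predict(X) >= 0.5).astype(int)

    @property
    def coefs_(self):
        return self.net_.coefs_


def garson_importance(coefs) -> np.ndarray:
    """Garson-style importance: products of absolute connection weights
    propagated through all hidden layers, normalized to sum to 1."""
    contrib = np.abs(np.asarray(coefs[0]))
    for layer in coefs[1:]:
        contrib = contrib @ np.abs(np.asarray(layer))
    imp = contrib.sum(axis=1) if contrib.ndim == 2 else contrib
    total = imp.sum()
    return imp / total if total > 0 else imp


def olden_importance(coefs) -> np.ndarray:
    """Olden's signed variant: products of raw connection weights."""
    contrib = np.asarray(coefs[0])
    for layer in coefs[1:]:
        contrib = contrib @ np.asarray(layer)
    return contrib.sum(axis=1) if contrib.ndim == 2 else contrib


def _labels_to_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    return (y == "case").astype(int) if y.dtype.kind in "OU" else y.astype(int)


def _inner_cv(y, seed, k=10):
    counts = np.bincount(y)
    k_eff = int(min(k, counts[counts > 0].min()))
    return StratifiedKFold(n_splits=max(2, k_eff), shuffle=True,
                           random_state=seed)


def _fit_estimator(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Fit one family on standardized training data; returns the fitted
    sklearn estimator. Any family-internal tuning (lasso penalty path, SVM
    cost grid, forest size by OOB error) happens here."""
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    family = spec.family
    if family == "lasso":
        est = LogisticRegressionCV(
            Cs=hp.get("Cs", np.logspace(-4, 2, 40)),
            cv=_inner_cv(y, seed), penalty="l1", solver="liblinear",
            scoring="accuracy", max_iter=10000, random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        return est
    if family == "svm_linear":
        costs = hp.get("costs", tuple(range(1, 21)))
        cv = _inner_cv(y, seed)
        folds = list(cv.split(X, y))
        best_c, best_acc = None, -1.0
        for c in costs:
            accs = []
            for tr, va in folds:
                m = SVC(kernel="linear", C=c).fit(X[tr], y[tr])
                accs.append((m.predict(X[va]) == y[va]).mean())
            acc = float(np.mean(accs))
            if acc > best_acc + 1e-12:
                best_acc, best_c = acc, c
        return SVC(kernel="linear", C=best_c).fit(X, y)
    if family == "decision_tree":
        return DecisionTreeClassifier(
            criterion="gini",
            min_impurity_decrease=hp.get("min_impurity_decrease", 1e-5),
            random_state=seed,
        ).fit(X, y)
    if family == "random_forest":
        max_trees = int(hp.get("max_trees", 500))
        step = int(hp.get("tree_step", 50))
        grid = list(range(step, max_trees + 1, step))
        scan = RandomForestClassifier(
            n_estimators=0, warm_start=True, oob_score=True,
            random_state=seed, n_jobs=1,
        )
        oob_err = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for n in grid:
                scan.set_params(n_estimators=n)
                scan.fit(X, y)
                oob_err.append(1.0 - scan.oob_score_)
        best_n = grid[int(np.argmin(oob_err))]
        return RandomForestClassifier(
            n_estimators=best_n, random_state=seed, n_jobs=1,
        ).fit(X, y)
    if family == "gbm":
        return GradientBoostingClassifier(
            n_estimators=int(hp.get("n_estimators", 200)),
            learning_rate=float(hp.get("learning_rate", 0.001)),
            subsample=float(hp.get("subsample", 0.9)),
            random_state=seed,
        ).fit(X, y)
    if family == "neural_net":
        return SquaredErrorNet(
            hidden_layer_sizes=tuple(hp.get("hidden_layer_sizes", (8, 5, 3))),
            max_iter=int(hp.get("max_iter", 2000)),
            random_state=seed,
        ).fit(X, y)
    raise ValueError(f"unknown model family {family!r}")


def _extract_raw_weights(spec: ModelSpec, est) -> np.ndarray:
    family = spec.family
    if family == "lasso":
        return est.coef_[0].copy()
    if family == "svm_linear":
        return np.asarray(est.coef_)[0].copy()
    if family == "decision_tree":
        # total impurity decrease per feature, NOT normalized, so unused
        # features are exactly 0
        return est.tree_.compute_feature_importances(normalize=False)
    if family == "random_forest":
        return est.feature_importances_.copy()
    if family == "gbm":
        return est.feature_importances_.copy()
    if family == "neural_net":
        if spec.hyperparameters.get("signed_importance", False):
            return olden_importance(est.coefs_)
        return garson_importance(est.coefs_)
    raise ValueError(f"unknown model family {family!r}")


def _split_xy(matrix: pd.DataFrame, annotation: pd.DataFrame, split: str):
    ann = annotation.loc[matrix.columns]
    cols = ann.index[(ann["split"] == split).to_numpy()]
    if len(cols) == 0:
        raise ValueError(f"no samples in split {split!r}")
    X = matrix[cols].to_numpy(float).T
    y = _labels_to_binary(ann.loc[cols, "label"])
    return X, y


def cross_validate(spec: ModelSpec, matrix: pd.DataFrame,
                   annotation: pd.DataFrame, k: int = 10,
                   seed: Optional[int] = None) -> float:
    """Mean accuracy over k stratified folds of the training split.

    Standardization and any family-internal tuning are redone inside each
    fold (no leakage). k is reduced with a warning when a class has fewer
    than k training samples.
    """
    seed = spec.seed if seed is None else seed
    X, y = _split_xy(matrix, annotation, "train")
    min_class = int(np.bincount(y).min())
    if min_class < k:
        warnings.warn(
            f"reducing CV folds from {k} to {min_class} "
            f"(smallest class has {min_class} samples)"
        )
        k = min_class
    if k < 2:
        raise ValueError("cross-validation needs at least 2 samples per class")
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, va in folds.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        est = _fit_estimator(spec, scaler.transform(X[tr]), y[tr])
        pred = est.predict(scaler.transform(X[va]))
        accs.append(float((pred == y[va]).mean()))
    return float(np.mean(accs))


def fit_model(spec: ModelSpec, matrix: pd.DataFrame,
              annotation: pd.DataFrame, compute_cv: bool = True):
    """Fit one family on the training split of a DEG-restricted matrix.

    Returns ``(FittedModel, ImportanceVector, ModelPerformance)``. The
    matrix is genes x samples; features are z-scored per gene with training
    moments. Test accuracy is filled in when the annotation contains a test
    split, else NaN.
    """
    X, y = _split_xy(matrix, annotation, "train")
    if np.bincount(y).min() < 2:
        raise ValueError("need at least 2 training samples per class")
    scaler = StandardScaler().fit(X)
    est = _fit_estimator(spec, scaler.transform(X), y)
    raw = _extract_raw_weights(spec, est)
    weights = pd.Series(raw, index=matrix.index, name=spec.family)
    degenerate = bool(np.all(np.abs(raw) == 0))
    fitted = FittedModel(spec=spec, genes=tuple(matrix.index),
                         scaler=scaler, estimator=est)
    train_acc = float((est.predict(scaler.transform(X)) == y).mean())
    cv_acc = (cross_validate(spec, matrix, annotation)
              if compute_cv else float("nan"))
    ann = annotation.loc[matrix.columns]
    if (ann["split"] == "test").any():
        test_acc = evaluate_split(fitted, matrix, annotation)
    else:
        test_acc = float("nan")
    perf = ModelPerformance(family=spec.family, cv_accuracy=cv_acc,
                            train_accuracy=train_acc, test_accuracy=test_acc)
    return fitted, ImportanceVector(spec.family, weights, degenerate), perf


def evaluate_split(fitted: FittedModel, matrix: pd.DataFrame,
                   annotation: pd.DataFrame, split: str = "test") -> float:
    """Accuracy on a held-out split, reusing the training standardization."""
    missing = [g for g in fitted.genes if g not in matrix.index]
    if missing:
        raise ValueError(f"genes missing from evaluation matrix: {missing}")
    sub = matrix.loc[list(fitted.genes)]
    X, y = _split_xy(sub, annotation, split)
    pred = fitted.estimator.predict(fitted.scaler.transform(X))
    return float((pred == y).mean())


def fit_all_models(matrix: pd.DataFrame, annotation: pd.DataFrame,
                   families=FAMILIES, seed: int = 0,
                   hyperparameters: Optional[Mapping] = None,
                   compute_cv: bool = True):
    """Fit every family; returns (fitted dict, importance dict, performance
    DataFrame indexed by family)."""
    hyperparameters = hyperparameters or {}
    fitted, importances, rows = {}, {}, []
    for fam in families:
        spec = ModelSpec(family=fam, seed=seed,
                         hyperparameters=hyperparameters.get(fam, {}))
        fm, iv, perf = fit_model(spec, matrix, annotation,
                                 compute_cv=compute_cv)
        fitted[fam] = fm
        importances[fam] = iv
        rows.append({"family": fam, "cv_accuracy": perf.cv_accuracy,
                     "train_accuracy": perf.train_accuracy,
                     "test_accuracy": perf.test_accuracy})
    performance = pd.DataFrame(rows).set_index("family")
    return fitted, importances, performance
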