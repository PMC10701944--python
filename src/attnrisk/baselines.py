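"""Static baseline models on the windowed feature matrix.

* :class:`LassoLogistic` — L1-regularized logistic regression with the
  regularization strength chosen by cross-validated log loss over a
  geometric path, then refit on the full training rows.  The L1 fit also
  drives feature reduction: the k features with the largest absolute
  coefficients define the reduced feature sets.
* :class:`GradientBoostedTrees` — an XGBoost classifier with exhaustive
  grid search over a small hyperparameter grid, selected by
  cross-validated log loss.

Both follow the scikit-learn estimator contract (``fit`` /
``predict_proba`` / ``get_params``), so they compose with pipelines and
model selection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import ParameterGrid, StratifiedKFold

from .features import FeatureMatrix

__all__ = ["LassoLogistic", "GradientBoostedTrees", "fit_lasso", "fit_gbt",
           "select_top_features", "report_coefficients"]


def _as_matrix(X):
    return X.X if isinstance(X, FeatureMatrix) else X


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    return y


class LassoLogistic(ClassifierMixin, BaseEstimator):
    """L1 logistic regression with a cross-validated regularization path.

    Parameters
    ----------
    n_candidates : points on the geometric C path (inverse strength).
    c_min, c_max : path endpoints.
    n_folds : stratified CV folds for path selection.
    random_state : fold shuffling / solver seed.

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : final refit on all training rows.
    C_ : selected inverse regularization strength.
    path_ : DataFrame of (C, mean CV log loss, nonzero count).
    """

    def __init__(self, n_candidates: int = 20, c_min: float = 1e-4,
                 c_max: float = 1e2, n_folds: int = 3, tol: float = 1e-4,
                 max_iter: int = 2000, random_state: int = 0):
        self.n_candidates = n_candidates
        self.c_min = c_min
        self.c_max = c_max
        self.n_folds = n_folds
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _solver(self, C, warm_start=False, tol=None):
        # saga handles sparse input and leaves the intercept unpenalized
        return LogisticRegression(l1_ratio=1.0, solver="saga", C=C,
                                  tol=self.tol if tol is None else tol,
                                  max_iter=self.max_iter, warm_start=warm_start,
                                  random_state=self.random_state)

    def fit(self, X, y):
        X = _as_matrix(X)
        y = _check_binary(y)
        # walk the path from strong to weak regularization, warm-starting
        Cs = np.geomspace(self.c_min, self.c_max, self.n_candidates)
        skf = StratifiedKFold(self.n_folds, shuffle=True, random_state=self.random_state)
        folds = list(skf.split(np.zeros(len(y)), y))
        losses = np.zeros((len(Cs), len(folds)))
        nnz = np.zeros((len(Cs), len(folds)), dtype=int)
        for f, (tr, te) in enumerate(folds):
            est = self._solver(Cs[0], warm_start=True, tol=max(self.tol, 1e-3))
            for ci, C in enumerate(Cs):
                est.C = C
                est.fit(X[tr], y[tr])
                p = est.predict_proba(X[te])[:, 1]
                losses[ci, f] = log_loss(y[te], p, labels=[0, 1])
                nnz[ci, f] = int(np.count_nonzero(est.coef_))
        self.path_ = pd.DataFrame({"C": Cs, "cv_log_loss": losses.mean(axis=1),
                                   "nonzero": nnz.mean(axis=1).round().astype(int)})
        best = int(self.path_["cv_log_loss"].idxmin())
        self.C_ = float(self.path_.loc[best, "C"])
        final = self._solver(Cs[0], warm_start=True)
        for C in Cs[:best + 1]:  # warm-start up the path to the selected C
            final.C = C
            final.fit(X, y)
        self.coef_ = final.coef_.ravel()
        # polish the unpenalized intercept to its exact profile MLE, so the
        # mean fitted risk matches the training event rate
        self.intercept_ = self._intercept_mle(np.asarray(X @ self.coef_).ravel(), y,
                                              float(final.intercept_[0]))
        self.classes_ = np.array([0, 1])
        return self

    @staticmethod
    def _intercept_mle(z: np.ndarray, y: np.ndarray, b0: float) -> float:
        b = b0
        for _ in range(100):
            p = 1.0 / (1.0 + np.exp(-(z + b)))
            grad = float(np.sum(y - p))
            hess = float(np.sum(p * (1.0 - p)))
            if hess <= 0:
                break
            step = grad / hess
            b += step
            if abs(step) < 1e-12:
                break
        return float(b)

    def decision_function(self, X):
        X = _as_matrix(X)
        return np.asarray(X @ self.coef_).ravel() + self.intercept_

    def predict_proba(self, X):
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.stack([1.0 - p, p], axis=1)

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


DEFAULT_GBT_GRID = {
    "max_depth": [3, 6],
    "n_estimators": [100, 300],
    "learning_rate": [0.1, 0.3],
}


class GradientBoostedTrees(ClassifierMixin, BaseEstimator):
    """XGBoost classifier with exhaustive grid search by CV log loss."""

    def __init__(self, search_grid: dict | None = None, n_folds: int = 3,
                 random_state: int = 0, n_jobs: int = 1):
        self.search_grid = search_grid
        self.n_folds = n_folds
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y):
        from xgboost import XGBClassifier

        X = _as_matrix(X)
        y = _check_binary(y)
        grid = self.search_grid if self.search_grid is not None else DEFAULT_GBT_GRID
        points = list(ParameterGrid(grid))
        if not points:
            raise ValueError("empty hyperparameter grid")
        skf = StratifiedKFold(self.n_folds, shuffle=True, random_state=self.random_state)
        folds = list(skf.split(np.zeros(len(y)), y))
        results = []
        for params in points:
            losses = []
            for tr, te in folds:
                est = XGBClassifier(random_state=self.random_state,
                                    n_jobs=self.n_jobs, eval_metric="logloss",
                                    **params)
                est.fit(X[tr], y[tr])
                p = est.predict_proba(X[te])[:, 1]
                losses.append(log_loss(y[te], p, labels=[0, 1]))
            results.append({"params": params, "cv_log_loss": float(np.mean(losses))})
        self.cv_results_ = results
        best = min(results, key=lambda r: r["cv_log_loss"])
        self.best_params_ = best["params"]
        self.model_ = XGBClassifier(random_state=self.random_state,
                                    n_jobs=self.n_jobs, eval_metric="logloss",
                                    **self.best_params_).fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(_as_matrix(X))

    def predict(self, X):
        return self.model_.predict(_as_matrix(X))


# -- module-level wrappers (the functional surface) ------------------------

def fit_lasso(fm_train, labels, n_folds: int = 3, seed: int = 0,
              **kwargs) -> LassoLogistic:
    return LassoLogistic(n_folds=n_folds, random_state=seed, **kwargs).fit(fm_train, labels)


def fit_gbt(fm_train, labels, search_grid: dict | None = None,
            n_folds: int = 3, seed: int = 0) -> GradientBoostedTrees:
    return GradientBoostedTrees(search_grid=search_grid, n_folds=n_folds,
                                random_state=seed).fit(fm_train, labels)


def _abs_order(coef: np.ndarray) -> list:
    """Indices by descending |coefficient|, ties broken by lower index."""
    return sorted(range(len(coef)), key=lambda i: (-abs(coef[i]), i))


def select_top_features(model: LassoLogistic, k: int, feature_map=None):
    """The k features with the largest absolute coefficients.

    If fewer than k coefficients are nonzero, all nonzero features are
    returned with a warning.  Returns sorted column indices, or
    ``(indices, FeatureMap subset)`` when a feature map is supplied.
    """
    coef = np.asarray(model.coef_).ravel()
    nnz = int(np.count_nonzero(coef))
    if k > nnz:
        warnings.warn(f"k={k} exceeds nonzero coefficient count {nnz}; "
                      "returning all nonzero features")
        k = nnz
    idx = sorted(_abs_order(coef)[:k])
    if feature_map is not None:
        return idx, feature_map.subset(idx)
    return idx


def report_coefficients(model: LassoLogistic, feature_map, top_n: int = 10) -> pd.DataFrame:
    """Top coefficients by absolute value, as a ranked table."""
    coef = np.asarray(model.coef_).ravel()
    order = _abs_order(coef)[:top_n]
    return pd.DataFrame({
        "feature": [feature_map[i] for i in order],
        "coefficient": [coef[i] for i in order],
    })
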