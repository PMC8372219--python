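"""Hyperparameter tuning by repeated k-fold cross-validation.

Six model families are supported: ridge-penalised logistic and linear
regression (``glmnet_logistic`` / ``glmnet_linear``), RBF-kernel support
vector machines, decision trees, random forests, and gradient-boosted trees
(XGBoost).  Each family ships a small default grid; every grid is
overridable and is serialized into results files for provenance.

Tuning draws ``cv_times`` independent stratified k-fold partitions of the
training set (one sub-seed per repetition), scores every grid combination on
every held-out fold with the chosen metric, and refits the best combination
on the whole training set.  Ties in mean metric break toward the earlier
combination in enumeration order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from xgboost import XGBClassifier, XGBRegressor

from ._seeds import derive_seed
from .core_data import DataError, Dataset, SUPPORTED_MODELS
from .evaluate import GREATER_IS_BETTER, compute_metric


@dataclass
class HyperparameterGrid:
    """A Cartesian grid of candidate hyperparameter values."""

    model_type: str
    params: Dict[str, List]

    def __post_init__(self) -> None:
        if not self.params or any(len(v) == 0 for v in self.params.values()):
            raise DataError("every grid parameter needs a non-empty value list")

    def combinations(self) -> List[dict]:
        names = list(self.params)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.params[n] for n in names))
        ]


@dataclass
class ModelHandle:
    """Opaque fitted predictor exposing the two downstream contracts.

    ``predict`` returns point predictions (original class labels for
    classification, floats for regression); ``score_matrix`` returns a
    probability-like score per class (classification only), with columns in
    ``classes`` order.  All evaluation and importance code uses only these.
    """

    estimator: object
    feature_names: List[str]
    outcome_kind: str
    classes: Optional[List[str]] = None
    positive_class: Optional[str] = None

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.feature_names].to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        raw = self.estimator.predict(self._matrix(X))
        if self.outcome_kind == "continuous":
            return np.asarray(raw, dtype=float)
        codes = np.asarray(raw, dtype=int)
        return np.array([self.classes[c] for c in codes], dtype=object)

    def score_matrix(self, X: pd.DataFrame) -> np.ndarray:
        if self.outcome_kind == "continuous":
            raise DataError("class scores are undefined for continuous outcomes")
        return np.asarray(self.estimator.predict_proba(self._matrix(X)), dtype=float)

    def positive_score(self, X: pd.DataFrame) -> np.ndarray:
        k = self.classes.index(self.positive_class)
        return self.score_matrix(X)[:, k]


@dataclass
class TrainResult:
    """Best hyperparameters, the per-combination CV table, and the refitted model."""

    best_params: dict
    cv_table: pd.DataFrame
    model_handle: ModelHandle
    seed: int
    metric: str
    grid: HyperparameterGrid = field(repr=False, default=None)

    @property
    def best_mean(self) -> float:
        mask = np.ones(len(self.cv_table), dtype=bool)
        for k, v in self.best_params.items():
            mask &= self.cv_table[k] == v
        return float(self.cv_table.loc[mask, "mean_perf"].iloc[0])


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise squared distance."""
    if X.shape[0] > 200:
        X = X[:200]
    d2 = pdist(X, metric="sqeuclidean")
    med = float(np.median(d2[d2 > 0])) if np.any(d2 > 0) else 1.0
    return 1.0 / med


def default_grid(model_type: str, n_features: int, data: Optional[pd.DataFrame] = None) -> HyperparameterGrid:
    """Default hyperparameter grid for a model family.

    The SVM kernel width uses the median heuristic (+/- one decade) when
    training data is supplied, falling back to 1/n_features otherwise.
    Random-forest candidate features-per-split are
    {floor(sqrt(p)/2), floor(sqrt(p)), 2*floor(sqrt(p))}, deduplicated and
    floored at 1.
    """
    if model_type not in SUPPORTED_MODELS:
        raise DataError(
            f"unknown model_type {model_type!r}; supported: {list(SUPPORTED_MODELS)}"
        )
    if model_type in ("glmnet_logistic", "glmnet_linear"):
        return HyperparameterGrid(
            model_type, {"alpha": [0.0], "lambda": [1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0]}
        )
    if model_type == "svm_rbf":
        if data is not None:
            g0 = _median_heuristic_gamma(np.asarray(data, dtype=float))
        else:
            g0 = 1.0 / max(n_features, 1)
        return HyperparameterGrid(
            model_type,
            {"C": [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2], "gamma": [g0 / 10, g0, g0 * 10]},
        )
    if model_type == "decision_tree":
        return HyperparameterGrid(model_type, {"max_depth": [1, 2, 4, 8, 16, 32]})
    if model_type == "random_forest":
        r = int(np.sqrt(n_features))
        mtry = sorted({max(1, r // 2), max(1, r), max(1, 2 * r)})
        return HyperparameterGrid(model_type, {"mtry": mtry})
    # xgboost
    return HyperparameterGrid(
        model_type,
        {"eta": [0.01, 0.1, 0.3], "max_depth": [2, 4, 6], "nrounds": [100]},
    )


def make_estimator(model_type: str, params: dict, outcome_kind: str, seed: int):
    """Instantiate the scikit-learn/XGBoost estimator behind a model type."""
    classify = outcome_kind != "continuous"
    if model_type == "glmnet_logistic":
        if not classify:
            raise DataError("glmnet_logistic requires a categorical outcome; use glmnet_linear")
        lam = float(params.get("lambda", 1.0))
        # default penalty is L2; C = 1/lambda emulates ridge-penalised glmnet
        return LogisticRegression(C=1.0 / max(lam, 1e-12), solver="lbfgs", max_iter=2000)
    if model_type == "glmnet_linear":
        if classify:
            raise DataError("glmnet_linear requires a continuous outcome; use glmnet_logistic")
        return Ridge(alpha=float(params.get("lambda", 1.0)))
    if model_type == "svm_rbf":
        C = float(params.get("C", 1.0))
        gamma = params.get("gamma", "scale")
        if classify:
            return SVC(C=C, gamma=gamma, probability=True, random_state=seed)
        return SVR(C=C, gamma=gamma)
    if model_type == "decision_tree":
        depth = params.get("max_depth")
        cls = DecisionTreeClassifier if classify else DecisionTreeRegressor
        return cls(max_depth=depth, random_state=seed)
    if model_type == "random_forest":
        mtry = params.get("mtry")
        cls = RandomForestClassifier if classify else RandomForestRegressor
        return cls(n_estimators=500, max_features=mtry, random_state=seed, n_jobs=1)
    if model_type == "xgboost":
        kw = dict(
            n_estimators=int(params.get("nrounds", 100)),
            learning_rate=float(params.get("eta", 0.3)),
            max_depth=int(params.get("max_depth", 6)),
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        return XGBClassifier(**kw) if classify else XGBRegressor(**kw)
    raise DataError(
        f"unknown model_type {model_type!r}; supported: {list(SUPPORTED_MODELS)}"
    )


def _fit_handle(model_type, params, X, y_codes, classes, outcome_kind, positive, seed):
    est = make_estimator(model_type, params, outcome_kind, seed)
    est.fit(np.asarray(X, dtype=float), y_codes)
    return ModelHandle(
        estimator=est,
        feature_names=list(X.columns),
        outcome_kind=outcome_kind,
        classes=classes,
        positive_class=positive,
    )


def _draw_folds(y_codes, outcome_kind, kfold, rep_seed, classes):
    """One repetition's k folds; redrawn (up to 10 times) if any training
    side of a fold loses an outcome class."""
    n = len(y_codes)
    for attempt in range(10):
        rs = (rep_seed + attempt) % (2**31)
        if outcome_kind == "continuous":
            splitter = KFold(n_splits=kfold, shuffle=True, random_state=rs)
            folds = list(splitter.split(np.zeros(n)))
        else:
            splitter = StratifiedKFold(n_splits=kfold, shuffle=True, random_state=rs)
            folds = list(splitter.split(np.zeros(n), y_codes))
        if outcome_kind == "continuous" or all(
            len(np.unique(y_codes[tr])) == len(classes) for tr, _ in folds
        ):
            return folds
    warnings.warn("could not draw folds with all classes in every training side")
    return folds


def tune_and_train(
    train: Dataset,
    model_type: str,
    grid: Optional[HyperparameterGrid] = None,
    kfold: int = 5,
    cv_times: int = 10,
    metric: str = "auroc",
    seed: int = 1,
) -> TrainResult:
    """Grid-search hyperparameters by repeated k-fold CV, refit the best.

    Returns a :class:`TrainResult` whose ``cv_table`` has one row per grid
    combination with the mean and sd of the tuning metric over
    ``kfold * cv_times`` resamples.
    """
    if metric not in GREATER_IS_BETTER:
        raise DataError(f"unknown metric {metric!r}; known: {sorted(GREATER_IS_BETTER)}")
    outcome_kind = train.outcome_kind
    if outcome_kind == "continuous" and metric not in ("rmse", "mae", "r2"):
        raise DataError(f"metric {metric!r} is undefined for continuous outcomes")
    if outcome_kind != "continuous" and metric in ("rmse", "mae", "r2"):
        raise DataError(f"metric {metric!r} is undefined for classification outcomes")

    X = train.features
    if grid is None:
        grid = default_grid(model_type, X.shape[1], data=X)
    combos = grid.combinations()

    if outcome_kind == "continuous":
        y_codes = train.outcome.to_numpy(dtype=float)
        classes = None
        positive = None
    else:
        y_str = np.array([str(v) for v in train.outcome.to_numpy()], dtype=object)
        classes = sorted(set(y_str.tolist()))
        y_codes = np.searchsorted(classes, y_str)
        positive = classes[1] if len(classes) == 2 else None
        counts = np.bincount(y_codes)
        if kfold > counts.min():
            raise DataError(
                f"kfold={kfold} exceeds the smallest training-class count ({counts.min()})"
            )

    scores = np.empty((len(combos), kfold * cv_times), dtype=float)
    col = 0
    for rep in range(cv_times):
        rep_seed = derive_seed(seed, "cv", rep)
        folds = _draw_folds(y_codes, outcome_kind, kfold, rep_seed, classes)
        for fold_i, (tr_idx, te_idx) in enumerate(folds):
            Xtr, Xte = X.iloc[tr_idx], X.iloc[te_idx]
            ytr = y_codes[tr_idx]
            yte_labels = (
                y_codes[te_idx]
                if outcome_kind == "continuous"
                else np.array([classes[c] for c in y_codes[te_idx]], dtype=object)
            )
            for ci, params in enumerate(combos):
                handle = _fit_handle(
                    model_type, params, Xtr, ytr, classes, outcome_kind, positive,
                    derive_seed(seed, "fit", rep, fold_i, ci),
                )
                scores[ci, col] = compute_metric(metric, handle, Xte, yte_labels, outcome_kind)
            col += 1

    means = scores.mean(axis=1)
    sds = scores.std(axis=1, ddof=1) if scores.shape[1] > 1 else np.zeros(len(combos))
    maximize = GREATER_IS_BETTER[metric]
    best_i = 0
    for i in range(1, len(combos)):
        if (means[i] > means[best_i]) if maximize else (means[i] < means[best_i]):
            best_i = i

    cv_table = pd.DataFrame(combos)
    cv_table["mean_perf"] = means
    cv_table["sd_perf"] = sds
    cv_table["n_resamples"] = kfold * cv_times

    handle = _fit_handle(
        model_type, combos[best_i], X, y_codes, classes, outcome_kind, positive,
        derive_seed(seed, "refit"),
    )
    return TrainResult(
        best_params=combos[best_i],
        cv_table=cv_table,
        model_handle=handle,
        seed=seed,
        metric=metric,
        grid=grid,
    )
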