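"""Classifier training, stratified cross-validation and grid search.

The primary classifier is a gradient-boosted tree ensemble (XGBoost); random
forests and an RBF-kernel SVM serve as baselines.  Hyperparameters are tuned
by exhaustive grid search under stratified k-fold cross-validation with mean
AUROC as the selection metric.  Folds are stratified rather than plain
random so that both classes are guaranteed in every fold even for small
balanced sets (a few hundred rows per class).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

ALGORITHMS = ("xgboost", "rf", "svm")

#: full published tuning grid for the boosted model:
#: 8 depths x 5 learning rates x 7 tree counts = 280 combinations.
XGB_FULL_GRID = {
    "max_depth": [2, 4, 6, 8, 10, 12, 14, 16],
    "learning_rate": [0.005, 0.01, 0.02, 0.05, 0.1],
    "n_estimators": [1600, 1800, 2000, 2200, 2400, 2600, 2800],
}

#: baseline grids (documented defaults; ranges not prescribed upstream).
RF_DEFAULT_GRID = {"n_estimators": [200, 500, 1000], "max_depth": [None, 8, 16]}
SVM_DEFAULT_GRID = {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.001]}

DEFAULT_GRIDS = {
    "xgboost": XGB_FULL_GRID,
    "rf": RF_DEFAULT_GRID,
    "svm": SVM_DEFAULT_GRID,
}


@dataclasses.dataclass
class CvConfig:
    """Stratified k-fold cross-validation settings."""

    k: int = 5
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclasses.dataclass
class ModelSpec:
    """An algorithm plus its hyperparameter grid and fixed parameters."""

    algorithm: str
    grid: dict[str, list] = dataclasses.field(default_factory=dict)
    fixed_params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def combinations(self) -> list[dict]:
        """All grid combinations in grid order (first key varies slowest)."""
        if not self.grid:
            return [dict(self.fixed_params)]
        keys = list(self.grid)
        out = []
        for values in itertools.product(*(self.grid[k] for k in keys)):
            params = dict(self.fixed_params)
            params.update(zip(keys, values))
            out.append(params)
        return out


def make_estimator(algorithm: str, params: dict, seed: int = 0):
    """Build an unfitted estimator for one of the three algorithms."""
    if algorithm == "xgboost":
        return xgb.XGBClassifier(
            n_jobs=1,
            tree_method="hist",
            random_state=seed,
            eval_metric="logloss",
            **params,
        )
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "svm":
        # probability scores via internal (sigmoid) calibration on CV folds
        svc = SVC(kernel="rbf", random_state=seed, **params)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", CalibratedClassifierCV(svc, ensemble=False)),
            ]
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def make_folds(y: Sequence[int], cv: CvConfig) -> np.ndarray:
    """Deterministic stratified fold assignment, one fold id per sample.

    Fold sizes differ by at most one per class (hence by at most the number
    of classes overall); the same seed always yields the same assignment.
    """
    yarr = np.asarray(y)
    if cv.k > len(yarr):
        raise ValueError(f"k={cv.k} exceeds sample count {len(yarr)}")
    splitter = StratifiedKFold(
        n_splits=cv.k,
        shuffle=cv.shuffle,
        random_state=cv.seed if cv.shuffle else None,
    )
    folds = np.empty(len(yarr), dtype=int)
    for fold_id, (_, val_idx) in enumerate(splitter.split(np.zeros(len(yarr)), yarr)):
        folds[val_idx] = fold_id
    return folds


def cross_val_auroc(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str,
    params: dict,
    cv: CvConfig,
) -> float:
    """Mean validation AUROC over stratified folds."""
    X = np.asarray(X)
    y = np.asarray(y)
    folds = make_folds(y, cv)
    aurocs = []
    for fold_id in range(cv.k):
        val = folds == fold_id
        est = make_estimator(algorithm, params, seed=cv.seed)
        est.fit(X[~val], y[~val])
        scores = est.predict_proba(X[val])[:, 1]
        aurocs.append(roc_auc_score(y[val], scores))
    return float(np.mean(aurocs))


@dataclasses.dataclass
class GridSearchResult:
    best_params: dict
    best_auroc: float
    results: list[tuple[dict, float]]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "best_params": self.best_params,
                    "best_auroc": self.best_auroc,
                    "results": [[p, a] for p, a in self.results],
                },
                fh,
                indent=1,
            )
        return path


def grid_search_cv(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    spec: ModelSpec,
    cv: CvConfig | None = None,
) -> GridSearchResult:
    """Exhaustive grid evaluation by mean CV AUROC; ties keep grid order."""
    cv = cv or CvConfig()
    X = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    yarr = np.asarray(y)
    combos = spec.combinations()
    if not combos:
        raise ValueError("empty grid")
    results = []
    for params in combos:
        auroc = cross_val_auroc(X, yarr, spec.algorithm, params, cv)
        results.append((params, auroc))
    best_idx = int(np.argmax([a for _, a in results]))
    return GridSearchResult(
        best_params=results[best_idx][0],
        best_auroc=results[best_idx][1],
        results=results,
    )


@dataclasses.dataclass
class TrainedModel:
    """A fitted classifier plus its feature-column contract and threshold."""

    algorithm: str
    estimator: object
    feature_names: list[str]
    threshold: float = 0.5
    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    metadata: dict = dataclasses.field(default_factory=dict)

    def _check_columns(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(
                f"input is missing {len(missing)} contract columns "
                f"(first: {missing[:3]})"
            )
        return X[self.feature_names]

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, directory / "estimator.joblib")
        meta = {
            "algorithm": self.algorithm,
            "feature_names": self.feature_names,
            "threshold": self.threshold,
            "params": self.params,
            "seed": self.seed,
            "metadata": self.metadata,
        }
        with open(directory / "model.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        with open(directory / "model.json") as fh:
            meta = json.load(fh)
        estimator = joblib.load(directory / "estimator.joblib")
        return cls(
            algorithm=meta["algorithm"],
            estimator=estimator,
            feature_names=meta["feature_names"],
            threshold=meta["threshold"],
            params=meta["params"],
            seed=meta["seed"],
            metadata=meta.get("metadata", {}),
        )


def train_final(
    X: pd.DataFrame,
    y: Sequence[int],
    algorithm: str = "xgboost",
    params: dict | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> TrainedModel:
    """Fit on all rows and freeze the feature-column contract."""
    from m5cboost.encoders import FeatureMatrix

    if isinstance(X, FeatureMatrix):
        X = X.data
    params = params or {}
    est = make_estimator(algorithm, params, seed)
    est.fit(X.to_numpy(), np.asarray(y))
    return TrainedModel(
        algorithm=algorithm,
        estimator=est,
        feature_names=list(X.columns),
        threshold=threshold,
        params=params,
        seed=seed,
    )


def predict_scores(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Class-1 (methylated) probabilities, order-preserving with input rows.

    Refuses inputs missing any contract column; extra columns are ignored
    and columns are re-ordered to the contract.
    """
    from m5cboost.encoders import FeatureMatrix

    if isinstance(X, FeatureMatrix):
        X = X.data
    sub = model._check_columns(X)
    return model.estimator.predict_proba(sub.to_numpy())[:, 1]
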