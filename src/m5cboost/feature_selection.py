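"""Feature ranking (TreeSHAP, F-score, mRMR) and incremental selection.

Three rankers order the feature columns best-first:

* ``rank_by_shap`` fits a gradient-boosted tree ensemble and scores each
  feature by the mean absolute Shapley attribution over the training rows,
  computed exactly by the tree-path-dependent TreeSHAP algorithm.
* ``rank_by_fscore`` scores each feature by the ratio of between-class mean
  separation to the summed within-class sample variances.
* ``rank_by_mrmr`` greedily selects features maximizing mutual information
  with the label minus mean mutual information with already-selected
  features (discretized by equal-frequency binning).

``incremental_selection`` then sweeps top-n prefixes of a ranking and picks
the n with the best mean cross-validated AUROC.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from m5cboost.encoders import FeatureMatrix
from m5cboost.modeling import CvConfig, cross_val_auroc

#: ensemble used to produce the SHAP ranking; fixed and independent of the
#: later per-dataset hyperparameter search, since ranking precedes tuning.
SHAP_RANKING_PARAMS = {"max_depth": 6, "learning_rate": 0.1, "n_estimators": 500}

#: classifier used to score top-n prefixes during incremental selection.
IFS_MODEL_PARAMS = {"max_depth": 4, "learning_rate": 0.1, "n_estimators": 200}


def _as_frame(X: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    return X.data if isinstance(X, FeatureMatrix) else X


@dataclasses.dataclass
class FeatureRanking:
    """Feature names ordered best-first with the scores that produced them."""

    method: str
    ordered_names: list[str]
    scores: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    def top(self, n: int) -> list[str]:
        return self.ordered_names[:n]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("name\tscore\n")
            for name, score in zip(self.ordered_names, self.scores):
                fh.write(f"{name}\t{float(score)!r}\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, method: str = "unknown") -> "FeatureRanking":
        table = pd.read_csv(path, sep="\t")
        return cls(method, list(table["name"]), table["score"].to_numpy())


def _stable_descending(scores: np.ndarray) -> np.ndarray:
    """Indices sorting scores descending, ties broken by original position."""
    return np.argsort(-scores, kind="stable")


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")


def fit_shap_ranking_model(
    X: FeatureMatrix | pd.DataFrame,
    y: Sequence[int],
    model_params: dict | None = None,
    seed: int = 0,
) -> xgb.XGBClassifier:
    frame = _as_frame(X)
    params = dict(SHAP_RANKING_PARAMS, **(model_params or {}))
    model = xgb.XGBClassifier(
        n_jobs=1,
        tree_method="hist",
        random_state=seed,
        eval_metric="logloss",
        **params,
    )
    model.fit(frame.to_numpy(), np.asarray(y))
    return model


def tree_shap_contributions(
    model: xgb.XGBClassifier, X: FeatureMatrix | pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-row Shapley attributions in margin (log-odds) space.

    Returns ``(contribs, bias)`` where ``contribs`` is (rows, features) and
    ``contribs.sum(1) + bias`` equals the model's raw margin prediction
    (the local-accuracy identity of Shapley values).
    """
    arr = X if isinstance(X, np.ndarray) else _as_frame(X).to_numpy()
    full = model.get_booster().predict(xgb.DMatrix(arr), pred_contribs=True)
    return full[:, :-1], full[:, -1]


def rank_by_shap(
    X: FeatureMatrix | pd.DataFrame,
    y: Sequence[int],
    model_params: dict | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Rank by mean |Shapley attribution| from one full-training-set fit."""
    frame = _as_frame(X)
    yarr = np.asarray(y)
    _check_two_classes(yarr)
    model = fit_shap_ranking_model(frame, yarr, model_params, seed)
    contribs, _ = tree_shap_contributions(model, frame)
    importance = np.abs(contribs).mean(axis=0)
    order = _stable_descending(importance)
    return FeatureRanking(
        method="shap",
        ordered_names=[frame.columns[i] for i in order],
        scores=importance[order],
        provenance={"model_params": dict(SHAP_RANKING_PARAMS, **(model_params or {})),
                    "seed": seed},
    )


def fscore(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column F-score: between-class separation over within-class variance.

    Numerator: squared deviations of the class means from the overall mean;
    denominator: sum of the two within-class sample variances (n-1).  A zero
    denominator with a positive numerator yields +inf (perfectly separating
    constant-within-class feature); 0/0 yields 0.
    """
    y = np.asarray(y)
    pos = X[y == 1]
    neg = X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least two samples per class")
    mean_all = X.mean(axis=0)
    num = (pos.mean(axis=0) - mean_all) ** 2 + (neg.mean(axis=0) - mean_all) ** 2
    denom = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / denom
    out[(denom == 0) & (num > 0)] = np.inf
    out[(denom == 0) & (num == 0)] = 0.0
    return out


def rank_by_fscore(
    X: FeatureMatrix | pd.DataFrame, y: Sequence[int]
) -> FeatureRanking:
    frame = _as_frame(X)
    yarr = np.asarray(y)
    _check_two_classes(yarr)
    scores = fscore(frame.to_numpy(), yarr)
    order = _stable_descending(scores)
    return FeatureRanking(
        method="fscore",
        ordered_names=[frame.columns[i] for i in order],
        scores=scores[order],
    )


def discretize_equal_frequency(col: np.ndarray, bins: int = 5) -> np.ndarray:
    """Equal-frequency bin codes; duplicate quantile edges are collapsed, so
    low-cardinality columns (e.g. 0/1 indicators) keep their natural levels."""
    if not np.all(np.isfinite(col)):
        raise ValueError("non-finite values cannot be discretized")
    edges = np.unique(np.quantile(col, np.arange(1, bins) / bins))
    return np.searchsorted(edges, col, side="left").astype(np.int64)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in nats between two integer-coded vectors, from the joint histogram."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / len(a)
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa * pb)[nz])).sum())


def rank_by_mrmr(
    X: FeatureMatrix | pd.DataFrame,
    y: Sequence[int],
    n_select: int = 50,
    bins: int = 5,
) -> FeatureRanking:
    """Greedy max-relevance min-redundancy selection.

    The first pick maximizes I(feature, label); each later pick maximizes
    I(f, label) - mean over selected s of I(f, s).  Mutual information is
    estimated in nats from the empirical joint histogram after
    equal-frequency discretization.  Scores record the criterion value at
    selection time; features beyond ``n_select`` are appended in the order
    of their final-step criterion so the result is a full permutation.
    """
    frame = _as_frame(X)
    yarr = np.asarray(y)
    _check_two_classes(yarr)
    p = frame.shape[1]
    n_select = min(n_select, p)
    cols = frame.to_numpy()
    disc = np.empty_like(cols, dtype=np.int64)
    for j in range(p):
        disc[:, j] = discretize_equal_frequency(cols[:, j], bins)

    ycodes = yarr.astype(np.int64)
    relevance = np.array(
        [mutual_information(ycodes, disc[:, j]) for j in range(p)]
    )
    selected: list[int] = []
    sel_scores: list[float] = []
    redundancy_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    criterion = relevance.copy()
    for _ in range(n_select):
        masked = np.where(remaining, criterion, -np.inf)
        best = int(np.argmax(masked))  # first index on ties
        selected.append(best)
        sel_scores.append(float(criterion[best]))
        remaining[best] = False
        if remaining.any() and len(selected) < n_select:
            rem_idx = np.flatnonzero(remaining)
            for j in rem_idx:
                redundancy_sum[j] += mutual_information(disc[:, best], disc[:, j])
            criterion = relevance - redundancy_sum / len(selected)

    rest = np.flatnonzero(remaining)
    rest = rest[_stable_descending(criterion[rest])]
    order = selected + list(rest)
    scores = np.array(sel_scores + [float(criterion[j]) for j in rest])
    return FeatureRanking(
        method="mrmr",
        ordered_names=[frame.columns[i] for i in order],
        scores=scores,
        provenance={"n_select": n_select, "bins": bins},
    )


@dataclasses.dataclass
class SelectionResult:
    """Top-n AUROC curve of an incremental selection sweep and its argmax."""

    curve: list[tuple[int, float]]
    best_n: int
    best_auroc: float
    selected_names: list[str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "curve": [[int(n), float(a)] for n, a in self.curve],
                    "best_n": self.best_n,
                    "best_auroc": self.best_auroc,
                    "selected_names": self.selected_names,
                },
                fh,
                indent=1,
            )
        return path


def default_n_grid(p: int) -> list[int]:
    """Step-4 sweep up to 300 features, then step 20 up to all of them."""
    grid = list(range(4, min(p, 300) + 1, 4)) + list(range(320, p + 1, 20))
    if p not in grid:
        grid.append(p)
    return grid


def incremental_selection(
    ranking: FeatureRanking,
    X: FeatureMatrix | pd.DataFrame,
    y: Sequence[int],
    n_grid: Sequence[int] | None = None,
    cv: CvConfig | None = None,
    model_params: dict | None = None,
    algorithm: str = "xgboost",
) -> SelectionResult:
    """Pick the top-n prefix of a ranking maximizing mean CV AUROC.

    Ties go to the smallest n.  The CV folds come from ``cv`` (same seed as
    the modeling grid search, so curves are comparable across stages).
    """
    frame = _as_frame(X)
    yarr = np.asarray(y)
    cv = cv or CvConfig()
    p = frame.shape[1]
    if n_grid is None:
        n_grid = default_n_grid(p)
    n_grid = list(n_grid)
    if not n_grid:
        raise ValueError("empty n_grid")
    if any(n < 1 or n > p for n in n_grid):
        raise ValueError(f"n_grid values must lie in [1, {p}]")
    params = dict(IFS_MODEL_PARAMS, **(model_params or {}))
    curve = []
    for n in sorted(set(n_grid)):
        sub = frame[ranking.top(n)]
        auroc = cross_val_auroc(sub.to_numpy(), yarr, algorithm, params, cv)
        curve.append((n, float(auroc)))
    aurocs = np.array([a for _, a in curve])
    best_idx = int(np.argmax(aurocs))  # first (smallest n) on exact ties
    best_n = curve[best_idx][0]
    return SelectionResult(
        curve=curve,
        best_n=best_n,
        best_auroc=float(aurocs[best_idx]),
        selected_names=ranking.top(best_n),
    )
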