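"""Region-grouped data splitting, grid search and evaluation metrics.

Municipalities are the observation units but neighbouring municipalities
(same health region) have correlated features, so every split in this
module keeps each region whole: the train/validation/test partition and
the 5-fold cross-validation folds never let one region straddle two sets.
Model families span linear models (standardized inputs) and tree
ensembles (raw inputs); the grid-search winner is the point with the
highest mean out-of-fold ROC AUC, ties broken by grid order, refit on the
whole training set.

Learner internals come from scikit-learn; the splitting, cross-validation
orchestration, selection rule and the ROC/PR/confusion metrics are owned
and tested here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SplitAssignment",
    "ModelFamily",
    "GridPoint",
    "default_model_space",
    "grouped_split",
    "grouped_cv_folds",
    "run_grid_search",
    "QualityModelSearch",
    "roc_auc",
    "roc_curve_points",
    "pr_auc",
    "pr_curve_points",
    "confusion_at_threshold",
    "evaluate_classifier",
]

SET_NAMES = ("train", "validation", "test")


# ---------------------------------------------------------------------------
# Grouped splitting


@dataclass(frozen=True)
class SplitAssignment:
    """Exhaustive, exclusive municipality -> set assignment, region-whole."""

    assignment: Mapping[str, str]  # municipality_id -> train/validation/test
    fractions: tuple[float, float, float]
    group_map: Mapping[str, str]  # municipality_id -> region_id
    seed: int

    def members(self, set_name: str) -> list[str]:
        return [m for m, s in self.assignment.items() if s == set_name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "municipality_id": list(self.assignment),
                "region_id": [self.group_map[m] for m in self.assignment],
                "set": list(self.assignment.values()),
            }
        )


def _greedy_pack(
    region_sizes: Mapping[str, int], targets: Sequence[float], seed: int
) -> dict[str, int]:
    """Assign whole regions to bins, largest region first into the bin with
    the largest remaining deficit (ties: lowest bin index; equal-sized
    regions in seeded-shuffle order)."""
    rng = np.random.default_rng(seed)
    regions = list(region_sizes)
    rng.shuffle(regions)
    regions.sort(key=lambda r: -region_sizes[r])  # stable: ties keep shuffled order
    counts = np.zeros(len(targets))
    out: dict[str, int] = {}
    for r in regions:
        deficits = np.asarray(targets) - counts
        bin_idx = int(np.argmax(deficits))
        out[r] = bin_idx
        counts[bin_idx] += region_sizes[r]
    return out


def grouped_split(
    group_map: Mapping[str, str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Partition municipalities into train/validation/test, regions whole.

    Seeded randomized greedy packing toward the target municipality-count
    fractions; with >= 30 regions the achieved fractions land within about
    5 percentage points of the targets.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    regions = set(group_map.values())
    if len(regions) < 3:
        raise ValueError("need at least 3 distinct regions to form 3 sets")
    sizes: dict[str, int] = {}
    for region in group_map.values():
        sizes[region] = sizes.get(region, 0) + 1
    n = len(group_map)
    region_bin = _greedy_pack(sizes, [f * n for f in fractions], seed)
    assignment = {m: SET_NAMES[region_bin[r]] for m, r in group_map.items()}
    return SplitAssignment(assignment, tuple(fractions), dict(group_map), seed)


def grouped_cv_folds(
    group_map: Mapping[str, str], k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Fold label (0..k-1) per municipality; each region in exactly one fold."""
    sizes: dict[str, int] = {}
    for region in group_map.values():
        sizes[region] = sizes.get(region, 0) + 1
    if len(sizes) < k:
        raise ValueError(f"need at least {k} regions for {k} folds, got {len(sizes)}")
    region_fold = _greedy_pack(sizes, [len(group_map) / k] * k, seed)
    return {m: region_fold[r] for m, r in group_map.items()}


# ---------------------------------------------------------------------------
# Metrics (own implementations; the module's contract)


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != len(labels):
        raise ValueError("labels must be 0/1")
    return n_pos, n_neg


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve, rank (Mann-Whitney) formulation.

    Equals the probability that a random positive outranks a random
    negative, with half credit for ties.  Requires both classes present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = _check_binary(labels)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC undefined with a single class")
    ranks = rankdata(scores, method="average")
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve_points(labels: Sequence[int], scores: Sequence[float]) -> pd.DataFrame:
    """ROC curve by threshold sweep over the distinct scores (descending)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = _check_binary(labels)
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    last_of_tie = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[last_of_tie] / max(n_pos, 1)]
    fpr = np.r_[0.0, fp[last_of_tie] / max(n_neg, 1)]
    thr = np.r_[np.inf, sorted_scores[last_of_tie]]
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def pr_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Precision-recall AUC in the average-precision formulation:
    the step-wise integral of precision over recall increments."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos, _ = _check_binary(labels)
    if n_pos == 0:
        raise ValueError("PR AUC undefined without positives")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels == 1)
    n_seen = np.arange(1, len(labels) + 1)
    last_of_tie = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    precision = tp[last_of_tie] / n_seen[last_of_tie]
    recall = tp[last_of_tie] / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def pr_curve_points(labels: Sequence[int], scores: Sequence[float]) -> pd.DataFrame:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos, _ = _check_binary(labels)
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels == 1)
    n_seen = np.arange(1, len(labels) + 1)
    last_of_tie = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    return pd.DataFrame(
        {
            "threshold": sorted_scores[last_of_tie],
            "recall": tp[last_of_tie] / max(n_pos, 1),
            "precision": tp[last_of_tie] / n_seen[last_of_tie],
        }
    )


def confusion_at_threshold(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> dict[str, float]:
    """Class-conditional confusion rates; probability exactly at the
    threshold predicts positive."""
    labels = np.asarray(labels)
    probs = np.asarray(probabilities, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    _check_binary(labels)
    predicted = probs >= threshold
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return {
        "tp_rate": float((predicted & pos).sum() / n_pos) if n_pos else float("nan"),
        "fn_rate": float((~predicted & pos).sum() / n_pos) if n_pos else float("nan"),
        "tn_rate": float((~predicted & neg).sum() / n_neg) if n_neg else float("nan"),
        "fp_rate": float((predicted & neg).sum() / n_neg) if n_neg else float("nan"),
    }


def _probability_scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    raise TypeError("model exposes neither predict_proba nor decision_function")


def evaluate_classifier(
    model, X, labels: Sequence[int], threshold: float = 0.5, n_bins: int = 10
) -> dict:
    """Full evaluation report: ROC/PR curves and AUCs, confusion rates at
    the threshold, and a per-class predicted-probability histogram."""
    labels = np.asarray(labels)
    scores = _probability_scores(model, X)
    in_unit = bool((scores >= 0).all() and (scores <= 1).all())
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    histogram = None
    confusion = None
    if in_unit:
        histogram = {
            "bin_edges": edges.tolist(),
            "good_quality": np.histogram(scores[labels == 0], bins=edges)[0].tolist(),
            "poor_quality": np.histogram(scores[labels == 1], bins=edges)[0].tolist(),
        }
        confusion = confusion_at_threshold(labels, scores, threshold)
    return {
        "roc_auc": roc_auc(labels, scores),
        "roc_curve": roc_curve_points(labels, scores).to_dict(orient="list"),
        "pr_auc": pr_auc(labels, scores),
        "pr_curve": pr_curve_points(labels, scores).to_dict(orient="list"),
        "confusion": confusion,
        "probability_histogram": histogram,
        "n": int(len(labels)),
    }


# ---------------------------------------------------------------------------
# Model space and grid search


@dataclass(frozen=True)
class ModelFamily:
    name: str
    factory: Callable[[int], BaseEstimator]  # seed -> fresh estimator
    grid: Mapping[str, Sequence]
    standardize: bool


@dataclass(frozen=True)
class GridPoint:
    family: str
    params: Mapping[str, object]
    standardize: bool


def default_model_space() -> list[ModelFamily]:
    """Linear models and SVM with standardization; trees on raw inputs.

    Small documented grids per family; the random-forest grid includes the
    1,000-tree / depth-10 configuration.
    """
    return [
        ModelFamily(
            "logistic_regression",
            lambda seed: LogisticRegression(max_iter=5000),
            {"C": [0.01, 0.1, 1.0, 10.0]},
            standardize=True,
        ),
        ModelFamily(
            "sgd_linear",
            lambda seed: SGDClassifier(loss="log_loss", random_state=seed),
            {"alpha": [1e-4, 1e-3, 1e-2]},
            standardize=True,
        ),
        ModelFamily(
            "svm",
            lambda seed: SVC(probability=True, random_state=seed),
            {"C": [0.1, 1.0, 10.0]},
            standardize=True,
        ),
        ModelFamily(
            "decision_tree",
            lambda seed: DecisionTreeClassifier(random_state=seed),
            {"max_depth": [5, 10, None]},
            standardize=False,
        ),
        ModelFamily(
            "random_forest",
            lambda seed: RandomForestClassifier(random_state=seed),
            {"n_estimators": [300, 1000], "max_depth": [10, None]},
            standardize=False,
        ),
        ModelFamily(
            "gradient_boosting",
            lambda seed: GradientBoostingClassifier(random_state=seed),
            {"n_estimators": [100, 300], "max_depth": [3]},
            standardize=False,
        ),
    ]


def _expand(space: Sequence[ModelFamily]) -> list[tuple[ModelFamily, GridPoint]]:
    points = []
    for family in space:
        keys = list(family.grid)
        for combo in itertools.product(*(family.grid[k] for k in keys)):
            points.append(
                (family, GridPoint(family.name, dict(zip(keys, combo)), family.standardize))
            )
    return points


def _build_pipeline(family: ModelFamily, point: GridPoint, seed: int) -> Pipeline:
    est = clone(family.factory(seed))
    est.set_params(**point.params)
    steps = [("scale", StandardScaler())] if point.standardize else []
    steps.append(("model", est))
    return Pipeline(steps)


def run_grid_search(
    X: pd.DataFrame,
    y: Sequence[int],
    groups: Sequence[str],
    model_space: Sequence[ModelFamily] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[Pipeline, GridPoint, pd.DataFrame]:
    """Grouped-CV grid search selecting by mean out-of-fold ROC AUC.

    Returns (refit best pipeline, winning grid point, CV score table).
    Standardization, when a family uses it, lives inside the pipeline, so
    its statistics are estimated only on each fold's fitting portion and
    on the training set for the final refit.  Ties go to the earlier grid
    point.  A fold whose fitting portion is single-class is skipped with a
    warning; a grid point with no usable fold is scored NaN.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    groups = np.asarray(groups)
    if len(X) != len(y) or len(y) != len(groups):
        raise ValueError("X, y and groups must be aligned")
    space = list(model_space) if model_space is not None else default_model_space()
    fold_of = grouped_cv_folds(
        {str(i): g for i, g in enumerate(groups)}, k=k, seed=seed
    )
    folds = np.array([fold_of[str(i)] for i in range(len(groups))])

    rows = []
    candidates = _expand(space)
    for family, point in candidates:
        fold_scores = []
        for fold in range(k):
            held = folds == fold
            fit_y = y[~held]
            if len(np.unique(fit_y)) < 2 or len(np.unique(y[held])) < 2:
                warnings.warn(
                    f"skipping fold {fold} for {point.family}: single-class data",
                    stacklevel=2,
                )
                continue
            pipe = _build_pipeline(family, point, seed)
            pipe.fit(X[~held], fit_y)
            fold_scores.append(roc_auc(y[held], _probability_scores(pipe, X[held])))
        rows.append(
            {
                "family": point.family,
                "params": dict(point.params),
                "standardize": point.standardize,
                "mean_cv_roc_auc": float(np.mean(fold_scores)) if fold_scores else float("nan"),
                "n_folds_used": len(fold_scores),
            }
        )
    cv_table = pd.DataFrame(rows)
    if cv_table["mean_cv_roc_auc"].isna().all():
        raise ValueError("every grid point lost all folds; cannot select a model")
    best_idx = int(np.nanargmax(cv_table["mean_cv_roc_auc"].to_numpy()))
    best_family, best_point = candidates[best_idx]
    best_pipe = _build_pipeline(best_family, best_point, seed)
    best_pipe.fit(X, y)
    return best_pipe, best_point, cv_table


class QualityModelSearch(BaseEstimator, ClassifierMixin):
    """Grid-search classifier for municipal death-certification quality.

    A scikit-learn-style estimator: ``fit(X, y, groups=...)`` runs the
    region-grouped 5-fold grid search over the model space, refits the
    winner on the whole training input, and exposes it for prediction.

    Parameters
    ----------
    model_space : sequence of ModelFamily, optional
        Families and grids to search; the default space when omitted.
    k : int, default 5
        Number of grouped cross-validation folds.
    seed : int, default 0
        Seed for fold packing and stochastic learners.

    Attributes
    ----------
    best_estimator_ : sklearn Pipeline, the refit winner.
    best_point_ : GridPoint of the winner.
    best_score_ : winner's mean out-of-fold ROC AUC.
    cv_results_ : DataFrame with one row per grid point.
    classes_ : array of class labels.
    """

    def __init__(self, model_space=None, k: int = 5, seed: int = 0):
        self.model_space = model_space
        self.k = k
        self.seed = seed

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (region ids) are required to avoid spatial leakage")
        best, point, table = run_grid_search(
            X, y, groups, model_space=self.model_space, k=self.k, seed=self.seed
        )
        self.best_estimator_ = best
        self.best_point_ = point
        self.cv_results_ = table
        self.best_score_ = float(
            table["mean_cv_roc_auc"].iloc[int(np.nanargmax(table["mean_cv_roc_auc"].to_numpy()))]
        )
        self.classes_ = np.unique(np.asarray(y))
        return self

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict_proba(X)
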