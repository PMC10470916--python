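"""Grouped splitting, grid-search orchestration and metric implementations."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from vitalqc import (
    confusion_at_threshold,
    grouped_cv_folds,
    grouped_split,
    pr_auc,
    roc_auc,
    run_grid_search,
)
from vitalqc.model_selection import (
    ModelFamily,
    QualityModelSearch,
    pr_curve_points,
    roc_curve_points,
)

from conftest import compact_model_space


# -- grouped splitting -------------------------------------------------------


def _group_map(n_regions: int, per_region: int) -> dict[str, str]:
    return {
        f"M{r}_{i}": f"R{r}" for r in range(n_regions) for i in range(per_region)
    }


def test_split_is_partition_and_regions_never_straddle():
    gm = _group_map(10, 4)
    for seed in range(20):
        split = grouped_split(gm, seed=seed)
        assert set(split.assignment) == set(gm)
        frame = split.to_frame()
        assert (frame.groupby("region_id")["set"].nunique() == 1).all()


def test_split_fractions_near_targets_with_many_regions():
    rng = np.random.default_rng(0)
    gm = {}
    for r in range(100):
        for i in range(int(rng.integers(5, 36))):
            gm[f"M{r}_{i}"] = f"R{r}"
    for seed in range(20):
        split = grouped_split(gm, seed=seed)
        achieved = split.to_frame()["set"].value_counts(normalize=True)
        assert abs(achieved["train"] - 0.70) <= 0.05
        assert abs(achieved["validation"] - 0.15) <= 0.05
        assert abs(achieved["test"] - 0.15) <= 0.05


def test_split_needs_three_regions_and_unit_fractions():
    with pytest.raises(ValueError):
        grouped_split({"a": "R1", "b": "R2"})
    with pytest.raises(ValueError):
        grouped_split(_group_map(5, 2), fractions=(0.5, 0.2, 0.2))


def test_cv_folds_partition_regions():
    gm = _group_map(5, 3)
    folds = grouped_cv_folds(gm, k=5, seed=1)
    frame = pd.DataFrame(
        {"m": list(folds), "fold": list(folds.values()),
         "region": [gm[m] for m in folds]}
    )
    assert set(frame["fold"]) == set(range(5))
    assert (frame.groupby("region")["fold"].nunique() == 1).all()
    # 5 regions into 5 folds: exactly one region each
    assert frame.groupby("fold")["region"].nunique().eq(1).all()


def test_cv_fold_sizes_reasonably_balanced():
    rng = np.random.default_rng(1)
    gm = {}
    for r in range(50):
        for i in range(int(rng.integers(3, 20))):
            gm[f"M{r}_{i}"] = f"R{r}"
    for seed in range(20):
        folds = grouped_cv_folds(gm, k=5, seed=seed)
        sizes = pd.Series(list(folds.values())).value_counts()
        assert sizes.max() / sizes.min() <= 1.5


def test_more_folds_than_regions_rejected():
    with pytest.raises(ValueError):
        grouped_cv_folds(_group_map(3, 5), k=5)


# -- metrics -----------------------------------------------------------------


def test_roc_auc_perfect_and_tied():
    assert roc_auc([1, 0], [0.9, 0.1]) == 1.0
    assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
    assert roc_auc([1, 0], [0.5, 0.5]) == 0.5


def test_roc_auc_single_class_undefined():
    with pytest.raises(ValueError):
        roc_auc([1, 1], [0.2, 0.3])


def test_roc_auc_matches_pair_counting_oracle():
    """Rank formulation equals explicit O(n^2) enumeration of positive/
    negative pairs with half credit for ties."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = 30
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        wins = ties = 0
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        for p in pos:
            for q in neg:
                wins += p > q
                ties += p == q
        expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert roc_auc(labels, scores) == pytest.approx(expected, abs=1e-12)


def test_roc_auc_monotone_invariance_and_label_flip():
    rng = np.random.default_rng(6)
    labels = rng.integers(0, 2, size=50)
    labels[:2] = [0, 1]
    scores = rng.normal(size=50)  # continuous: ties have probability zero
    auc = roc_auc(labels, scores)
    assert roc_auc(labels, np.exp(scores)) == pytest.approx(auc, abs=1e-12)
    assert roc_auc(1 - labels, scores) == pytest.approx(1.0 - auc, abs=1e-12)


def test_curves_agree_with_sklearn():
    rng = np.random.default_rng(7)
    labels = rng.integers(0, 2, size=200)
    labels[:2] = [0, 1]
    scores = np.round(rng.random(200), 2)
    assert roc_auc(labels, scores) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12
    )
    assert pr_auc(labels, scores) == pytest.approx(
        average_precision_score(labels, scores), abs=1e-12
    )
    curve = roc_curve_points(labels, scores)
    assert curve["tpr"].iloc[0] == 0.0 and curve["tpr"].iloc[-1] == 1.0
    assert curve["fpr"].is_monotonic_increasing


def test_pr_auc_hand_computed_step_integral():
    """labels (1,0,1), scores (0.9,0.8,0.7): precision steps 1 at recall
    1/2 and 2/3 at recall 1, so the area is 1/2 + 1/3."""
    assert pr_auc([1, 0, 1], [0.9, 0.8, 0.7]) == pytest.approx(0.5 + 1.0 / 3.0)
    assert pr_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0


def test_pr_auc_random_scores_approach_prevalence():
    rng = np.random.default_rng(8)
    n = 20000
    labels = (rng.random(n) < 0.3).astype(int)
    scores = rng.random(n)
    assert pr_auc(labels, scores) == pytest.approx(0.3, abs=0.02)


def test_pr_auc_requires_positives():
    with pytest.raises(ValueError):
        pr_auc([0, 0, 0], [0.1, 0.2, 0.3])


def test_confusion_rates_hand_count():
    labels = np.array([1] * 10 + [0] * 10)
    probs = np.concatenate([np.linspace(0.1, 1.0, 10), np.linspace(0.0, 0.9, 10)])
    rates = confusion_at_threshold(labels, probs, threshold=0.5)
    # positives with prob >= 0.5: 0.5, 0.6, 0.7, 0.8, 0.9, 1.0 -> 6 of 10
    assert rates["tp_rate"] == pytest.approx(0.6)
    assert rates["fn_rate"] == pytest.approx(0.4)
    # negatives with prob >= 0.5: 0.5, 0.6, 0.7, 0.8, 0.9 -> 5 of 10
    assert rates["fp_rate"] == pytest.approx(0.5)
    assert rates["tn_rate"] == pytest.approx(0.5)
    assert rates["tp_rate"] + rates["fn_rate"] == pytest.approx(1.0)


def test_probability_exactly_at_threshold_predicts_positive():
    rates = confusion_at_threshold([1, 0], [0.5, 0.5])
    assert rates["tp_rate"] == 1.0
    assert rates["fp_rate"] == 1.0


def test_confusion_rejects_out_of_range_probabilities():
    with pytest.raises(ValueError):
        confusion_at_threshold([1, 0], [1.2, 0.1])


# -- grid search -------------------------------------------------------------


def _toy_problem(seed=0, n=300, n_regions=20):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    y = (X["a"] + 0.5 * rng.normal(size=n) > 0).astype(int).to_numpy()
    groups = np.array([f"R{i % n_regions}" for i in range(n)])
    return X, y, groups


def test_single_grid_point_is_selected():
    X, y, groups = _toy_problem()
    space = [
        ModelFamily(
            "logistic_regression",
            lambda seed: LogisticRegression(max_iter=2000),
            {"C": [1.0]},
            standardize=True,
        )
    ]
    model, point, table = run_grid_search(X, y, groups, model_space=space)
    assert point.family == "logistic_regression"
    assert len(table) == 1
    assert 0.5 < table["mean_cv_roc_auc"].iloc[0] <= 1.0


def test_tied_grid_points_resolve_to_first():
    X, y, groups = _toy_problem()
    space = [
        ModelFamily(
            "logistic_regression",
            lambda seed: LogisticRegression(max_iter=2000),
            {"C": [1.0, 1.0]},  # two identical points, identical scores
            standardize=True,
        )
    ]
    _, point, table = run_grid_search(X, y, groups, model_space=space)
    assert table["mean_cv_roc_auc"].iloc[0] == table["mean_cv_roc_auc"].iloc[1]
    assert point.params == {"C": 1.0}
    assert int(np.argmax(table["mean_cv_roc_auc"].to_numpy())) == 0


def test_strong_linear_signal_recovered():
    X, y, groups = _toy_problem(seed=3, n=500)
    search = QualityModelSearch(model_space=compact_model_space(), seed=1).fit(
        X, y, groups=groups
    )
    assert search.best_score_ >= 0.9
    assert search.predict_proba(X).shape == (500, 2)


def test_search_requires_groups():
    X, y, _ = _toy_problem()
    with pytest.raises(ValueError):
        QualityModelSearch(model_space=compact_model_space()).fit(X, y)


def test_refit_standardization_uses_training_data_only():
    """The refit pipeline's scaler statistics equal the training input's
    moments, so a shifted held-out set cannot leak into preprocessing."""
    X, y, groups = _toy_problem(seed=4)
    space = [
        ModelFamily(
            "logistic_regression",
            lambda seed: LogisticRegression(max_iter=2000),
            {"C": [1.0]},
            standardize=True,
        )
    ]
    model, _, _ = run_grid_search(X, y, groups, model_space=space)
    scaler = model.named_steps["scale"]
    np.testing.assert_allclose(scaler.mean_, X.mean(axis=0).to_numpy(), atol=1e-12)
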