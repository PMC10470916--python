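"""Additive feature attributions and residual-based outlier detection.

Attributions are interventional Shapley values estimated by seeded
permutation sampling: for each instance, features enter in random order
and each feature is credited with the change in the model's mean
predicted probability (over a background sample) when its value is
switched from background to the instance.  Because every permutation's
marginal contributions telescope from the background mean to the
instance's prediction, the additivity identity

    base_value + sum(attributions) == predicted probability

holds exactly (up to floating point), whatever the number of
permutations; more permutations only reduce the variance of how credit
is shared among correlated features.

Residuals are observed label (0 = good, 1 = poor) minus predicted
probability of poor quality; large-magnitude residuals flag
municipalities whose observed certification quality is inconsistent with
what their socioeconomic and health-infrastructure context predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

__all__ = [
    "AttributionMatrix",
    "ShapleyAttributor",
    "attribute",
    "rank_features",
    "residuals",
]


@dataclass(frozen=True)
class AttributionMatrix:
    """Signed per-feature contributions; rows sum (with the base value)
    to the model's predicted probability for each row."""

    values: pd.DataFrame  # municipalities x features
    base_value: float
    feature_values: pd.DataFrame  # the inputs the attributions refer to

    def row_sums(self) -> np.ndarray:
        return self.base_value + self.values.to_numpy().sum(axis=1)


def _proba(model, X: np.ndarray, columns) -> np.ndarray:
    frame = pd.DataFrame(X, columns=columns)
    if not hasattr(model, "predict_proba"):
        raise TypeError("attribution requires a model with probability output")
    return model.predict_proba(frame)[:, 1]


class ShapleyAttributor(BaseEstimator):
    """Permutation-sampling Shapley attribution for probability models.

    ``fit`` stores a (seeded, size-capped) background sample representing
    the feature distribution; ``attribute`` explains rows of a feature
    matrix against it.

    Parameters
    ----------
    n_permutations : int, default 8
        Feature orderings sampled per explained row.
    max_background : int, default 100
        Background rows kept (seeded subsample when the reference sample
        is larger).
    seed : int, default 0
    """

    def __init__(self, n_permutations: int = 8, max_background: int = 100, seed: int = 0):
        self.n_permutations = n_permutations
        self.max_background = max_background
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None) -> "ShapleyAttributor":
        X = pd.DataFrame(X)
        if len(X) == 0:
            raise ValueError("reference sample must be non-empty")
        rng = np.random.default_rng(self.seed)
        if len(X) > self.max_background:
            keep = rng.choice(len(X), size=self.max_background, replace=False)
            X = X.iloc[np.sort(keep)]
        self.background_ = X.reset_index(drop=True)
        return self

    def attribute(self, model, X: pd.DataFrame) -> AttributionMatrix:
        """Explain each row of ``X`` for ``model``'s positive-class probability."""
        X = pd.DataFrame(X)
        bg = self.background_[X.columns].to_numpy(dtype=float)
        rows = X.to_numpy(dtype=float)
        n_rows, n_feat = rows.shape
        n_bg = len(bg)
        rng = np.random.default_rng(self.seed)
        base = float(_proba(model, bg, X.columns).mean())

        contrib = np.zeros((n_rows, n_feat))
        for _ in range(self.n_permutations):
            order = rng.permutation(n_feat)
            # Coalition matrices for all rows at once: stage s has the
            # first s features (in this order) switched to the instance.
            hybrids = np.tile(bg, (n_rows * (n_feat + 1), 1))
            hybrids = hybrids.reshape(n_rows, n_feat + 1, n_bg, n_feat)
            for stage in range(1, n_feat + 1):
                feats = order[:stage]
                hybrids[:, stage, :, feats] = rows[:, feats].T[:, :, None]
            flat = hybrids.reshape(-1, n_feat)
            preds = _proba(model, flat, X.columns).reshape(n_rows, n_feat + 1, n_bg)
            stage_means = preds.mean(axis=2)  # value of each coalition
            marginals = np.diff(stage_means, axis=1)  # per added feature
            contrib[:, order] += marginals
        contrib /= self.n_permutations

        values = pd.DataFrame(contrib, columns=X.columns, index=X.index)
        return AttributionMatrix(values=values, base_value=base, feature_values=X)


def attribute(
    model,
    X: pd.DataFrame,
    reference: pd.DataFrame,
    seed: int = 0,
    n_permutations: int = 8,
    max_background: int = 100,
) -> AttributionMatrix:
    """Functional wrapper over :class:`ShapleyAttributor`."""
    return (
        ShapleyAttributor(n_permutations=n_permutations, max_background=max_background, seed=seed)
        .fit(reference)
        .attribute(model, X)
    )


def rank_features(attributions: AttributionMatrix) -> pd.DataFrame:
    """Features ordered by mean |attribution|, with a direction summary.

    Direction is the sign of the rank correlation between a feature's
    values and its attributions (+1: higher values push toward poor
    quality); 0 flags an undefined direction (constant feature or zero
    attributions).
    """
    values = attributions.values
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError("empty attribution matrix")
    rows = []
    for feature in values.columns:
        attr = values[feature].to_numpy(dtype=float)
        feat = attributions.feature_values[feature].to_numpy(dtype=float)
        if np.ptp(attr) == 0 or np.ptp(feat) == 0:
            direction = 0
        else:
            ra = rankdata(attr) - (len(attr) + 1) / 2.0
            rf = rankdata(feat) - (len(feat) + 1) / 2.0
            direction = int(np.sign(np.dot(ra, rf)))
        rows.append(
            {
                "feature": feature,
                "mean_abs_attribution": float(np.abs(attr).mean()),
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "mean_abs_attribution", ascending=False, kind="stable"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def residuals(
    observed,
    predicted_probability,
    municipality_ids=None,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Residual table: observed label minus predicted poor-quality probability.

    Flags (symmetric about 0): residual >= cutoff -> ``worse_than_expected``
    (observed poor, context predicted good); residual <= -cutoff ->
    ``better_than_expected`` (observed good, context predicted poor);
    otherwise ``consistent``.
    """
    observed = np.asarray(observed)
    probs = np.asarray(predicted_probability, dtype=float)
    if len(observed) != len(probs):
        raise ValueError("observed and predicted sequences must be aligned")
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(observed, [0, 1]).all():
        raise ValueError("observed labels must be 0 (good) or 1 (poor)")
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    res = observed - probs
    flag = np.where(
        res >= cutoff,
        "worse_than_expected",
        np.where(res <= -cutoff, "better_than_expected", "consistent"),
    )
    out = pd.DataFrame(
        {
            "observed_label": observed,
            "predicted_probability": probs,
            "residual": res,
            "inconsistency_flag": flag,
        }
    )
    if municipality_ids is not None:
        out.insert(0, "municipality_id", np.asarray(municipality_ids))
    return out
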