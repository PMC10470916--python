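"""Shared fixtures.

``recovery_study`` is the expensive session fixture: a 2,000-municipality
simulated universe with the feature-quality signal tripled, carried through
the full pipeline (validation, garbage percentages, stratified correlation,
grouped split, grid search, attribution).  Several generative-recovery
tests share it so the simulation runs once per session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vitalqc import (
    GeneratorConfig,
    MODEL_FEATURES,
    QualityModelSearch,
    generate_certificates,
    generate_municipalities,
    grouped_split,
    stratified_correlation,
    summarize_municipalities,
)
from vitalqc.explain import ShapleyAttributor
from vitalqc.garbage import GarbageCodeClassifier
from vitalqc.model_selection import ModelFamily, evaluate_classifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression


def compact_model_space() -> list[ModelFamily]:
    """A small two-family space (standardized linear + raw-input forest)
    that keeps grid-search tests fast while still exercising selection."""
    return [
        ModelFamily(
            "logistic_regression",
            lambda seed: LogisticRegression(max_iter=5000),
            {"C": [0.1, 1.0]},
            standardize=True,
        ),
        ModelFamily(
            "random_forest",
            lambda seed: RandomForestClassifier(random_state=seed),
            {"n_estimators": [300], "max_depth": [10]},
            standardize=False,
        ),
    ]


@pytest.fixture(scope="session")
def small_world():
    """200 municipalities with small populations: fast end-to-end data."""
    config = GeneratorConfig(
        n_municipalities=200,
        n_regions=25,
        seed=11,
        feature_scales={"population": (1500.0, 0.8)},
    )
    profiles = generate_municipalities(config)
    records = generate_certificates(profiles, config)
    return config, profiles, records


@pytest.fixture(scope="session")
def recovery_study():
    """Tripled-signal 2,000-municipality study, run end to end."""
    config = GeneratorConfig(
        n_municipalities=2000, n_regions=160, seed=202, signal_scale=3.0
    )
    profiles = generate_municipalities(config)
    records = generate_certificates(profiles, config)
    summaries = summarize_municipalities(records)
    garbage = GarbageCodeClassifier().fit().municipal_pct(records)
    merged = summaries.merge(garbage, on="municipality_id").merge(
        profiles, on="municipality_id"
    )
    merged["label"] = (merged["quality_label"] == "poor").astype(int)

    strat = stratified_correlation(
        merged["overall_flaw_pct"], merged["garbage_pct"], merged["geoses_index"]
    )

    split = grouped_split(
        dict(zip(merged["municipality_id"], merged["region_id"])), seed=config.seed
    )
    merged["set"] = merged["municipality_id"].map(split.assignment)
    train = merged[merged["set"] == "train"]
    test = merged[merged["set"] == "test"]

    search = QualityModelSearch(model_space=compact_model_space(), seed=config.seed).fit(
        train[MODEL_FEATURES], train["label"].to_numpy(), groups=train["region_id"].to_numpy()
    )
    test_report = evaluate_classifier(search, test[MODEL_FEATURES], test["label"].to_numpy())

    attributor = ShapleyAttributor(n_permutations=4, max_background=60, seed=config.seed).fit(
        train[MODEL_FEATURES]
    )
    attributions = attributor.attribute(search, test[MODEL_FEATURES])

    return {
        "config": config,
        "profiles": profiles,
        "records": records,
        "merged": merged,
        "stratified": strat,
        "split": split,
        "search": search,
        "train": train,
        "test": test,
        "test_report": test_report,
        "attributions": attributions,
    }
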