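"""End-to-end orchestration of the quality analysis.

Stage order: validate certificates -> garbage percentages -> stratified
correlation -> grouped split -> grid search -> test-set evaluation ->
attributions -> residuals.  Every artifact is written in a format the
package's own readers accept, and the run log records seeds and input
checksums so a run is reproducible from (inputs, config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .correlation import stratified_correlation
from .explain import ShapleyAttributor, rank_features, residuals
from .garbage import GarbageCodeClassifier, GarbageCodeList
from .model_selection import (
    QualityModelSearch,
    evaluate_classifier,
    grouped_split,
)
from .synthetic import MODEL_FEATURES
from .validation import CertificateValidator, FieldDictionary

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("vitalqc")


@dataclass(frozen=True)
class PipelineConfig:
    records_csv: str | Path
    municipalities_csv: str | Path
    output_dir: str | Path
    dictionary_json: str | Path | None = None
    garbage_list_json: str | Path | None = None
    threshold_pct: float = 80.0
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    cv_folds: int = 5
    residual_cutoff: float = 0.5
    raw_geoses_orientation: bool = False
    attribution_permutations: int = 8
    attribution_background: int = 100
    model_space: object | None = None  # sequence of ModelFamily overrides
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0.0 < self.threshold_pct < 100.0:
            raise ValueError("threshold_pct must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the artifact paths and model report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_lines: list[str] = [f"seed={config.seed}"]
    for name, path in (
        ("records", config.records_csv),
        ("municipalities", config.municipalities_csv),
    ):
        checksum = vio.file_checksum(path)
        log_lines.append(f"input {name}={path} sha256={checksum}")
        logger.info("input %s=%s sha256=%s", name, path, checksum)

    records = vio.read_records(config.records_csv)
    municipalities = vio.read_municipalities(
        config.municipalities_csv, raw_geoses_orientation=config.raw_geoses_orientation
    )
    logger.info("read %d records, %d municipalities", len(records), len(municipalities))
    orphans = sorted(
        set(records["municipality_id"]) - set(municipalities["municipality_id"])
    )
    if orphans:
        raise ValueError(f"records reference unknown municipalities: {orphans[:10]}")

    dictionary = (
        FieldDictionary.from_json(config.dictionary_json)
        if config.dictionary_json
        else FieldDictionary.default()
    )
    garbage_list = (
        GarbageCodeList.from_json(config.garbage_list_json)
        if config.garbage_list_json
        else GarbageCodeList.default()
    )

    # 1. Field validation and municipal quality summaries.
    validator = CertificateValidator(
        dictionary=dictionary, threshold_pct=config.threshold_pct
    ).fit()
    summaries = validator.summarize(records)
    vio.write_table(summaries, out / "quality_summaries.csv")

    # 2. Garbage percentages.
    garbage = GarbageCodeClassifier(garbage_list=garbage_list).fit().municipal_pct(records)
    vio.write_table(garbage, out / "garbage_pct.csv")

    # 3. Stratified correlation (aligned on municipalities with both measures).
    merged = summaries.merge(garbage, on="municipality_id").merge(
        municipalities, on="municipality_id"
    )
    strat = stratified_correlation(
        merged["overall_flaw_pct"], merged["garbage_pct"], merged["geoses_index"]
    )
    vio.write_table(strat.to_frame(), out / "stratified_correlation.csv")
    vio.write_table(
        merged[["municipality_id", "overall_flaw_pct", "garbage_pct", "geoses_index"]],
        out / "correlation_scatter.csv",
    )

    # 4. Grouped split.
    group_map = dict(zip(merged["municipality_id"], merged["region_id"]))
    split = grouped_split(group_map, fractions=config.fractions, seed=config.seed)
    vio.write_table(split.to_frame(), out / "split_assignment.csv")
    merged["set"] = merged["municipality_id"].map(split.assignment)
    merged["label"] = (merged["quality_label"] == "poor").astype(int)

    X = {s: merged.loc[merged["set"] == s, MODEL_FEATURES] for s in ("train", "validation", "test")}
    y = {s: merged.loc[merged["set"] == s, "label"].to_numpy() for s in X}
    groups_train = merged.loc[merged["set"] == "train", "region_id"].to_numpy()

    # 5. Grid search with grouped CV; refit winner on the training set.
    search = QualityModelSearch(
        model_space=config.model_space, k=config.cv_folds, seed=config.seed
    ).fit(X["train"], y["train"], groups=groups_train)
    logger.info(
        "selected %s %s (CV ROC AUC %.3f)",
        search.best_point_.family,
        dict(search.best_point_.params),
        search.best_score_,
    )

    # 6. Evaluation: validation set for interim monitoring, test set for
    #    the reported numbers.
    report = {
        "selected_family": search.best_point_.family,
        "selected_params": {k: repr(v) for k, v in search.best_point_.params.items()},
        "cv_results": search.cv_results_.assign(
            params=search.cv_results_["params"].map(repr)
        ).to_dict(orient="records"),
        "cv_roc_auc": search.best_score_,
        "validation": evaluate_classifier(search, X["validation"], y["validation"]),
        "test": evaluate_classifier(search, X["test"], y["test"]),
        "seed": config.seed,
    }
    with open(out / "model_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)

    # 7. Attributions on the test set against a training-set background.
    attributor = ShapleyAttributor(
        n_permutations=config.attribution_permutations,
        max_background=config.attribution_background,
        seed=config.seed,
    ).fit(X["train"])
    attr = attributor.attribute(search, X["test"])
    attr_table = attr.values.copy()
    attr_table.insert(
        0, "municipality_id", merged.loc[merged["set"] == "test", "municipality_id"].to_numpy()
    )
    vio.write_table(attr_table, out / "attributions.csv")
    ranking = rank_features(attr)
    with open(out / "attribution_ranking.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"base_value": attr.base_value, "ranking": ranking.to_dict(orient="records")},
            fh,
            indent=2,
        )

    # 8. Residuals on the test set.
    test_probs = search.predict_proba(X["test"])[:, 1]
    res = residuals(
        y["test"],
        test_probs,
        municipality_ids=merged.loc[merged["set"] == "test", "municipality_id"].to_numpy(),
        cutoff=config.residual_cutoff,
    )
    vio.write_table(res, out / "residuals.csv")

    log_lines.append(f"selected={search.best_point_.family} cv_roc_auc={search.best_score_:.6f}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return {
        "output_dir": str(out),
        "report": report,
        "n_municipalities": int(len(merged)),
        "poor_pct": float(100.0 * merged["label"].mean()),
        "stratified_correlation": strat,
    }
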