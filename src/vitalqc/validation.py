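"""Field-level validation of death-certificate core topics.

A certificate field is *missing* when its raw value is empty (or
whitespace-only, for CSV robustness), *unexpected* when present but outside
the predefined codification list — for categorical topics, not in the
allowed code set; for date topics, not a calendar-valid date in the
configured layout — and *valid* otherwise.  A certificate is fully correct
when all seven core topics are valid.  Municipal quality is the percentage
of fully-correct certificates; a municipality is labelled ``poor`` when
that percentage falls strictly below the threshold (default 80%), ``good``
at or above it.
"""

from __future__ import annotations

import calendar
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import CORE_TOPICS

__all__ = [
    "FieldDictionary",
    "FieldVerdict",
    "QualitySummary",
    "VALID",
    "MISSING",
    "UNEXPECTED",
    "validate_field",
    "validate_record",
    "summarize_municipality",
    "summarize_municipalities",
    "topic_distribution",
    "CertificateValidator",
]

VALID = "valid"
MISSING = "missing"
UNEXPECTED = "unexpected"

DATE_TOPICS = ["date_of_occurrence", "date_of_registration", "date_of_birth"]
CATEGORICAL_TOPICS = ["place_of_occurrence", "certifier", "sex", "marital_status"]


@dataclass(frozen=True)
class FieldDictionary:
    """Per-topic validation rules: allowed code sets and date layouts."""

    categorical: Mapping[str, frozenset[str]]
    date_layouts: Mapping[str, str] = field(
        default_factory=lambda: {t: "DDMMYYYY" for t in DATE_TOPICS}
    )

    def __post_init__(self) -> None:
        topics = set(self.categorical) | set(self.date_layouts)
        missing = set(CORE_TOPICS) - topics
        if missing:
            raise ValueError(f"dictionary lacks rules for topics: {sorted(missing)}")
        for topic, allowed in self.categorical.items():
            if not allowed:
                raise ValueError(f"allowed set for {topic!r} is empty")
        for topic, layout in self.date_layouts.items():
            if layout != "DDMMYYYY":
                raise ValueError(f"unsupported date layout {layout!r} for {topic!r}")

    @classmethod
    def default(cls) -> "FieldDictionary":
        """The shipped dictionary mirroring MIS codification conventions."""
        text = resources.files("vitalqc.data").joinpath("field_dictionary.json").read_text()
        return cls.from_mapping(json.loads(text))

    @classmethod
    def from_json(cls, path: str | Path) -> "FieldDictionary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(json.load(fh))

    @classmethod
    def from_mapping(cls, spec: Mapping) -> "FieldDictionary":
        categorical = {
            topic: frozenset(rule["allowed"]) for topic, rule in spec["categorical"].items()
        }
        layouts = {topic: rule["layout"] for topic, rule in spec["dates"].items()}
        return cls(categorical=categorical, date_layouts=layouts)


@dataclass(frozen=True)
class FieldVerdict:
    topic: str
    status: str  # one of VALID / MISSING / UNEXPECTED


@dataclass(frozen=True)
class QualitySummary:
    """Municipal quality: per-topic and overall flaw percentages plus label."""

    municipality_id: str
    n_records: int
    per_topic_flaw_pct: Mapping[str, float]
    overall_flaw_pct: float
    pct_correct: float
    quality_label: str  # "good" or "poor"


def _is_calendar_valid_ddmmyyyy(raw: str) -> bool:
    if len(raw) != 8 or not raw.isdigit():
        return False
    day, month, year = int(raw[:2]), int(raw[2:4]), int(raw[4:])
    if not (1 <= month <= 12) or year == 0:
        return False
    return 1 <= day <= calendar.monthrange(year, month)[1]


_MONTH_DAYS = np.array([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def _calendar_valid_vector(raw: pd.Series) -> np.ndarray:
    """Vectorised DDMMYYYY calendar validity (agrees with the scalar rule
    for any year, unconstrained by timestamp ranges)."""
    shaped = raw.str.fullmatch(r"\d{8}").to_numpy(dtype=bool)
    day = pd.to_numeric(raw.str[0:2], errors="coerce").to_numpy()
    month = pd.to_numeric(raw.str[2:4], errors="coerce").to_numpy()
    year = pd.to_numeric(raw.str[4:8], errors="coerce").to_numpy()
    day = np.nan_to_num(day).astype(int)
    month = np.nan_to_num(month).astype(int)
    year = np.nan_to_num(year).astype(int)
    month_ok = (month >= 1) & (month <= 12)
    leap = ((year % 4 == 0) & (year % 100 != 0)) | (year % 400 == 0)
    max_day = _MONTH_DAYS[np.where(month_ok, month, 1)] + ((month == 2) & leap)
    return shaped & month_ok & (year >= 1) & (day >= 1) & (day <= max_day)


def validate_field(topic: str, raw: str, dictionary: FieldDictionary) -> FieldVerdict:
    """Classify one raw field value as valid, missing or unexpected."""
    if raw is None or str(raw).strip() == "":
        return FieldVerdict(topic, MISSING)
    raw = str(raw).strip()
    if topic in dictionary.categorical:
        status = VALID if raw in dictionary.categorical[topic] else UNEXPECTED
    elif topic in dictionary.date_layouts:
        status = VALID if _is_calendar_valid_ddmmyyyy(raw) else UNEXPECTED
    else:
        raise KeyError(f"unknown topic {topic!r}")
    return FieldVerdict(topic, status)


def validate_record(record: Mapping[str, str], dictionary: FieldDictionary) -> set[str]:
    """Return exactly the core topics whose value is missing or unexpected."""
    return {
        t for t in CORE_TOPICS if validate_field(t, record.get(t, ""), dictionary).status != VALID
    }


class CertificateValidator(BaseEstimator, TransformerMixin):
    """Vectorised validator for certificate tables.

    ``transform`` maps a records DataFrame (raw-string schema) to a
    same-length DataFrame of per-topic statuses; ``summarize`` aggregates
    to one :class:`QualitySummary` row per municipality.

    Parameters
    ----------
    dictionary : FieldDictionary, optional
        Validation rules; the shipped MIS-style defaults when omitted.
    threshold_pct : float, default 80.0
        Municipal quality label boundary: poor iff the percentage of
        fully-correct certificates is strictly below this value.
    """

    def __init__(self, dictionary: FieldDictionary | None = None, threshold_pct: float = 80.0):
        self.dictionary = dictionary
        self.threshold_pct = threshold_pct

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "CertificateValidator":
        if not 0.0 < self.threshold_pct < 100.0 + 1e-9:
            raise ValueError("threshold_pct must lie in (0, 100]")
        self.dictionary_ = self.dictionary if self.dictionary is not None else FieldDictionary.default()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-topic status table (``valid``/``missing``/``unexpected``)."""
        if not hasattr(self, "dictionary_"):
            self.fit()
        missing_cols = [t for t in CORE_TOPICS if t not in X.columns]
        if missing_cols:
            raise ValueError(f"records table lacks core-topic columns: {missing_cols}")
        out = {}
        for topic in CORE_TOPICS:
            raw = X[topic].astype(str).str.strip()
            is_missing = raw == ""
            if topic in self.dictionary_.categorical:
                allowed = self.dictionary_.categorical[topic]
                is_valid = raw.isin(list(allowed))
            else:
                is_valid = _calendar_valid_vector(raw)
            status = np.where(is_missing, MISSING, np.where(is_valid, VALID, UNEXPECTED))
            out[topic] = status
        return pd.DataFrame(out, index=X.index)

    def summarize(self, X: pd.DataFrame) -> pd.DataFrame:
        """One row per municipality with flaw percentages and quality label."""
        if "municipality_id" not in X.columns:
            raise ValueError("records table lacks municipality_id")
        if len(X) == 0:
            raise ValueError("cannot summarize an empty records table")
        statuses = self.transform(X)
        flawed = statuses != VALID
        grouped = flawed.groupby(X["municipality_id"].to_numpy())
        n = grouped.size()
        per_topic_pct = grouped.mean() * 100.0
        overall_pct = flawed.any(axis=1).groupby(X["municipality_id"].to_numpy()).mean() * 100.0
        out = per_topic_pct.add_suffix("_flaw_pct")
        out.insert(0, "n_records", n)
        out["overall_flaw_pct"] = overall_pct
        out["pct_correct"] = 100.0 - overall_pct
        out["quality_label"] = np.where(out["pct_correct"] < self.threshold_pct, "poor", "good")
        out.index.name = "municipality_id"
        return out.reset_index()


def summarize_municipality(
    records: pd.DataFrame | Iterable[Mapping[str, str]],
    dictionary: FieldDictionary | None = None,
    threshold_pct: float = 80.0,
) -> QualitySummary:
    """Quality summary for the records of a single municipality.

    Records must be non-empty and share one municipality_id; an empty input
    raises (an undefined summary, never a 0% default).
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if len(df) == 0:
        raise ValueError("cannot summarize zero records")
    ids = df["municipality_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"records span multiple municipalities: {sorted(ids)}")
    table = (
        CertificateValidator(dictionary=dictionary, threshold_pct=threshold_pct)
        .fit()
        .summarize(df)
    )
    row = table.iloc[0]
    return QualitySummary(
        municipality_id=str(row["municipality_id"]),
        n_records=int(row["n_records"]),
        per_topic_flaw_pct={t: float(row[f"{t}_flaw_pct"]) for t in CORE_TOPICS},
        overall_flaw_pct=float(row["overall_flaw_pct"]),
        pct_correct=float(row["pct_correct"]),
        quality_label=str(row["quality_label"]),
    )


def summarize_municipalities(
    records: pd.DataFrame,
    dictionary: FieldDictionary | None = None,
    threshold_pct: float = 80.0,
) -> pd.DataFrame:
    """Quality summary table over all municipalities present in ``records``."""
    return (
        CertificateValidator(dictionary=dictionary, threshold_pct=threshold_pct)
        .fit()
        .summarize(records)
    )


def topic_distribution(summaries: pd.DataFrame) -> pd.DataFrame:
    """Distribution of per-topic flaw percentages across municipalities.

    Returns one row per core topic with min, p25, median, p75 and max of
    the municipal flaw percentage for that topic.
    """
    if len(summaries) == 0:
        raise ValueError("no summaries given")
    rows = []
    for topic in CORE_TOPICS:
        vals = summaries[f"{topic}_flaw_pct"].to_numpy(dtype=float)
        rows.append(
            {
                "topic": topic,
                "min": vals.min(),
                "p25": np.percentile(vals, 25),
                "median": np.percentile(vals, 50),
                "p75": np.percentile(vals, 75),
                "max": vals.max(),
            }
        )
    return pd.DataFrame(rows)
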