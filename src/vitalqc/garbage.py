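"""Garbage-code classification of underlying causes of death.

Garbage codes are ICD-10 underlying-cause codes of no use for public-health
analysis — impossible underlying causes, intermediate or immediate causes,
or non-specific causes — that should be redistributed before mortality
statistics are interpreted.  This module classifies normalized ICD-10
codes against an interval list (a small documented default ships with the
package; a complete list can be supplied as JSON) and aggregates municipal
garbage percentages.  Downstream analyses use only the binary garbage
verdict; the four-type classification is carried for reporting.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GarbageCodeList",
    "GarbageInterval",
    "CauseVerdict",
    "NormalizationError",
    "normalize_icd",
    "classify_cause",
    "municipal_garbage_pct",
    "GarbageCodeClassifier",
]

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]?$")


class NormalizationError(ValueError):
    """Raised when a raw cause string is not a well-formed ICD-10 code."""


def normalize_icd(raw: str) -> str:
    """Canonicalize an ICD-10 code: trim, uppercase, drop the dot.

    The result must match letter + two digits + optional digit/letter
    (e.g. ``"i50.0" -> "I500"``); anything else raises
    :class:`NormalizationError`.
    """
    if raw is None:
        raise NormalizationError("empty cause")
    code = str(raw).strip().upper().replace(".", "")
    if not code:
        raise NormalizationError("empty cause")
    if not _CODE_RE.match(code):
        raise NormalizationError(f"malformed ICD-10 code: {raw!r}")
    return code


@dataclass(frozen=True)
class GarbageInterval:
    start: str
    end: str
    type: int
    label: str = ""

    def __post_init__(self) -> None:
        for endpoint in (self.start, self.end):
            if not _CODE_RE.match(endpoint) or len(endpoint) not in (3, 4):
                raise ValueError(f"bad interval endpoint {endpoint!r}")
        if len(self.start) != len(self.end):
            raise ValueError(f"interval endpoints differ in length: {self.start}-{self.end}")
        if self.start > self.end:
            raise ValueError(f"interval start after end: {self.start}-{self.end}")
        if self.type not in (1, 2, 3, 4):
            raise ValueError(f"garbage type must be 1-4, got {self.type}")

    def contains(self, code: str) -> bool:
        # 3-character intervals match any code sharing a stem in range;
        # 4-character intervals match codes literally in range.
        if len(self.start) == 3:
            return self.start <= code[:3] <= self.end
        return self.start <= code <= self.end


@dataclass(frozen=True)
class GarbageCodeList:
    """Ordered garbage-code intervals; first matching entry wins."""

    entries: tuple[GarbageInterval, ...]
    provenance: str = ""

    @classmethod
    def default(cls) -> "GarbageCodeList":
        text = resources.files("vitalqc.data").joinpath("garbage_codes.json").read_text()
        return cls.from_mapping(json.loads(text))

    @classmethod
    def from_json(cls, path: str | Path) -> "GarbageCodeList":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(json.load(fh))

    @classmethod
    def from_mapping(cls, spec) -> "GarbageCodeList":
        entries = tuple(
            GarbageInterval(e["start"], e["end"], int(e["type"]), e.get("label", ""))
            for e in spec["entries"]
        )
        return cls(entries=entries, provenance=spec.get("provenance", ""))


@dataclass(frozen=True)
class CauseVerdict:
    canonical_code: str
    is_garbage: bool
    garbage_type: int | None
    matched_interval: GarbageInterval | None


def classify_cause(raw: str, garbage_list: GarbageCodeList) -> CauseVerdict:
    """Classify one raw cause string against the garbage list."""
    code = normalize_icd(raw)
    for entry in garbage_list.entries:
        if entry.contains(code):
            return CauseVerdict(code, True, entry.type, entry)
    return CauseVerdict(code, False, None, None)


class GarbageCodeClassifier(BaseEstimator, TransformerMixin):
    """Vectorised garbage classification over record tables.

    ``transform`` maps a records DataFrame to a per-record verdict frame
    with columns ``classifiable`` (the cause normalizes), ``is_garbage``
    and ``garbage_type``; ``municipal_pct`` aggregates the garbage
    percentage per municipality among classifiable causes.
    """

    def __init__(self, garbage_list: GarbageCodeList | None = None):
        self.garbage_list = garbage_list

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "GarbageCodeClassifier":
        self.garbage_list_ = (
            self.garbage_list if self.garbage_list is not None else GarbageCodeList.default()
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "garbage_list_"):
            self.fit()
        raw = X["underlying_cause"].astype(str)
        # Classify each distinct raw string once.
        verdicts: dict[str, tuple[bool, bool, float]] = {}
        for value in raw.unique():
            try:
                v = classify_cause(value, self.garbage_list_)
            except NormalizationError:
                verdicts[value] = (False, False, np.nan)
            else:
                verdicts[value] = (True, v.is_garbage, v.garbage_type or np.nan)
        mapped = raw.map(verdicts)
        out = pd.DataFrame(
            {
                "classifiable": mapped.str[0].astype(bool),
                "is_garbage": mapped.str[1].astype(bool),
                "garbage_type": mapped.str[2],
            },
            index=X.index,
        )
        return out

    def municipal_pct(self, X: pd.DataFrame) -> pd.DataFrame:
        """Garbage percentage per municipality.

        The denominator is the number of classifiable causes (non-empty
        and normalizable); unclassifiable causes are counted separately in
        ``n_unclassifiable`` so the field-quality and cause-quality
        measures stay orthogonal.
        """
        verdicts = self.transform(X)
        key = X["municipality_id"].to_numpy()
        grouped = verdicts.groupby(key)
        n_classifiable = grouped["classifiable"].sum()
        n_garbage = grouped["is_garbage"].sum()
        if (n_classifiable == 0).any():
            bad = n_classifiable.index[n_classifiable == 0].tolist()
            raise ValueError(f"no classifiable causes for municipalities: {bad}")
        out = pd.DataFrame(
            {
                "n_records": grouped.size(),
                "n_classifiable": n_classifiable,
                "n_unclassifiable": grouped.size() - n_classifiable,
                "garbage_pct": 100.0 * n_garbage / n_classifiable,
            }
        )
        out.index.name = "municipality_id"
        return out.reset_index()


def municipal_garbage_pct(
    records: pd.DataFrame, garbage_list: GarbageCodeList | None = None
) -> float:
    """Garbage percentage for the records of a single municipality."""
    if len(records) == 0:
        raise ValueError("no records given")
    ids = records["municipality_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"records span multiple municipalities: {sorted(ids)}")
    table = GarbageCodeClassifier(garbage_list=garbage_list).fit().municipal_pct(records)
    return float(table["garbage_pct"].iloc[0])
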