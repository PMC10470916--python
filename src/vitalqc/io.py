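"""Readers and writers for the pipeline's tabular formats.

CSV dialect: comma-separated, UTF-8, empty field = missing.  Certificate
fields are always read as raw strings (validation happens downstream);
municipality features are parsed as locale-independent numbers.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .synthetic import CORE_TOPICS, MODEL_FEATURES, RECORD_COLUMNS

__all__ = [
    "read_records",
    "read_municipalities",
    "write_table",
    "file_checksum",
    "MUNICIPALITY_INPUT_COLUMNS",
]

#: Required columns of a municipality input table (latent_quality, present
#: in synthetic fixtures, is optional and never a model feature).
MUNICIPALITY_INPUT_COLUMNS = ["municipality_id", "region_id"] + MODEL_FEATURES + ["geoses_index"]


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a certificate-level records CSV into the raw-string schema."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file {path} lacks required columns: {missing}")
    return df[RECORD_COLUMNS]


def read_municipalities(path: str | Path, raw_geoses_orientation: bool = False) -> pd.DataFrame:
    """Read a municipality table, validating the feature schema.

    With ``raw_geoses_orientation=True`` the file carries education and
    deprivation in the raw GeoSES orientation (education = share without
    instruction, deprivation = car ownership) and both columns are
    multiplied by -1 on read so that, as everywhere in this package,
    higher education/lower deprivation mean better conditions.
    """
    df = pd.read_csv(path)
    missing = [c for c in MUNICIPALITY_INPUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"municipality file {path} lacks required columns: {missing}")
    for col in MODEL_FEATURES + ["geoses_index"]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in column {col!r} of {path}") from exc
    if raw_geoses_orientation:
        df["education"] = -df["education"]
        df["deprivation"] = -df["deprivation"]
    bad = df[(df["geoses_index"] < -1) | (df["geoses_index"] > 1)]
    if len(bad):
        raise ValueError(
            f"geoses_index outside [-1, 1] for municipalities: "
            f"{bad['municipality_id'].tolist()[:5]}"
        )
    for col in ["pct_sus_facilities", "pct_emergency_facilities"]:
        if ((df[col] < 0) | (df[col] > 100)).any():
            raise ValueError(f"{col} outside [0, 100] in {path}")
    df["municipality_id"] = df["municipality_id"].astype(str)
    df["region_id"] = df["region_id"].astype(str)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for the run log."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
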