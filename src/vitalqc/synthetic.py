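"""Synthetic municipality tables and certificate-level death records.

Every downstream stage of the pipeline (field validation, garbage coding,
stratified correlation, grouped model selection, attribution) is testable
against data produced here, with no external download.  The generator
emulates the statistical structure of the Brazilian Mortality Information
System (SIM/MIS) setting:

* municipality-level socioeconomic dimensions that are strongly mutually
  correlated through a shared latent "disadvantage" factor, with skewed,
  census-like marginal distributions;
* health-region grouping that induces spatial correlation (municipalities
  in the same region share a region-level latent component);
* a hidden municipal flaw propensity (``latent_quality``) that is a
  logistic function of the standardized features with a configurable sign
  structure (by default: poverty, deprivation, population and %-SUS push
  quality down; education, income, wealth, physicians, beds and death rate
  push it up);
* a per-certificate flaw process on the seven core topics (missing or
  unexpected raw values) driven by that propensity; and
* a garbage-coding process for the underlying cause whose coupling to the
  flaw propensity strengthens as the socioeconomic index decreases.

All record fields are raw strings; missing is the empty string.  Validation
is a downstream concern (:mod:`vitalqc.validation`), never performed here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "MODEL_FEATURES",
    "MUNICIPALITY_COLUMNS",
    "RECORD_COLUMNS",
    "CORE_TOPICS",
    "generate_municipalities",
    "generate_certificates",
    "simulate",
    "export_fixture",
]

#: The eleven model features (socioeconomic + health-infrastructure +
#: demography).  ``geoses_index`` is reserved for stratification and
#: ``latent_quality`` is generator-internal; neither is a model feature.
MODEL_FEATURES = [
    "population",
    "education",
    "poverty",
    "wealth",
    "income",
    "deprivation",
    "physicians_per_1000",
    "beds_per_1000",
    "pct_sus_facilities",
    "pct_emergency_facilities",
    "death_rate_per_1000",
]

MUNICIPALITY_COLUMNS = (
    ["municipality_id", "region_id"] + MODEL_FEATURES + ["geoses_index", "latent_quality"]
)

#: The seven core topics of a death certificate, in schema order.
CORE_TOPICS = [
    "date_of_occurrence",
    "date_of_registration",
    "date_of_birth",
    "place_of_occurrence",
    "certifier",
    "sex",
    "marital_status",
]

RECORD_COLUMNS = ["municipality_id"] + CORE_TOPICS + ["underlying_cause"]

# Default per-topic baseline flaw probabilities.  Dates and sex are almost
# always filled correctly; certifier and marital status carry most of the
# flaw mass, with date of registration in between (median municipal flaw
# percentages near 10%, 9% and 1% respectively).
_DEFAULT_TOPIC_BASE_RATES: dict[str, float] = {
    "date_of_occurrence": 0.002,
    "date_of_registration": 0.010,
    "date_of_birth": 0.003,
    "place_of_occurrence": 0.004,
    "certifier": 0.092,
    "sex": 0.001,
    "marital_status": 0.083,
}

# Signed weights linking standardized features to the latent flaw
# propensity.  Positive = higher value pushes quality down.
_DEFAULT_QUALITY_COEFFICIENTS: dict[str, float] = {
    "poverty": 0.090,
    "deprivation": 0.090,
    "education": -0.090,
    "income": -0.090,
    "wealth": -0.045,
    "population": 0.023,
    "pct_sus_facilities": 0.034,
    "pct_emergency_facilities": 0.0,
    "physicians_per_1000": -0.034,
    "beds_per_1000": -0.023,
    "death_rate_per_1000": -0.023,
}

# Location/spread knobs per feature; the structural (link) form of each
# marginal is fixed, these set its centre and scale.
_DEFAULT_FEATURE_SCALES: dict[str, tuple[float, float]] = {
    "population": (11000.0, 1.1),          # lognormal median, log-sd
    "education": (-70.0, 7.0),
    "poverty": (45.0, 20.0),
    "wealth": (0.45, 0.4),                 # lognormal-like centre, log-sd
    "income": (1500.0, 0.3),               # lognormal-like centre, log-sd
    "deprivation": (-22.0, 15.0),
    "physicians_per_1000": (1.0, 0.4),     # lognormal-like centre, log-sd
    "beds_per_1000": (2.0, 0.5),           # given non-zero; ~30% zeros
    "pct_sus_facilities": (88.0, 12.0),
    "pct_emergency_facilities": (8.0, 7.0),
    "death_rate_per_1000": (3.6, 0.35),    # lognormal-like centre, log-sd
}

# Raw-string vocabularies used when a topic is generated as valid /
# unexpected.  Valid pools mirror the shipped field dictionary; unexpected
# tokens are deliberately outside every allowed set.
_VALID_POOLS: dict[str, tuple[list[str], list[float]]] = {
    "place_of_occurrence": (["1", "2", "3", "4", "5", "9"], [0.55, 0.08, 0.22, 0.06, 0.07, 0.02]),
    "certifier": (["1", "2", "3", "4", "5", "9"], [0.45, 0.20, 0.12, 0.10, 0.11, 0.02]),
    "sex": (["1", "2", "0"], [0.52, 0.46, 0.02]),
    "marital_status": (["1", "2", "3", "4", "5", "9"], [0.28, 0.34, 0.22, 0.05, 0.08, 0.03]),
}
_UNEXPECTED_TOKENS: dict[str, str] = {
    "place_of_occurrence": "0",
    "certifier": "7",
    "sex": "3",
    "marital_status": "8",
}

_GARBAGE_CAUSES = ["R54", "R99", "A419", "I500", "D65", "I469", "C80", "M545", "I519"]
_NONGARBAGE_CAUSES = ["I219", "C509", "J449", "E112", "G309", "K703", "I64"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the simulated mortality-system universe.

    Defaults match the real setting being emulated: 5,570 municipalities
    grouped into ~450 health regions, certificates pooled over 2010-2017,
    feature locations and spreads on census-like scales, and flaw/garbage
    rates producing a median municipality near the 80% correct-entry
    threshold.
    """

    n_municipalities: int = 5570
    n_regions: int = 450
    years: tuple[int, int] = (2010, 2017)
    seed: int = 0
    quality_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_QUALITY_COEFFICIENTS)
    )
    topic_base_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TOPIC_BASE_RATES)
    )
    garbage_base_rate: float = 0.25
    #: Per-quartile (Q1..Q4 of geoses_index) multipliers coupling the
    #: garbage probability to latent quality; larger = tighter coupling.
    garbage_quality_coupling: tuple[float, float, float, float] = (4.5, 1.4, 0.8, 0.1)
    #: Municipality-level noise (sd, probability scale) on the garbage rate.
    garbage_noise_sd: float = 0.05
    #: Noise sd inside the latent-quality logistic link; controls how
    #: predictable quality is from the features.
    quality_noise_sd: float = 0.5
    #: Multiplier on every quality coefficient (signal strength knob).
    signal_scale: float = 1.0
    #: Within-region share of the variance of the disadvantage factor.
    region_correlation: float = 0.5
    cause_missing_rate: float = 0.005
    feature_scales: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_FEATURE_SCALES)
    )

    def __post_init__(self) -> None:
        if self.n_municipalities < 0:
            raise ValueError("n_municipalities must be non-negative")
        if self.n_municipalities > 0 and not (1 <= self.n_regions <= self.n_municipalities):
            raise ValueError("need 1 <= n_regions <= n_municipalities")
        for name, p in {
            "garbage_base_rate": self.garbage_base_rate,
            "cause_missing_rate": self.cause_missing_rate,
            **dict(self.topic_base_rates),
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if not 0.0 <= self.region_correlation <= 1.0:
            raise ValueError("region_correlation outside [0, 1]")
        if self.years[0] > self.years[1]:
            raise ValueError("years must be an inclusive (first, last) range")

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from a key-value (YAML) file; seed is mandatory."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("generator config file must set a seed")
        for key in ("years", "garbage_quality_coupling"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "feature_scales" in raw:
            raw["feature_scales"] = {k: tuple(v) for k, v in raw["feature_scales"].items()}
        return cls(**raw)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_municipalities(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the municipality table.

    Returns a DataFrame with :data:`MUNICIPALITY_COLUMNS`.  Socioeconomic
    dimensions load on a shared disadvantage factor (itself partly shared
    within health regions), producing the strong pairwise correlations and
    the region-level spatial correlation the analysis assumes.
    ``latent_quality`` in [0, 1] is the hidden flaw propensity: a logistic
    function of the standardized features with the configured signs, plus
    noise; it is exported in this table for calibration checks but is never
    part of the model feature set.
    """
    n = config.n_municipalities
    if n == 0:
        return pd.DataFrame(columns=MUNICIPALITY_COLUMNS)
    rng = np.random.default_rng(config.seed)
    sc = dict(_DEFAULT_FEATURE_SCALES) | dict(config.feature_scales)

    region = rng.integers(0, config.n_regions, size=n)
    region_latent = rng.normal(size=config.n_regions)
    rc = config.region_correlation
    # Disadvantage factor: shared region component + municipal component.
    d = np.sqrt(rc) * region_latent[region] + np.sqrt(1.0 - rc) * rng.normal(size=n)

    def mixed(weight_d: float = 0.8, weight_e: float = 0.6) -> np.ndarray:
        return weight_d * d + weight_e * rng.normal(size=n)

    poverty = np.clip(sc["poverty"][0] + sc["poverty"][1] * mixed(), 0.0, 100.0)
    deprivation = np.clip(sc["deprivation"][0] + sc["deprivation"][1] * mixed(), -100.0, 0.0)
    education = np.clip(sc["education"][0] - sc["education"][1] * mixed(), -100.0, 0.0)
    income = sc["income"][0] * np.exp(-sc["income"][1] * mixed())
    wealth = sc["wealth"][0] * np.exp(-sc["wealth"][1] * mixed())
    population = np.maximum(
        np.exp(np.log(sc["population"][0]) + 0.15 * d + sc["population"][1] * rng.normal(size=n)),
        500.0,
    ).astype(np.int64)
    physicians = sc["physicians_per_1000"][0] * np.exp(
        -0.3 * d + sc["physicians_per_1000"][1] * rng.normal(size=n)
    )
    beds_nonzero = sc["beds_per_1000"][0] * np.exp(
        -0.1 * d + sc["beds_per_1000"][1] * rng.normal(size=n)
    )
    beds = np.where(rng.random(n) < 0.30, 0.0, beds_nonzero)
    pct_sus = np.clip(
        sc["pct_sus_facilities"][0]
        + sc["pct_sus_facilities"][1] * (0.8 * d + 0.6 * rng.normal(size=n)),
        0.0,
        100.0,
    )
    pct_emergency = np.clip(
        sc["pct_emergency_facilities"][0]
        + sc["pct_emergency_facilities"][1] * rng.normal(size=n),
        0.0,
        100.0,
    )
    death_rate = np.clip(
        sc["death_rate_per_1000"][0]
        * np.exp(-0.1 * d + sc["death_rate_per_1000"][1] * rng.normal(size=n)),
        0.5,
        25.0,
    )
    geoses = np.clip(np.tanh(-0.55 * d + 0.15 * rng.normal(size=n)), -1.0, 1.0)

    table = pd.DataFrame(
        {
            "municipality_id": [f"M{i:05d}" for i in range(n)],
            "region_id": [f"R{r:04d}" for r in region],
            "population": population,
            "education": education,
            "poverty": poverty,
            "wealth": wealth,
            "income": income,
            "deprivation": deprivation,
            "physicians_per_1000": physicians,
            "beds_per_1000": beds,
            "pct_sus_facilities": pct_sus,
            "pct_emergency_facilities": pct_emergency,
            "death_rate_per_1000": death_rate,
            "geoses_index": geoses,
        }
    )

    coefs = dict(_DEFAULT_QUALITY_COEFFICIENTS) | dict(config.quality_coefficients)
    eta = np.zeros(n)
    for feat, c in coefs.items():
        col = table[feat].to_numpy(dtype=float)
        sd = col.std()
        if sd > 0:
            eta += c * (col - col.mean()) / sd
    eta *= config.signal_scale
    eta += config.quality_noise_sd * rng.normal(size=n)
    table["latent_quality"] = _sigmoid(eta)
    return table[MUNICIPALITY_COLUMNS]


def _quartile_of(values: np.ndarray) -> np.ndarray:
    """Quartile labels 0..3 with the <=p25 / (p25,p50] / (p50,p75] / rest rule."""
    cuts = np.percentile(values, [25, 50, 75])
    return np.searchsorted(cuts, values, side="left").clip(0, 3)


def _valid_dates(rng: np.random.Generator, size: int, years: tuple[int, int]) -> np.ndarray:
    """Calendar-valid DDMMYYYY strings (days 1-28 so validity never depends
    on the month; validation still handles the full calendar)."""
    day = rng.integers(1, 29, size=size)
    month = rng.integers(1, 13, size=size)
    year = rng.integers(years[0], years[1] + 1, size=size)
    packed = day * 1_000_000 + month * 10_000 + year
    return np.char.zfill(packed.astype("U8"), 8)


def _invalid_dates(rng: np.random.Generator, size: int, years: tuple[int, int]) -> np.ndarray:
    """Calendar-invalid DDMMYYYY strings (day 32, month 13)."""
    year = rng.integers(years[0], years[1] + 1, size=size)
    return np.char.add("3213", year.astype("U4"))


def generate_certificates(profiles: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Generate certificate-level records for the given municipalities.

    Per municipality the record count is Poisson around
    population x death_rate/1000 x n_years (re-drawn until at least one
    record, so percentage denominators are always positive).  Each core
    topic is independently flawed with probability p = 2 x base_rate x
    latent_quality, split evenly between missing ("") and an unexpected
    raw value.  The underlying cause is drawn as a garbage code with a
    probability coupled to latent quality, the coupling strength set by
    the municipality's socioeconomic-index quartile (strongest in Q1).
    """
    if len(profiles) == 0:
        raise ValueError("profiles must be non-empty")
    rng = np.random.default_rng([config.seed, 1])
    n_years = config.years[1] - config.years[0] + 1
    pop = profiles["population"].to_numpy(dtype=float)
    dr = profiles["death_rate_per_1000"].to_numpy(dtype=float)
    quality = profiles["latent_quality"].to_numpy(dtype=float)
    expectation = pop * dr / 1000.0 * n_years

    counts = rng.poisson(expectation)
    for _ in range(100):
        zero = counts == 0
        if not zero.any():
            break
        counts[zero] = rng.poisson(expectation[zero])
    counts = np.maximum(counts, 1)

    total = int(counts.sum())
    muni_idx = np.repeat(np.arange(len(profiles)), counts)
    base_rates = dict(_DEFAULT_TOPIC_BASE_RATES) | dict(config.topic_base_rates)

    data: dict[str, np.ndarray] = {
        "municipality_id": profiles["municipality_id"].to_numpy(dtype=object)[muni_idx]
    }
    rec_quality = quality[muni_idx]
    for topic in CORE_TOPICS:
        p = np.clip(2.0 * base_rates[topic] * rec_quality, 0.0, 1.0)
        u = rng.random(total)
        missing = u < p / 2.0
        unexpected = (u >= p / 2.0) & (u < p)
        if topic in _VALID_POOLS:
            pool, weights = _VALID_POOLS[topic]
            values = rng.choice(np.array(pool, dtype="U2"), size=total, p=weights)
            values[unexpected] = _UNEXPECTED_TOKENS[topic]
        else:
            yr = config.years if topic != "date_of_birth" else (1920, config.years[1])
            values = _valid_dates(rng, total, yr)
            values[unexpected] = _invalid_dates(rng, int(unexpected.sum()), config.years)
        values = values.astype(object)
        values[missing] = ""
        data[topic] = values

    # Garbage process: municipal garbage probability coupled to latent
    # quality, more tightly so in lower socioeconomic quartiles.
    quartile = _quartile_of(profiles["geoses_index"].to_numpy(dtype=float))
    coupling = np.asarray(config.garbage_quality_coupling)[quartile]
    p_garbage = np.clip(
        config.garbage_base_rate * (1.0 + coupling * (quality - 0.5))
        + config.garbage_noise_sd * rng.normal(size=len(profiles)),
        0.01,
        0.95,
    )
    u = rng.random(total)
    cause = np.where(
        u < p_garbage[muni_idx],
        rng.choice(np.array(_GARBAGE_CAUSES, dtype=object), size=total),
        rng.choice(np.array(_NONGARBAGE_CAUSES, dtype=object), size=total),
    )
    cause[rng.random(total) < config.cause_missing_rate] = ""
    data["underlying_cause"] = cause

    return pd.DataFrame(data, columns=RECORD_COLUMNS)


def simulate(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: generate the municipality table and its certificates."""
    profiles = generate_municipalities(config)
    records = generate_certificates(profiles, config)
    return profiles, records


def export_fixture(
    profiles: pd.DataFrame, records: pd.DataFrame, directory: str | Path
) -> tuple[Path, Path]:
    """Write municipality and record CSVs in the pipeline's input formats.

    Missing values are written as empty fields; the files round-trip
    losslessly through :mod:`vitalqc.io` readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    muni_path = directory / "municipalities.csv"
    rec_path = directory / "records.csv"
    profiles.to_csv(muni_path, index=False)
    records.to_csv(rec_path, index=False)
    return muni_path, rec_path
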