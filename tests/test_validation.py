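"""Field-validation engine: verdicts, municipal summaries, 80% boundary."""

import numpy as np
import pandas as pd
import pytest

from vitalqc import (
    CORE_TOPICS,
    FieldDictionary,
    summarize_municipalities,
    summarize_municipality,
    topic_distribution,
    validate_field,
    validate_record,
)
from vitalqc.validation import CertificateValidator

DICT = FieldDictionary.default()


def _record(**overrides) -> dict:
    base = {
        "municipality_id": "M1",
        "date_of_occurrence": "15032014",
        "date_of_registration": "20032014",
        "date_of_birth": "01011950",
        "place_of_occurrence": "1",
        "certifier": "1",
        "sex": "1",
        "marital_status": "2",
        "underlying_cause": "I219",
    }
    base.update(overrides)
    return base


@pytest.mark.parametrize(
    "topic, raw, status",
    [
        ("sex", "1", "valid"),          # male, from the predefined list
        ("sex", "2", "valid"),
        ("sex", "0", "valid"),          # the "ignored" code is on the list
        ("sex", "", "missing"),
        ("sex", "   ", "missing"),      # whitespace-only counts as missing
        ("sex", "3", "unexpected"),
        ("marital_status", "9", "valid"),
        ("marital_status", "8", "unexpected"),
        ("certifier", "7", "unexpected"),
        ("date_of_occurrence", "32132010", "unexpected"),  # day 32, month 13
        ("date_of_occurrence", "29022012", "valid"),       # leap day
        ("date_of_occurrence", "29022013", "unexpected"),  # not a leap year
        ("date_of_occurrence", "31042015", "unexpected"),  # April has 30 days
        ("date_of_occurrence", "2013", "unexpected"),      # wrong layout
        ("date_of_birth", "01011890", "valid"),            # any calendar-valid year
    ],
)
def test_field_verdicts(topic, raw, status):
    assert validate_field(topic, raw, DICT).status == status


def test_unknown_topic_is_a_configuration_error():
    with pytest.raises(KeyError):
        validate_field("age", "60", DICT)


def test_dictionary_must_cover_every_core_topic():
    with pytest.raises(ValueError):
        FieldDictionary(categorical={"sex": frozenset({"1"})}, date_layouts={})


def test_record_verdicts():
    assert validate_record(_record(), DICT) == set()
    flawed = _record(sex="3", marital_status="")
    assert validate_record(flawed, DICT) == {"sex", "marital_status"}
    all_empty = _record(**{t: "" for t in CORE_TOPICS})
    assert validate_record(all_empty, DICT) == set(CORE_TOPICS)


def test_quality_label_boundary_at_80_percent():
    """Exactly 80% fully-correct certificates is still good quality; the
    poor label needs the percentage to fall strictly below 80."""
    eight_good = [_record() for _ in range(8)] + [_record(sex="3") for _ in range(2)]
    summary = summarize_municipality(pd.DataFrame(eight_good))
    assert summary.pct_correct == pytest.approx(80.0)
    assert summary.quality_label == "good"

    seven_good = [_record() for _ in range(7)] + [_record(sex="3") for _ in range(3)]
    summary = summarize_municipality(pd.DataFrame(seven_good))
    assert summary.pct_correct == pytest.approx(70.0)
    assert summary.quality_label == "poor"


def test_single_correct_record_summary():
    summary = summarize_municipality(pd.DataFrame([_record()]))
    assert summary.pct_correct == 100.0
    assert summary.overall_flaw_pct == 0.0
    assert summary.n_records == 1


def test_empty_records_raise_rather_than_default():
    with pytest.raises(ValueError):
        summarize_municipality(pd.DataFrame(columns=list(_record())))


def _random_records(rng: np.random.Generator, n: int) -> pd.DataFrame:
    tokens = {
        "date_of_occurrence": ["15032014", "32132010", ""],
        "date_of_registration": ["20032014", "99999999", ""],
        "date_of_birth": ["01011950", "31042015", ""],
        "place_of_occurrence": ["1", "0", ""],
        "certifier": ["2", "7", ""],
        "sex": ["1", "3", ""],
        "marital_status": ["2", "8", ""],
    }
    rows = []
    for _ in range(n):
        row = {"municipality_id": "M1", "underlying_cause": "I219"}
        for topic, pool in tokens.items():
            row[topic] = pool[rng.integers(0, 3)]
        rows.append(row)
    return pd.DataFrame(rows)


def test_summary_matches_brute_force_recount():
    """On small record sets the vectorised summary equals a field-by-field
    recount through the scalar validator."""
    rng = np.random.default_rng(42)
    for _ in range(5):
        records = _random_records(rng, int(rng.integers(1, 21)))
        summary = summarize_municipality(records)
        flaw_sets = [validate_record(row, DICT) for row in records.to_dict(orient="records")]
        n = len(records)
        expected_overall = 100.0 * sum(bool(s) for s in flaw_sets) / n
        assert summary.overall_flaw_pct == pytest.approx(expected_overall)
        assert summary.pct_correct == pytest.approx(100.0 - expected_overall)
        for topic in CORE_TOPICS:
            expected = 100.0 * sum(topic in s for s in flaw_sets) / n
            assert summary.per_topic_flaw_pct[topic] == pytest.approx(expected)
        # union bound and lower envelope
        assert summary.overall_flaw_pct <= sum(summary.per_topic_flaw_pct.values()) + 1e-9
        assert summary.overall_flaw_pct >= max(summary.per_topic_flaw_pct.values()) - 1e-9


def test_validation_is_idempotent_and_monotone():
    rng = np.random.default_rng(7)
    records = _random_records(rng, 12)
    first = summarize_municipality(records)
    second = summarize_municipality(records)
    assert first == second

    with_good = pd.concat([records, pd.DataFrame([_record()])], ignore_index=True)
    assert summarize_municipality(with_good).pct_correct >= first.pct_correct
    with_bad = pd.concat([records, pd.DataFrame([_record(sex="3")])], ignore_index=True)
    assert summarize_municipality(with_bad).pct_correct <= first.pct_correct


def test_mixed_municipalities_rejected_by_single_summary():
    records = pd.DataFrame([_record(), _record(municipality_id="M2")])
    with pytest.raises(ValueError):
        summarize_municipality(records)


def test_topic_distribution_quartiles():
    frames = []
    for mid, n_flawed in [("A", 0), ("B", 1), ("C", 2)]:
        rows = [_record(municipality_id=mid) for _ in range(10 - n_flawed)]
        rows += [_record(municipality_id=mid, sex="3") for _ in range(n_flawed)]
        frames.append(pd.DataFrame(rows))
    summaries = summarize_municipalities(pd.concat(frames, ignore_index=True))
    dist = topic_distribution(summaries)
    sex_row = dist[dist["topic"] == "sex"].iloc[0]
    assert sex_row["median"] == pytest.approx(10.0)
    assert sex_row["min"] == pytest.approx(0.0)
    assert sex_row["max"] == pytest.approx(20.0)

    single = topic_distribution(summaries.iloc[:1])
    row = single[single["topic"] == "sex"].iloc[0]
    assert row["min"] == row["p25"] == row["median"] == row["p75"] == row["max"]


def test_date_topics_flawed_less_often_than_certifier(recovery_study):
    """With the configured base rates, municipal medians for date topics sit
    far below the certifier/marital-status medians, as in the emulated
    system."""
    summaries = recovery_study["merged"]
    dates = np.median(summaries["date_of_occurrence_flaw_pct"])
    certifier = np.median(summaries["certifier_flaw_pct"])
    marital = np.median(summaries["marital_status_flaw_pct"])
    assert dates < certifier / 5
    assert dates < marital / 5


def test_validator_is_estimator_compatible():
    from sklearn.base import clone

    validator = CertificateValidator(threshold_pct=75.0)
    cloned = clone(validator)
    assert cloned.get_params()["threshold_pct"] == 75.0
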