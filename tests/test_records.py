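import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxcohort.records import (
    Dialect,
    DispensingRecord,
    atc_prefix,
    build_profiles,
    days_supplied,
    is_antidiabetic,
    is_valid_atc,
    read_dispensing_table,
    write_dispensing_table,
)


@pytest.mark.parametrize(
    "code,level,expected",
    [
        ("A10BA02", 1, "A"),
        ("A10BA02", 2, "A10"),
        ("A10BA02", 3, "A10B"),
        ("A10BA02", 4, "A10BA"),
        ("A10BA02", 5, "A10BA02"),
        ("C09AA05", 4, "C09AA"),
    ],
)
def test_atc_prefix_levels(code, level, expected):
    assert atc_prefix(code, level) == expected


def test_atc_prefix_rejects_bad_input():
    with pytest.raises(ValueError):
        atc_prefix("A10BA02", 6)
    with pytest.raises(ValueError):
        atc_prefix("10ABA", 2)


_atc_codes = st.from_regex(r"[A-Z]\d{2}[A-Z]{2}\d{2}", fullmatch=True)


@settings(derandomize=True, max_examples=50)
@given(code=_atc_codes, level=st.integers(2, 4))
def test_atc_prefix_idempotent_under_reprefixing(code, level):
    assert atc_prefix(atc_prefix(code, 5), level) == atc_prefix(code, level)


@pytest.mark.parametrize(
    "code,expected",
    [("A10BA02", True), ("A10BD07", True), ("A10AB05", True), ("C10AA01", False), ("A02BC01", False)],
)
def test_is_antidiabetic(code, expected):
    assert is_antidiabetic(code) is expected


def test_days_supplied_paths(make_record):
    assert days_supplied(make_record(ddd_total=28)) == 28
    # fallback: total active substance divided by the DDD
    rec = make_record(ddd_total=0, n_packages=2)
    assert days_supplied(rec, ddd_per_unit=0.5, units_per_package=28) == 28.0
    # degenerate zero-supply record
    assert days_supplied(make_record(ddd_total=0)) == 0.0


def test_days_supplied_additive_over_packages(make_record):
    one = days_supplied(make_record(ddd_total=0, n_packages=1), ddd_per_unit=1.0, units_per_package=14)
    five = days_supplied(make_record(ddd_total=0, n_packages=5), ddd_per_unit=1.0, units_per_package=14)
    assert five == 5 * one


def test_record_validation(make_record):
    with pytest.raises(ValueError):
        make_record(atc_code="10ABA")
    with pytest.raises(ValueError):
        make_record(gender="unknown")
    with pytest.raises(ValueError):
        make_record(n_packages=0)


def test_read_write_round_trip(tmp_path, make_record):
    records = [make_record(patient_id=f"p{i}", day=i, ddd_total=14.5) for i in range(3)]
    path = tmp_path / "disp.csv"
    write_dispensing_table(records, path)
    back, report = read_dispensing_table(path)
    assert report.n_rejected == 0
    assert [
        (r.patient_id, r.dispense_date, r.atc_code, r.n_packages, r.ddd_total) for r in back
    ] == [(r.patient_id, r.dispense_date, r.atc_code, r.n_packages, r.ddd_total) for r in records]


def test_read_rejects_malformed_rows(tmp_path):
    path = tmp_path / "disp.csv"
    path.write_text(
        "patient_id,birth_date,gender,dispense_date,atc_code,n_packages,ddd_total\n"
        "p1,1960-01-01,male,2019-02-01,A10BA02,1,28\n"
        "p2,1960-01-01,male,2019-02-01,10ABA,1,28\n"
        "p3,1960-01-01,male,not-a-date,A10BA02,1,28\n"
    )
    records, report = read_dispensing_table(path)
    assert len(records) == 1
    assert report.n_rejected == 2
    assert report.n_read == 3


def test_read_empty_file_with_header(tmp_path):
    path = tmp_path / "disp.csv"
    path.write_text("patient_id,birth_date,gender,dispense_date,atc_code,n_packages,ddd_total\n")
    records, report = read_dispensing_table(path)
    assert records == [] and report.n_read == 0


def test_missing_mandatory_column_is_hard_error(tmp_path):
    path = tmp_path / "disp.csv"
    path.write_text("patient_id,gender\np1,male\n")
    with pytest.raises(ValueError, match="missing mandatory column"):
        read_dispensing_table(path)


def test_dialect_column_mapping(tmp_path):
    path = tmp_path / "disp.tsv"
    path.write_text(
        "id\tdob\tsex\tdate\tatc\tnpk\tddd\n"
        "p1\t01/01/1960\tmale\t01/02/2019\tA10BA02\t1\t28\n"
    )
    dialect = Dialect(
        delimiter="\t",
        date_format="%d/%m/%Y",
        column_map={
            "patient_id": "id",
            "birth_date": "dob",
            "gender": "sex",
            "dispense_date": "date",
            "atc_code": "atc",
            "n_packages": "npk",
            "ddd_total": "ddd",
        },
    )
    records, report = read_dispensing_table(path, dialect)
    assert report.n_rejected == 0
    assert records[0].dispense_date == dt.date(2019, 2, 1)


def test_build_profiles_sorts_events(make_record):
    recs = [make_record(day=d) for d in (30, 0, 15)]
    (profile,) = build_profiles(recs)
    days = [e.dispense_date for e in profile.events]
    assert days == sorted(days)
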