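import datetime as dt
import random

import pytest

from rxcohort.cohort import (
    ExclusionReason,
    StudyConfig,
    find_index_event,
    refine_metformin_cohort,
    select_naive_cohort,
)
from rxcohort.records import build_profiles


def _select(records, deaths=()):
    profiles = build_profiles(records, list(deaths))
    return select_naive_cohort(profiles, list(deaths))


def _chronic_metformin(make_record, pid="p1", **kw):
    """Metformin refills 2019 through 2021, >=2 per year."""
    return [
        make_record(patient_id=pid, day=d, **kw)
        for d in range(0, 1030, 60)  # 2019-02-01 .. 2021-11-25
    ]


def test_prevalent_user_excluded_by_washout(make_record):
    recs = [make_record(day=-200)] + _chronic_metformin(make_record)  # 2018 event
    cohort, ledger = _select(recs)
    assert cohort == []
    assert ledger == [("p1", ExclusionReason.WASHOUT)]


def test_sparse_follow_up_excluded(make_record):
    # one dispensation in 2019, none afterwards
    cohort, ledger = _select([make_record(day=0)])
    assert ledger == [("p1", ExclusionReason.FOLLOW_UP_FREQUENCY)]


def test_one_dispensation_per_follow_up_year_excluded(make_record):
    recs = [make_record(day=d) for d in (0, 365, 900, 960)]  # only 1 event in 2020
    _, ledger = _select(recs)
    assert ledger == [("p1", ExclusionReason.FOLLOW_UP_FREQUENCY)]


def test_minor_excluded_by_age(make_record):
    recs = _chronic_metformin(make_record, birth_date=dt.date(2005, 6, 1))
    _, ledger = _select(recs)
    assert ledger == [("p1", ExclusionReason.AGE)]


def test_death_excluded_after_other_criteria(make_record):
    from rxcohort.records import DeathRecord

    recs = _chronic_metformin(make_record)
    _, ledger = _select(recs, [DeathRecord("p1", dt.date(2021, 12, 1))])
    assert ledger == [("p1", ExclusionReason.DEATH)]


def test_late_initiator_excluded_by_index_year(make_record):
    # first AD dispensation in 2020: never an index-year event
    recs = [make_record(day=d) for d in range(400, 1030, 60)]
    _, ledger = _select(recs)
    assert ledger == [("p1", ExclusionReason.INDEX_YEAR)]


def test_included_chronic_initiator(make_record):
    cohort, ledger = _select(_chronic_metformin(make_record))
    assert ledger == []
    (member,) = cohort
    assert member.index_date == dt.date(2019, 2, 1)
    assert member.subgroup == "1"
    # naive property: nothing before the index date
    assert all(e.dispense_date >= member.index_date for e in member.profile.ad_events())


def test_find_index_event_multiplicity(make_record):
    recs = [
        make_record(day=0, atc_code="A10BA02"),
        make_record(day=0, atc_code="A10AE04"),
        make_record(day=120, atc_code="A10BB09"),
    ]
    (profile,) = build_profiles(recs)
    ev = find_index_event(profile, StudyConfig())
    assert ev.index_date == dt.date(2019, 2, 1)
    assert ev.index_drugs == {"A10BA02", "A10AE04"}


def test_find_index_event_requires_index_year(make_record):
    (profile,) = build_profiles([make_record(day=400)])  # 2020 only
    with pytest.raises(ValueError):
        find_index_event(profile, StudyConfig())


@pytest.mark.parametrize("offset,expect_combination", [(2, True), (9, True), (10, False)])
def test_nine_day_window_boundary(make_record, offset, expect_combination):
    recs = _chronic_metformin(make_record) + [
        make_record(day=offset, atc_code="A10BK03")
    ]
    cohort, _ = _select(recs)
    met, combo = refine_metformin_cohort(cohort)
    if expect_combination:
        assert [m.patient_id for m in combo] == ["p1"] and met == []
    else:
        assert [m.patient_id for m in met] == ["p1"] and combo == []


def test_same_day_second_drug_is_combination_initiator(make_record):
    recs = _chronic_metformin(make_record) + [make_record(day=0, atc_code="A10AE04")]
    cohort, _ = _select(recs)
    met, combo = refine_metformin_cohort(cohort)
    assert met == [] and len(combo) == 1


def test_non_metformin_initiator_in_neither_list(make_record):
    recs = _chronic_metformin(make_record, atc_code="A10BB09")
    cohort, _ = _select(recs)
    met, combo = refine_metformin_cohort(cohort)
    assert met == [] and combo == []


@pytest.mark.parametrize(
    "extra_codes,subgroup",
    [((), "1"), (("A10BB09",), "2"), (("A10BB09", "A10BK01", "A10BH01", "A10BJ02", "A10BK03"), "5+")],
)
def test_ad_subgroup_buckets(make_record, extra_codes, subgroup):
    recs = _chronic_metformin(make_record)
    recs += [make_record(day=400 + 30 * i, atc_code=c) for i, c in enumerate(extra_codes)]
    cohort, _ = _select(recs)
    assert cohort[0].subgroup == subgroup


def test_selection_order_independent_and_idempotent(make_record):
    rng = random.Random(1)
    records = []
    for i in range(40):
        pid = f"p{i:02d}"
        if i % 3 == 0:  # prevalent
            records.append(make_record(patient_id=pid, day=-100))
        records += _chronic_metformin(make_record, pid=pid)
    profiles = build_profiles(records)
    cohort_a, ledger_a = select_naive_cohort(profiles, [])
    shuffled = profiles[:]
    rng.shuffle(shuffled)
    cohort_b, ledger_b = select_naive_cohort(shuffled, [])
    assert {m.patient_id for m in cohort_a} == {m.patient_id for m in cohort_b}
    assert sorted(ledger_a) == sorted(ledger_b)
    # idempotence: selecting from the retained profiles changes nothing
    cohort_c, ledger_c = select_naive_cohort([m.profile for m in cohort_a], [])
    assert {m.patient_id for m in cohort_c} == {m.patient_id for m in cohort_a}
    assert ledger_c == []
    # ledger completeness
    assert len(profiles) == len(cohort_a) + len(ledger_a)
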