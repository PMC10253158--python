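import datetime as dt

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from rxcohort.adherence import (
    ADHERENT,
    NON_ADHERENT,
    PARTIALLY_ADHERENT,
    AdherenceConfig,
    AdherenceResult,
    adherence_table,
    compute_cma,
    stratify,
)

BASE = dt.date(2019, 2, 1)
SIMPLE = AdherenceConfig(variant="simple_ratio")


def _window(days):
    return (BASE, BASE + dt.timedelta(days=days))


def test_gapless_refills_give_full_coverage(make_record):
    events = [make_record(day=d, ddd_total=28) for d in range(0, 281, 28)]
    r = compute_cma(events, _window(280))
    assert r.cma_percent == 100.0


def test_single_supply_hand_oracle(make_record):
    # 30 covered days in a 100-day window; the final-day dispensation lies
    # outside the observable window and contributes nothing
    events = [make_record(day=0, ddd_total=30), make_record(day=100, ddd_total=30)]
    r = compute_cma(events, _window(100))
    assert r.cma_percent == 30.0
    assert r.covered_days == 30.0


def test_same_day_supplies_stack_under_carryover(make_record):
    events = [make_record(day=0, ddd_total=30), make_record(day=0, ddd_total=30)]
    assert compute_cma(events, _window(100)).cma_percent == 60.0


def test_carryover_never_exceeds_100(make_record):
    events = [make_record(day=d, ddd_total=90) for d in range(0, 100, 10)]
    r = compute_cma(events, _window(100))
    assert r.cma_percent == 100.0
    assert r.covered_days <= r.window_days


def test_simple_ratio_uncapped_can_exceed_100(make_record):
    events = [make_record(day=0, ddd_total=90), make_record(day=1, ddd_total=90)]
    cfg = AdherenceConfig(variant="simple_ratio", cap_at_100=False)
    assert compute_cma(events, _window(100), cfg).cma_percent == 180.0


def test_simple_ratio_equals_carryover_when_no_overlap(make_record):
    # non-overlapping supplies, none crossing the window end
    events = [make_record(day=d, ddd_total=20) for d in (0, 30, 60)]
    a = compute_cma(events, _window(100)).cma_percent
    b = compute_cma(events, _window(100), SIMPLE).cma_percent
    assert a == b == 60.0


def test_degenerate_windows_rejected(make_record):
    with pytest.raises(ValueError):
        compute_cma([make_record(ddd_total=28)], (BASE, BASE))


@settings(derandomize=True, max_examples=60, suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(
    days=st.lists(st.tuples(st.integers(0, 360), st.floats(1, 60)), min_size=1, max_size=12),
    shift=st.integers(-400, 400),
)
def test_translation_and_permutation_invariance(make_record, days, shift):
    events = [make_record(day=d, ddd_total=s) for d, s in days]
    base = compute_cma(events, _window(365)).cma_percent
    shifted = [make_record(day=d + shift, ddd_total=s, base=BASE) for d, s in days]
    w = (BASE + dt.timedelta(days=shift), BASE + dt.timedelta(days=365 + shift))
    assert compute_cma(shifted, w).cma_percent == pytest.approx(base, abs=1e-12)
    perm = compute_cma(list(reversed(events)), _window(365)).cma_percent
    assert perm == pytest.approx(base, abs=1e-12)


@settings(derandomize=True, max_examples=40, suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(
    days=st.lists(st.tuples(st.integers(0, 360), st.floats(1, 60)), min_size=1, max_size=8),
    bump=st.floats(0.1, 40),
    which=st.integers(0, 7),
)
def test_carryover_monotone_in_supply(make_record, days, bump, which):
    events = [make_record(day=d, ddd_total=s) for d, s in days]
    base = compute_cma(events, _window(365)).cma_percent
    i = which % len(days)
    bumped = [
        make_record(day=d, ddd_total=s + (bump if j == i else 0))
        for j, (d, s) in enumerate(days)
    ]
    assert compute_cma(bumped, _window(365)).cma_percent >= base - 1e-12


@pytest.mark.parametrize(
    "cma,stratum",
    [
        (80.0, ADHERENT),
        (95.0, ADHERENT),
        (79.99, PARTIALLY_ADHERENT),
        (40.0, PARTIALLY_ADHERENT),
        (39.99, NON_ADHERENT),
        (0.0, NON_ADHERENT),
    ],
)
def test_stratification_boundaries(cma, stratum):
    assert stratify(cma) == stratum


def _result(pid, cma):
    return AdherenceResult(pid, cma, _window(100), cma, 100.0, stratify(cma))


def test_adherence_table_median_and_cross_subgroup_mean():
    results, subgroups, genders = [], {}, {}
    # subgroup 1 median 46.0; subgroups 2..5+ medians 60, 62, 63, 63
    planted = {"1": [44, 46, 48], "2": [40, 60, 84], "3": [41, 62, 82], "4": [52, 63, 83], "5+": [49, 63, 75]}
    for sg, values in planted.items():
        for i, v in enumerate(values):
            pid = f"{sg}-{i}"
            results.append(_result(pid, float(v)))
            subgroups[pid] = sg
            genders[pid] = "male" if i % 2 == 0 else "female"
    df = adherence_table(results, subgroups, genders)
    assert list(df["median"]) == [46.0, 60.0, 62.0, 63.0, 63.0]
    assert df.attrs["non_monotherapy_mean_median"] == 62.0
    for _, row in df.iterrows():
        assert row.pct_adherent + row.pct_partially_adherent + row.pct_non_adherent == pytest.approx(100.0, abs=0.2)


def test_adherence_table_quartile_convention():
    results = [_result(f"p{i}", v) for i, v in enumerate([60.0, 62.0, 63.0, 63.0])]
    df = adherence_table(results, {r.patient_id: "1" for r in results})
    assert df.iloc[0]["median"] == 62.5  # linear interpolation between 62 and 63


def test_single_member_subgroup_degenerate_iqr():
    df = adherence_table([_result("p", 55.0)], {"p": "1"})
    assert df.iloc[0]["median"] == 55.0
    assert df.iloc[0]["q1"] == 55.0 and df.iloc[0]["q3"] == 55.0
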