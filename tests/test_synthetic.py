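import datetime as dt
from collections import Counter

import numpy as np
import pytest

from rxcohort.adherence import compute_cma
from rxcohort.cohort import refine_metformin_cohort, select_naive_cohort
from rxcohort.comorbidity import assign_comorbidities
from rxcohort.records import build_profiles
from rxcohort.synthetic import (
    ARCHETYPES,
    GeneratorConfig,
    generate_population,
    make_fixture,
)
from rxcohort.trajectory import TherapyTimeline, classify_first_intensification


def test_empty_population():
    cfg = GeneratorConfig(seed=1, n_patients=0)
    assert generate_population(cfg) == ([], [], [])


def test_determinism_same_seed():
    cfg = GeneratorConfig(seed=123, n_patients=50)
    a = generate_population(cfg)
    b = generate_population(GeneratorConfig(seed=123, n_patients=50))
    assert a == b
    c = generate_population(GeneratorConfig(seed=124, n_patients=50))
    assert c != a


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(archetype_mix={"naive_monotherapy": 0.5})  # sums to 0.5
    with pytest.raises(ValueError):
        GeneratorConfig(target_cma={"naive_monotherapy": 0.0})
    with pytest.raises(ValueError):
        GeneratorConfig(date_window=(dt.date(2019, 1, 1), dt.date(2019, 12, 31)))


def test_exact_cma_at_zero_jitter():
    """Refill gaps of supply/CMA make the realized CMA equal the target."""
    cfg = GeneratorConfig(
        seed=7,
        n_patients=30,
        gap_jitter_days=0,
        archetype_mix={"naive_monotherapy": 1.0},
        target_cma={"naive_monotherapy": 0.8},
        ad_class_weights={"A10BA02": 1.0},
    )
    records, deaths, _ = generate_population(cfg)
    cohort, ledger = select_naive_cohort(build_profiles(records, deaths), deaths)
    assert ledger == []
    for m in cohort:
        events = [
            e for e in m.profile.ad_events() if m.index_date <= e.dispense_date <= m.follow_up_end
        ]
        assert compute_cma(events, (m.index_date, m.follow_up_end)).cma_percent == 80.0


def test_archetype_contract_with_selection():
    """Prevalent/sporadic/decedent are always excluded; naïve archetypes are
    always retained; planted combination initiators are detected."""
    cfg = GeneratorConfig(seed=11, n_patients=400, gap_jitter_days=0)
    records, deaths, labels = generate_population(cfg)
    cohort, ledger = select_naive_cohort(build_profiles(records, deaths), deaths)
    met, combo = refine_metformin_cohort(cohort)
    cohort_ids = {m.patient_id for m in cohort}
    combo_ids = {m.patient_id for m in combo}
    for label in labels:
        if label.archetype in ("prevalent_user", "sporadic_user", "decedent"):
            assert label.patient_id not in cohort_ids, label
        else:
            assert label.patient_id in cohort_ids, label
        if label.archetype == "naive_combination":
            assert label.patient_id in combo_ids, label


def test_trajectory_round_trip_at_zero_jitter():
    cfg = GeneratorConfig(seed=5, n_patients=400, gap_jitter_days=0)
    records, deaths, labels = generate_population(cfg)
    cohort, _ = select_naive_cohort(build_profiles(records, deaths), deaths)
    met, _ = refine_metformin_cohort(cohort)
    got = {
        m.patient_id: classify_first_intensification(TherapyTimeline.from_member(m)).category
        for m in met
    }
    want = {
        "naive_add_on": "add_on",
        "naive_switch": "switch",
        "naive_switch_discontinue": "switch_then_discontinue",
    }
    checked = 0
    for label in labels:
        if label.archetype in want and label.patient_id in got:
            assert got[label.patient_id] == want[label.archetype], label
            checked += 1
    assert checked > 0


def test_comorbidity_prevalence_within_three_standard_errors():
    cfg = GeneratorConfig(seed=3, n_patients=1000)
    records, _, labels = generate_population(cfg)
    profiles = build_profiles(records)
    flags = Counter()
    for p in profiles:
        cm = assign_comorbidities(p)
        for name, v in cm.flags.items():
            flags[name] += bool(v)
    n = len(profiles)
    for name, p_true in cfg.comorbidity_prevalence.items():
        if p_true in (0.0, 1.0):
            assert flags[name] == (n if p_true == 1.0 else 0)
            continue
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(flags[name] / n - p_true) <= 3 * se, name


@pytest.mark.parametrize(
    "name,n_patients",
    [("intensification", 289), ("subgroups", 1361), ("nine_day", 1464), ("enrollment", 1927)],
)
def test_fixture_sizes(name, n_patients):
    _, _, labels = make_fixture(name)
    assert len(labels) == n_patients


def test_fixture_aliases_and_unknown_name():
    assert make_fixture("table1")[2] == make_fixture("enrollment")[2]
    with pytest.raises(ValueError):
        make_fixture("nope")


def test_intensification_fixture_planted_split():
    _, _, labels = make_fixture("intensification")
    counts = Counter(l.archetype for l in labels)
    assert counts == {"naive_add_on": 189, "naive_switch": 92, "naive_switch_discontinue": 8}
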