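"""Synthetic pharmacy-claims generator.

Two layers:

* :func:`generate_population` draws a population of patients from a mix of
  behavioural archetypes (prevalent user, naïve monotherapy initiator, naïve
  first-line combination initiator, add-on, switch, switch-then-discontinue,
  sporadic user, decedent) over a four-year dispensing window.  Adherence
  behaviour is modelled through refill gaps — the observable in dispensing
  data — so that the expected continuous medication availability of an
  archetype equals its configured target: the gap between consecutive
  dispensations is days-of-supply / target CMA, plus optional jitter.
  Comorbidity co-dispensations are Bernoulli draws per Rx-Risk condition.
  Every patient carries a ground-truth :class:`ArchetypeLabel` so that
  pipeline round-trip tests can verify label recovery.

* :func:`make_fixture` builds fully deterministic populations (no sampling)
  whose planted marginal counts equal published study tables, for worked
  examples and exact end-to-end checks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .comorbidity import DEFAULT_RX_RISK
from .records import DeathRecord, DispensingRecord
from .reporting import round_half_up

__all__ = [
    "ARCHETYPES",
    "GeneratorConfig",
    "ArchetypeLabel",
    "generate_population",
    "make_fixture",
    "FIXTURE_NAMES",
]

ARCHETYPES = (
    "prevalent_user",
    "naive_monotherapy",
    "naive_combination",
    "naive_add_on",
    "naive_switch",
    "naive_switch_discontinue",
    "sporadic_user",
    "decedent",
)

#: Index-drug distribution among single-index-drug initiators (percent):
#: metformin dominates first-line therapy; sulfonylureas, insulins and the
#: newer classes (DPP-4i, SGLT-2i, GLP-1RAs) make up the remainder.
DEFAULT_INDEX_DRUG_WEIGHTS = {
    "A10BA02": 83.2,  # metformin
    "A10BB09": 4.7,   # gliclazide (sulfonylurea)
    "A10AB05": 4.2,   # insulin aspart (fast-acting)
    "A10BH01": 1.7,   # sitagliptin (DPP-4i)
    "A10AE04": 1.5,   # insulin glargine (long-acting)
    "A10BX02": 1.3,   # repaglinide
    "A10AC01": 1.3,   # insulin human (intermediate)
    "A10BK01": 1.2,   # dapagliflozin (SGLT-2i)
    "A10BG03": 0.5,   # pioglitazone
    "A10BJ02": 0.4,   # liraglutide (GLP-1RA)
}

#: Non-metformin second-line products used for planted therapy changes.
SECOND_LINE_POOL = ("A10BK01", "A10BK03", "A10BB09", "A10BH01", "A10BJ02")

#: Comorbidity prevalence per Rx-Risk condition (probability of >=1
#: qualifying dispensation over the study window), metformin-monotherapy
#: stratum of the emulated population.
DEFAULT_COMORBIDITY_PREVALENCE = {
    "cardiovascular/cerebrovascular and heart diseases": 1.0,
    "hypertension": 1.0,
    "hyperlipidemia": 0.625,
    "hyperuricemia/gout": 0.18,
    "infectious diseases": 0.838,
    "acid related disorders": 0.571,
    "inflammatory/rheumatic disorders": 0.566,
    "corticosteroid-responsive diseases": 0.407,
    "nutrition-related diseases": 0.365,
    "pain, including migraine": 0.299,
    "depression and other mental disorders": 0.214,
    "chronic obstructive airways diseases": 0.199,
    "gastrointestinal disorders and nausea": 0.199,
    "anemia": 0.177,
    "genito-urinary diseases": 0.174,
    "thyroid disorders": 0.125,
    "respiratory diseases": 0.102,
    "epilepsy": 0.097,
    "dermatological diseases": 0.073,
    "eye disorders, including glaucoma": 0.071,
    "psychotic illnesses": 0.033,
}

DEFAULT_ARCHETYPE_MIX = {
    "prevalent_user": 0.45,
    "naive_monotherapy": 0.25,
    "naive_combination": 0.02,
    "naive_add_on": 0.07,
    "naive_switch": 0.04,
    "naive_switch_discontinue": 0.01,
    "sporadic_user": 0.12,
    "decedent": 0.04,
}

DEFAULT_TARGET_CMA = {
    "prevalent_user": 0.80,
    "naive_monotherapy": 0.46,
    "naive_combination": 0.62,
    "naive_add_on": 0.62,
    "naive_switch": 0.62,
    "naive_switch_discontinue": 0.63,
    "sporadic_user": 0.62,
    "decedent": 0.80,
}

METFORMIN = "A10BA02"


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_patients: int = 1000
    date_window: tuple[dt.date, dt.date] = (dt.date(2018, 1, 1), dt.date(2021, 12, 31))
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_MIX)
    )
    target_cma: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TARGET_CMA))
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    ad_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEX_DRUG_WEIGHTS)
    )
    package_ddd: float = 28.0  # days of supply per dispensation
    gap_jitter_days: int = 2

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype mix must sum to 1, got {total}")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        for name, c in self.target_cma.items():
            if not (0 < c <= 1.5):
                raise ValueError(f"target_cma[{name!r}] must be in (0, 1.5], got {c}")
        for name, p in self.comorbidity_prevalence.items():
            if not (0 <= p <= 1):
                raise ValueError(f"prevalence[{name!r}] must be in [0, 1]")
        start, end = self.date_window
        if end.year - start.year < 1:
            raise ValueError("date window must span at least two calendar years")
        if self.package_ddd <= 0:
            raise ValueError("package_ddd must be positive")
        if self.gap_jitter_days < 0:
            raise ValueError("gap_jitter_days must be >= 0")

    @property
    def washout_year(self) -> int:
        return self.date_window[0].year

    @property
    def index_year(self) -> int:
        return self.date_window[0].year + 1


@dataclass(frozen=True)
class ArchetypeLabel:
    patient_id: str
    archetype: str
    planted_index_date: dt.date | None = None
    planted_second_ad: str | None = None


# ---------------------------------------------------------------------------
# Random population
# ---------------------------------------------------------------------------


def _refill_dates(
    start: dt.date,
    end: dt.date,
    gap: int,
    rng: np.random.Generator | None,
    jitter: int,
) -> list[dt.date]:
    """Dispensation dates from ``start`` while they stay on or before ``end``."""
    dates = []
    d = start
    while d <= end:
        dates.append(d)
        step = gap
        if rng is not None and jitter > 0:
            step = max(1, gap + int(rng.integers(-jitter, jitter + 1)))
        d = d + dt.timedelta(days=step)
    return dates


def _gap_for(cma: float, supply: float) -> int:
    return max(1, round(supply / cma))


def generate_population(
    config: GeneratorConfig,
) -> tuple[list[DispensingRecord], list[DeathRecord], list[ArchetypeLabel]]:
    """Draw a synthetic dispensing stream, death registry and ground truth.

    Deterministic for a fixed config (single seeded random stream; patients
    are emitted in generation order).
    """
    rng = np.random.default_rng(config.seed)
    start, end = config.date_window
    index_year = config.index_year
    supply = config.package_ddd
    jitter = config.gap_jitter_days

    mix_names = [a for a in ARCHETYPES if config.archetype_mix.get(a, 0) > 0]
    mix_probs = np.array([config.archetype_mix[a] for a in mix_names], dtype=float)
    mix_probs = mix_probs / mix_probs.sum()

    index_codes = list(config.ad_class_weights)
    index_probs = np.array(list(config.ad_class_weights.values()), dtype=float)
    index_probs = index_probs / index_probs.sum()

    records: list[DispensingRecord] = []
    deaths: list[DeathRecord] = []
    labels: list[ArchetypeLabel] = []

    for i in range(config.n_patients):
        pid = f"S{i:06d}"
        archetype = mix_names[int(rng.choice(len(mix_names), p=mix_probs))]
        gender = "male" if rng.random() < 0.5 else "female"
        birth = dt.date(
            int(rng.integers(1935, 1986)),
            int(rng.integers(1, 13)),
            int(rng.integers(1, 29)),
        )
        cma = config.target_cma.get(archetype, 0.8)
        gap = _gap_for(cma, supply)

        def disp(date: dt.date, code: str) -> DispensingRecord:
            return DispensingRecord(
                patient_id=pid,
                birth_date=birth,
                gender=gender,
                dispense_date=date,
                atc_code=code,
                n_packages=1,
                ddd_total=supply,
            )

        index_date: dt.date | None = None
        second_ad: str | None = None
        schedule_end = end - dt.timedelta(days=7)

        if archetype == "prevalent_user":
            first = start + dt.timedelta(days=int(rng.integers(0, 330)))
            code = index_codes[int(rng.choice(len(index_codes), p=index_probs))]
            for d in _refill_dates(first, schedule_end, gap, rng, jitter):
                records.append(disp(d, code))

        elif archetype == "naive_monotherapy":
            index_date = dt.date(index_year, 1, 1) + dt.timedelta(
                days=int(rng.integers(0, 180))
            )
            code = index_codes[int(rng.choice(len(index_codes), p=index_probs))]
            for d in _refill_dates(index_date, schedule_end, gap, rng, jitter):
                records.append(disp(d, code))

        elif archetype == "naive_combination":
            index_date = dt.date(index_year, 1, 1) + dt.timedelta(
                days=int(rng.integers(0, 180))
            )
            second_ad = SECOND_LINE_POOL[int(rng.integers(0, len(SECOND_LINE_POOL)))]
            second_start = index_date + dt.timedelta(days=int(rng.integers(2, 10)))
            for d in _refill_dates(index_date, schedule_end, gap, rng, jitter):
                records.append(disp(d, METFORMIN))
            for d in _refill_dates(second_start, schedule_end, gap, rng, jitter):
                records.append(disp(d, second_ad))

        elif archetype in ("naive_add_on", "naive_switch", "naive_switch_discontinue"):
            index_date = dt.date(index_year, 1, 1) + dt.timedelta(
                days=int(rng.integers(0, 180))
            )
            second_ad = SECOND_LINE_POOL[int(rng.integers(0, len(SECOND_LINE_POOL)))]
            if archetype == "naive_add_on":
                # after the change the two products alternate on one pooled
                # refill schedule, so availability stays at the target CMA
                change = index_date + dt.timedelta(days=int(rng.integers(270, 451)))
                take_second = True
                for d in _refill_dates(index_date, schedule_end, gap, rng, jitter):
                    if d < change:
                        records.append(disp(d, METFORMIN))
                    else:
                        records.append(disp(d, second_ad if take_second else METFORMIN))
                        take_second = not take_second
            elif archetype == "naive_switch":
                change = index_date + dt.timedelta(days=int(rng.integers(270, 451)))
                for d in _refill_dates(
                    index_date, change - dt.timedelta(days=1), gap, rng, jitter
                ):
                    records.append(disp(d, METFORMIN))
                for d in _refill_dates(change, schedule_end, gap, rng, jitter):
                    records.append(disp(d, second_ad))
            else:  # switch then discontinue: change early in the final year,
                # a couple of refills, then nothing for the rest of the window
                final_year = end.year
                change = dt.date(final_year, 1, 5) + dt.timedelta(
                    days=int(rng.integers(0, 20))
                )
                for d in _refill_dates(
                    index_date, dt.date(final_year - 1, 12, 20), gap, rng, jitter
                ):
                    records.append(disp(d, METFORMIN))
                records.append(disp(change, second_ad))
                records.append(disp(change + dt.timedelta(days=gap), second_ad))

        elif archetype == "sporadic_user":
            index_date = dt.date(index_year, 1, 1) + dt.timedelta(
                days=int(rng.integers(0, 330))
            )
            code = index_codes[int(rng.choice(len(index_codes), p=index_probs))]
            records.append(disp(index_date, code))

        elif archetype == "decedent":
            index_date = dt.date(index_year, 1, 1) + dt.timedelta(
                days=int(rng.integers(0, 180))
            )
            death = end - dt.timedelta(days=int(rng.integers(10, 80)))
            for d in _refill_dates(
                index_date, death - dt.timedelta(days=10), gap, rng, jitter
            ):
                records.append(disp(d, METFORMIN))
            deaths.append(DeathRecord(pid, death))

        # comorbidity co-dispensations, Bernoulli per Rx-Risk condition
        for cond in DEFAULT_RX_RISK.conditions:
            p = config.comorbidity_prevalence.get(cond.name, 0.0)
            if p <= 0 or rng.random() >= p:
                continue
            codes = sorted(cond.atcl2_codes)
            for _ in range(int(rng.integers(1, 4))):
                l2 = codes[int(rng.integers(0, len(codes)))]
                offset = int(rng.integers(0, (end - start).days + 1))
                records.append(disp(start + dt.timedelta(days=offset), f"{l2}AA01"))

        labels.append(ArchetypeLabel(pid, archetype, index_date, second_ad))

    return records, deaths, labels


# ---------------------------------------------------------------------------
# Deterministic fixtures replanting published marginal counts
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("enrollment", "subgroups", "intensification", "nine_day")
_FIXTURE_ALIASES = {"table1": "enrollment", "table2": "subgroups"}

#: Planted per-subgroup sizes of the metformin study cohort.
SUBGROUP_SIZES = {"1": 931, "2": 289, "3": 92, "4": 31, "5+": 18}
SUBGROUP_MALES = {"1": 488, "2": 176, "3": 54, "4": 18, "5+": 10}

#: Planted two-AD trajectory split: add-on / switch / switch-then-discontinue.
INTENSIFICATION_SPLIT = (189, 92, 8)

#: Switch-then-discontinue drug split: SGLT-2i, sulfonylureas, GLP-1RAs.
DISCONTINUE_DRUGS = ("A10BK01",) * 5 + ("A10BB09",) * 2 + ("A10BJ02",)

#: Comorbidity prevalence (%) per condition and subgroup used to plant the
#: comorbidity co-dispensations of the 'subgroups' fixture.
SUBGROUP_COMORBIDITY_PCT = {
    "cardiovascular/cerebrovascular and heart diseases": (100.0, 100.0, 100.0, 100.0, 100.0),
    "hypertension": (100.0, 100.0, 94.6, 100.0, 77.8),
    "hyperlipidemia": (62.5, 69.6, 80.4, 64.5, 61.1),
    "hyperuricemia/gout": (18.0, 20.4, 13.0, 16.1, 11.1),
    "infectious diseases": (83.8, 87.5, 88.0, 100.0, 100.0),
    "acid related disorders": (57.1, 60.2, 54.3, 67.7, 77.8),
    "inflammatory/rheumatic disorders": (56.6, 52.6, 43.5, 48.4, 55.6),
    "corticosteroid-responsive diseases": (40.7, 45.7, 33.7, 32.3, 44.4),
    "nutrition-related diseases": (36.5, 32.9, 29.3, 29.0, 33.3),
    "pain, including migraine": (29.9, 29.4, 23.9, 41.9, 33.3),
    "depression and other mental disorders": (21.4, 21.1, 20.7, 19.4, 27.8),
    "chronic obstructive airways diseases": (19.9, 20.8, 23.9, 22.6, 61.1),
    "gastrointestinal disorders and nausea": (19.9, 19.4, 18.5, 22.6, 50.0),
    "anemia": (17.7, 17.3, 9.8, 6.5, 11.1),
    "genito-urinary diseases": (17.4, 19.0, 16.3, 6.5, 11.1),
    "thyroid disorders": (12.5, 13.5, 7.6, 9.7, 11.1),
    "respiratory diseases": (10.2, 9.7, 10.9, 3.2, 11.1),
    "epilepsy": (9.7, 13.5, 5.4, 29.0, 27.8),
    "dermatological diseases": (7.3, 8.3, 9.8, 0.0, 22.2),
    "eye disorders, including glaucoma": (7.1, 6.2, 6.5, 12.9, 11.1),
    "psychotic illnesses": (3.3, 5.5, 3.3, 6.5, 11.1),
}

#: Index-drug counts among the 1759 single-index-drug members of the
#: enrollment fixture (sums to 1759; metformin share 1464).
ENROLLMENT_INDEX_DRUGS = (
    ("A10BA02", 1464),
    ("A10BB09", 83),
    ("A10AB05", 74),
    ("A10BH01", 30),
    ("A10AE04", 26),
    ("A10BX02", 23),
    ("A10AC01", 22),
    ("A10BK01", 21),
    ("A10BG03", 9),
    ("A10BJ02", 7),
)
ENROLLMENT_TOTAL = 1927
ENROLLMENT_MALES = 1090
ENROLLMENT_MULTI_INDEX = ((2, 152), (3, 13), (4, 3))

_EXTRA_AD_CODES = ("A10BK01", "A10BB09", "A10BH01", "A10BJ02", "A10BK03", "A10BG03")

_SUPPLY = 28.0
_GAP = 35  # 28-day supply every 35 days -> CMA 80%
_STUDY_END = dt.date(2021, 12, 31)
_SCHEDULE_END = dt.date(2021, 12, 15)


class _FixtureBuilder:
    def __init__(self) -> None:
        self.records: list[DispensingRecord] = []
        self.deaths: list[DeathRecord] = []
        self.labels: list[ArchetypeLabel] = []
        self._n = 0

    def new_patient(self, gender: str) -> tuple[str, dt.date]:
        pid = f"F{self._n:05d}"
        birth = dt.date(1940 + self._n % 40, 1 + self._n % 12, 1 + self._n % 28)
        self._n += 1
        return pid, birth

    def dispense(self, pid, birth, gender, date, code, ddd=_SUPPLY) -> None:
        self.records.append(
            DispensingRecord(
                patient_id=pid,
                birth_date=birth,
                gender=gender,
                dispense_date=date,
                atc_code=code,
                n_packages=1,
                ddd_total=ddd,
            )
        )

    def refills(self, pid, birth, gender, start, end, code, gap=_GAP) -> None:
        for d in _refill_dates(start, end, gap, None, 0):
            self.dispense(pid, birth, gender, d, code)


def _index_date_for(i: int) -> dt.date:
    # stagger index dates over the first half of the index year
    return dt.date(2019, 1, 10) + dt.timedelta(days=(i * 7) % 160)


def _build_cohort_patient(
    b: _FixtureBuilder,
    gender: str,
    i: int,
    trajectory: str,
    extra_ads: int = 0,
) -> ArchetypeLabel:
    """One metformin initiator passing every inclusion filter by construction.

    ``trajectory`` in {monotherapy, add_on, switch, switch_discontinue};
    ``extra_ads`` additional distinct products start late in follow-up so the
    distinct-AD count reaches 2 + extra_ads without changing the first-change
    classification.
    """
    pid, birth = b.new_patient(gender)
    index = _index_date_for(i)
    second = None

    if trajectory == "monotherapy":
        b.refills(pid, birth, gender, index, _SCHEDULE_END, METFORMIN)
        archetype = "naive_monotherapy"
    elif trajectory == "add_on":
        second = _EXTRA_AD_CODES[i % 4]
        change = dt.date(2020, 3, 1) + dt.timedelta(days=(i * 3) % 90)
        b.refills(pid, birth, gender, index, _SCHEDULE_END, METFORMIN)
        b.refills(pid, birth, gender, change, _SCHEDULE_END, second)
        archetype = "naive_add_on"
    elif trajectory == "switch":
        second = _EXTRA_AD_CODES[i % 4]
        change = dt.date(2020, 7, 1) + dt.timedelta(days=(i * 3) % 60)
        b.refills(pid, birth, gender, index, change - dt.timedelta(days=20), METFORMIN)
        b.refills(pid, birth, gender, change, _SCHEDULE_END, second)
        archetype = "naive_switch"
    elif trajectory == "switch_discontinue":
        second = DISCONTINUE_DRUGS[i % len(DISCONTINUE_DRUGS)]
        change = dt.date(2021, 1, 10) + dt.timedelta(days=i % 10)
        b.refills(pid, birth, gender, index, dt.date(2020, 12, 20), METFORMIN)
        b.dispense(pid, birth, gender, change, second)
        b.dispense(pid, birth, gender, change + dt.timedelta(days=_GAP), second)
        archetype = "naive_switch_discontinue"
    else:
        raise ValueError(trajectory)

    used = {METFORMIN} | ({second} if second else set())
    pool = [c for c in _EXTRA_AD_CODES if c not in used]
    for k in range(extra_ads):
        extra = pool[k % len(pool)]
        extra_start = dt.date(2021, 3, 1) + dt.timedelta(days=30 * k + i % 20)
        if trajectory == "switch_discontinue":
            # keep the planted discontinuation intact: extra codes must not
            # extend the supply tail, so they land before the switch
            extra_start = dt.date(2020, 6, 1) + dt.timedelta(days=30 * k)
        b.dispense(pid, birth, gender, extra_start, extra)
        used.add(extra)

    return ArchetypeLabel(pid, archetype, index, second)


def _plant_comorbidities(b: _FixtureBuilder, members_by_subgroup: dict[str, list]) -> None:
    """Give the first round(p% * n) members of each subgroup one qualifying
    dispensation per condition, reproducing the planted prevalence exactly
    under half-up rounding."""
    for cond in DEFAULT_RX_RISK.conditions:
        pcts = SUBGROUP_COMORBIDITY_PCT[cond.name]
        code = sorted(cond.atcl2_codes)[0] + "AA01"
        for sg_idx, sg in enumerate(("1", "2", "3", "4", "5+")):
            members = members_by_subgroup.get(sg, [])
            n_hit = int(round_half_up(pcts[sg_idx] / 100.0 * len(members), 0))
            for pid, birth, gender in members[:n_hit]:
                b.dispense(
                    pid, birth, gender, dt.date(2020, 5, 15), code, ddd=30.0
                )


def _build_subgroups(b: _FixtureBuilder, with_comorbidities: bool = True) -> None:
    """The 1361-patient metformin study cohort with planted subgroup sizes,
    gender splits, the two-AD trajectory split and comorbidity prevalences."""
    members_by_subgroup: dict[str, list] = {sg: [] for sg in SUBGROUP_SIZES}

    def gender_seq(sg: str, i: int) -> str:
        return "male" if i < SUBGROUP_MALES[sg] else "female"

    # subgroup 1: metformin monotherapy
    for i in range(SUBGROUP_SIZES["1"]):
        g = gender_seq("1", i)
        label = _build_cohort_patient(b, g, i, "monotherapy")
        members_by_subgroup["1"].append(_member_key(b, label))
        b.labels.append(label)

    # subgroup 2: the intensification split 189 add-on / 92 switch / 8 discontinue
    n_add, n_switch, n_disc = INTENSIFICATION_SPLIT
    plan = ["add_on"] * n_add + ["switch"] * n_switch + ["switch_discontinue"] * n_disc
    for i, trajectory in enumerate(plan):
        g = gender_seq("2", i)
        label = _build_cohort_patient(b, g, i, trajectory)
        members_by_subgroup["2"].append(_member_key(b, label))
        b.labels.append(label)

    # subgroups 3-5+: add-on patients with extra distinct products
    for sg, extra in (("3", 1), ("4", 2), ("5+", 3)):
        for i in range(SUBGROUP_SIZES[sg]):
            g = gender_seq(sg, i)
            label = _build_cohort_patient(b, g, i, "add_on", extra_ads=extra)
            members_by_subgroup[sg].append(_member_key(b, label))
            b.labels.append(label)

    if with_comorbidities:
        _plant_comorbidities(b, members_by_subgroup)


def _member_key(b: _FixtureBuilder, label: ArchetypeLabel):
    rec = next(r for r in reversed(b.records) if r.patient_id == label.patient_id)
    return (rec.patient_id, rec.birth_date, rec.gender)


def _build_nine_day(b: _FixtureBuilder) -> None:
    """The subgroups cohort plus 103 first-line combination initiators whose
    second distinct product starts 2-9 days after index."""
    _build_subgroups(b, with_comorbidities=False)
    for i in range(103):
        gender = "male" if i % 2 == 0 else "female"
        pid, birth = b.new_patient(gender)
        index = _index_date_for(i)
        second = SECOND_LINE_POOL[i % len(SECOND_LINE_POOL)]
        offset = 2 + i % 8  # days 2..9 inclusive
        b.refills(pid, birth, gender, index, _SCHEDULE_END, METFORMIN)
        b.refills(pid, birth, gender, index + dt.timedelta(days=offset), _SCHEDULE_END, second)
        b.labels.append(ArchetypeLabel(pid, "naive_combination", index, second))


def _build_enrollment(b: _FixtureBuilder) -> None:
    """The 1927-patient enrolled population: planted gender and index-drug
    multiplicity marginals, everyone passing the inclusion cascade."""
    i_global = 0

    def next_gender() -> str:
        nonlocal i_global
        g = "male" if i_global < ENROLLMENT_MALES else "female"
        i_global += 1
        return g

    # 1759 single-index-drug patients with the planted drug distribution
    for code, count in ENROLLMENT_INDEX_DRUGS:
        for i in range(count):
            gender = next_gender()
            pid, birth = b.new_patient(gender)
            index = _index_date_for(i)
            b.refills(pid, birth, gender, index, _SCHEDULE_END, code)
            b.labels.append(ArchetypeLabel(pid, "naive_monotherapy", index, None))

    # multi-index-drug starters: several distinct products on the index date
    multi_pool = (METFORMIN, "A10AE04", "A10BB09", "A10AB05")
    for n_drugs, count in ENROLLMENT_MULTI_INDEX:
        for i in range(count):
            gender = next_gender()
            pid, birth = b.new_patient(gender)
            index = _index_date_for(i)
            for code in multi_pool[:n_drugs]:
                b.dispense(pid, birth, gender, index, code)
            b.refills(
                pid,
                birth,
                gender,
                index + dt.timedelta(days=_GAP),
                _SCHEDULE_END,
                multi_pool[0],
            )
            b.labels.append(ArchetypeLabel(pid, "naive_combination", index, multi_pool[1]))

    assert i_global == ENROLLMENT_TOTAL


def make_fixture(
    name: str, seed: int = 0
) -> tuple[list[DispensingRecord], list[DeathRecord], list[ArchetypeLabel]]:
    """Build a registered deterministic fixture.

    Fixtures are constructed without sampling (``seed`` is accepted for API
    symmetry with :func:`generate_population` and does not change the
    output), so counts derived from them are exact.

    Registered names: ``enrollment`` (the 1927-patient enrolled population),
    ``subgroups`` (the 1361-patient metformin cohort with subgroup sizes
    931/289/92/31/18), ``intensification`` (the 289-patient two-AD subgroup
    planted 189 add-on / 92 switch / 8 switch-then-discontinue) and
    ``nine_day`` (subgroups plus 103 planted first-line combination
    initiators).  ``table1``/``table2`` are accepted as aliases of
    enrollment/subgroups.
    """
    name = _FIXTURE_ALIASES.get(name, name)
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    b = _FixtureBuilder()
    if name == "intensification":
        n_add, n_switch, n_disc = INTENSIFICATION_SPLIT
        plan = ["add_on"] * n_add + ["switch"] * n_switch + ["switch_discontinue"] * n_disc
        for i, trajectory in enumerate(plan):
            gender = "male" if i < SUBGROUP_MALES["2"] else "female"
            b.labels.append(_build_cohort_patient(b, gender, i, trajectory))
    elif name == "subgroups":
        _build_subgroups(b)
    elif name == "nine_day":
        _build_nine_day(b)
    elif name == "enrollment":
        _build_enrollment(b)
    return b.records, b.deaths, b.labels
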