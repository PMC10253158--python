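"""New-user (treatment-naïve) cohort selection from dispensing timelines.

The selection mirrors the standard new-user design on administrative
dispensing data: a wash-out year free of the study drug class qualifies a
patient as naïve; the index date is the first qualifying dispensation in the
index year; dispensing-frequency filters restrict the cohort to chronically
treated patients; deaths during the study window are excluded.  A metformin
refinement then removes first-line combination initiators (a second distinct
antidiabetic dispensed within a short window after index) and stratifies the
remaining initiators by the number of distinct antidiabetics seen during
follow-up.

Exclusion reasons are assessed in a fixed order (age, wash-out, index-year,
follow-up frequency, death); the first failed criterion is recorded, so the
exclusion ledger partitions the input exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum

from .drugs import METFORMIN_CONTAINING
from .records import DeathRecord, PatientProfile

__all__ = [
    "StudyConfig",
    "IndexEvent",
    "CohortMember",
    "ExclusionReason",
    "select_naive_cohort",
    "find_index_event",
    "refine_metformin_cohort",
    "assign_ad_subgroup",
    "SUBGROUP_LABELS",
]

SUBGROUP_LABELS = ("1", "2", "3", "4", "5+")


@dataclass(frozen=True)
class StudyConfig:
    """Study-window dates, thresholds and rule options.

    Defaults encode a 4-year observation window (2018-2021) with calendar
    2018 as wash-out, 2019 as index year, age measured at the end of the
    window, and the 9-day first-line combination window.
    """

    data_window: tuple[dt.date, dt.date] = (dt.date(2018, 1, 1), dt.date(2021, 12, 31))
    washout_year: int = 2018
    index_year: int = 2019
    age_reference_date: dt.date = dt.date(2021, 12, 31)
    min_age_years: int = 18
    min_index_year_dispensations: int = 1
    min_follow_up_dispensations_per_year: int = 2
    combination_window_days: int = 9
    index_drug_atc: str = "A10"
    first_line_atc: frozenset[str] = METFORMIN_CONTAINING

    def __post_init__(self) -> None:
        if self.washout_year >= self.index_year:
            raise ValueError("washout_year must precede index_year")
        if self.combination_window_days < 0:
            raise ValueError("combination_window_days must be >= 0")
        start, end = self.data_window
        if not (start.year <= self.washout_year and self.index_year <= end.year):
            raise ValueError("washout/index years must lie inside the data window")

    @property
    def study_end(self) -> dt.date:
        return self.data_window[1]

    @property
    def follow_up_years(self) -> range:
        """Calendar years after the index year, up to the study end."""
        return range(self.index_year + 1, self.study_end.year + 1)


class ExclusionReason(str, Enum):
    AGE = "age"
    WASHOUT = "wash-out"
    INDEX_YEAR = "index-year"
    FOLLOW_UP_FREQUENCY = "follow-up frequency"
    DEATH = "death"


@dataclass(frozen=True)
class IndexEvent:
    patient_id: str
    index_date: dt.date
    index_drugs: frozenset[str]


@dataclass
class CohortMember:
    profile: PatientProfile
    index_event: IndexEvent
    follow_up_end: dt.date
    n_distinct_ads: int = 0
    subgroup: str = ""

    @property
    def patient_id(self) -> str:
        return self.profile.patient_id

    @property
    def index_date(self) -> dt.date:
        return self.index_event.index_date


def _age_in_completed_years(birth_date: dt.date, at: dt.date) -> int:
    years = at.year - birth_date.year
    if (at.month, at.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def find_index_event(profile: PatientProfile, cfg: StudyConfig) -> IndexEvent:
    """Locate the index dispensation of a naïve initiator.

    The index date is the first antidiabetic dispensation in the index year;
    the index drugs are all distinct antidiabetic level-5 codes dispensed on
    that date (several distinct products on one day are all index drugs).
    """
    ads = profile.ad_events()
    in_index_year = [e for e in ads if e.dispense_date.year == cfg.index_year]
    if not in_index_year:
        raise ValueError(f"patient {profile.patient_id} has no index-year AD event")
    if any(e.dispense_date.year < cfg.index_year for e in ads):
        raise ValueError(f"patient {profile.patient_id} is not naïve")
    index_date = in_index_year[0].dispense_date
    drugs = frozenset(e.atc_code for e in in_index_year if e.dispense_date == index_date)
    return IndexEvent(profile.patient_id, index_date, drugs)


def _follow_up_end(profile: PatientProfile, index_date: dt.date, cfg: StudyConfig) -> dt.date:
    last_ad = max(e.dispense_date for e in profile.ad_events())
    return min(last_ad, cfg.study_end)


def select_naive_cohort(
    profiles: list[PatientProfile],
    deaths: list[DeathRecord],
    cfg: StudyConfig | None = None,
) -> tuple[list[CohortMember], list[tuple[str, ExclusionReason]]]:
    """Apply the eligibility cascade and return (cohort, exclusion ledger).

    A patient is retained iff they (a) reach the minimum age at the reference
    date, (b) have no antidiabetic dispensation before the index year
    (wash-out), (c) initiate in the index year with the required number of
    index-year dispensations, (d) keep at least the required number of
    antidiabetic dispensations in every calendar year after the index year
    through the study end, and (e) do not appear in the death registry within
    the study window.  The ledger lists every excluded patient with the first
    failed criterion.
    """
    cfg = cfg or StudyConfig()
    dead = {
        d.patient_id
        for d in deaths
        if d.death_date <= cfg.study_end
    }
    cohort: list[CohortMember] = []
    ledger: list[tuple[str, ExclusionReason]] = []
    for profile in sorted(profiles, key=lambda p: p.patient_id):
        reason = _first_failed_criterion(profile, dead, cfg)
        if reason is not None:
            ledger.append((profile.patient_id, reason))
            continue
        index_event = find_index_event(profile, cfg)
        member = CohortMember(
            profile=profile,
            index_event=index_event,
            follow_up_end=_follow_up_end(profile, index_event.index_date, cfg),
        )
        member.n_distinct_ads = _count_distinct_ads(member)
        member.subgroup = assign_ad_subgroup(member)
        cohort.append(member)
    return cohort, ledger


def _first_failed_criterion(
    profile: PatientProfile, dead: set[str], cfg: StudyConfig
) -> ExclusionReason | None:
    if _age_in_completed_years(profile.birth_date, cfg.age_reference_date) < cfg.min_age_years:
        return ExclusionReason.AGE
    ads = profile.ad_events()
    if any(e.dispense_date.year < cfg.index_year for e in ads):
        return ExclusionReason.WASHOUT
    n_index_year = sum(1 for e in ads if e.dispense_date.year == cfg.index_year)
    if n_index_year < max(cfg.min_index_year_dispensations, 1):
        return ExclusionReason.INDEX_YEAR
    for year in cfg.follow_up_years:
        n = sum(1 for e in ads if e.dispense_date.year == year)
        if n < cfg.min_follow_up_dispensations_per_year:
            return ExclusionReason.FOLLOW_UP_FREQUENCY
    if profile.patient_id in dead or (
        profile.death_date is not None and profile.death_date <= cfg.study_end
    ):
        return ExclusionReason.DEATH
    return None


def _count_distinct_ads(member: CohortMember) -> int:
    codes = {
        e.atc_code
        for e in member.profile.ad_events()
        if member.index_date <= e.dispense_date <= member.follow_up_end
    }
    return len(codes)


def assign_ad_subgroup(member: CohortMember) -> str:
    """Bucket by the number of distinct antidiabetic level-5 codes in follow-up."""
    n = member.n_distinct_ads or _count_distinct_ads(member)
    assert n >= 1, "a cohort member has at least the index drug"
    return SUBGROUP_LABELS[min(n, 5) - 1]


def refine_metformin_cohort(
    cohort: list[CohortMember], cfg: StudyConfig | None = None
) -> tuple[list[CohortMember], list[CohortMember]]:
    """Restrict to metformin initiators and split off combination initiators.

    Keeps members whose sole index drug is a metformin-containing product.
    Members with a dispensation of a second distinct antidiabetic code within
    ``combination_window_days`` of the index date (inclusive at both ends,
    so same-day multi-drug starters qualify) are first-line combination-
    therapy initiators and are returned separately.  Members who did not
    start with metformin at all belong to neither list.
    """
    cfg = cfg or StudyConfig()
    window = dt.timedelta(days=cfg.combination_window_days)
    metformin: list[CohortMember] = []
    combination: list[CohortMember] = []
    for member in cohort:
        drugs = member.index_event.index_drugs
        met_codes = drugs & cfg.first_line_atc
        if not met_codes:
            continue
        if len(drugs) > 1:
            combination.append(member)
            continue
        index_code = next(iter(drugs))
        second_early = any(
            e.atc_code != index_code
            and member.index_date <= e.dispense_date <= member.index_date + window
            for e in member.profile.ad_events()
        )
        (combination if second_early else metformin).append(member)
    return metformin, combination
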