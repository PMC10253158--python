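"""Model-style front end: a drug-utilization study fitted to dispensing data.

:class:`DrugUtilizationStudy` plays the role a model class plays in a
statistical package: it is constructed from the data (dispensing records,
death registry) and the study design (:class:`~rxcohort.cohort.StudyConfig`),
and ``fit()`` runs the whole analysis — cohort selection, metformin
refinement, subgroup assignment, comorbidity profiling, first-intensification
classification and adherence — returning a :class:`StudyResults` object that
carries the tables, the significance tests and a ``summary()``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from . import reporting
from .adherence import AdherenceConfig, AdherenceResult, adherence_table, compute_cma
from .cohort import (
    CohortMember,
    ExclusionReason,
    StudyConfig,
    refine_metformin_cohort,
    select_naive_cohort,
)
from .comorbidity import (
    DEFAULT_RX_RISK,
    RxRiskMap,
    assign_comorbidities,
    atcl1_usage_table,
    prevalence_table,
)
from .records import (
    DeathRecord,
    DispensingRecord,
    Dialect,
    build_profiles,
    read_death_table,
    read_dispensing_table,
)
from .trajectory import (
    MONOTHERAPY,
    TherapyTimeline,
    TrajectoryLabel,
    classify_first_intensification,
    intensification_summary,
)

__all__ = ["DrugUtilizationStudy", "StudyResults"]


class DrugUtilizationStudy:
    """New-user antidiabetic drug-utilization analysis of a dispensing stream.

    Parameters
    ----------
    records
        All dispensing records (any drug class) for the source population.
    deaths
        The death registry.
    config
        Study design: windows, wash-out/index years, thresholds.
    rx_risk_map
        Comorbidity map; defaults to the adapted ATC level-2 Rx-Risk index.
    adherence_config
        CMA variant and stratification thresholds.
    """

    def __init__(
        self,
        records: list[DispensingRecord],
        deaths: list[DeathRecord] | None = None,
        config: StudyConfig | None = None,
        rx_risk_map: RxRiskMap = DEFAULT_RX_RISK,
        adherence_config: AdherenceConfig | None = None,
    ) -> None:
        self.records = records
        self.deaths = deaths or []
        self.config = config or StudyConfig()
        self.rx_risk_map = rx_risk_map
        self.adherence_config = adherence_config or AdherenceConfig()

    @classmethod
    def from_csv(
        cls,
        dispensing_path,
        deaths_path=None,
        dialect: Dialect | None = None,
        **kwargs,
    ) -> "DrugUtilizationStudy":
        records, _ = read_dispensing_table(dispensing_path, dialect)
        deaths = read_death_table(deaths_path, dialect) if deaths_path else []
        return cls(records, deaths, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, deaths: pd.DataFrame | None = None, **kwargs):
        """Build from in-memory frames with the canonical column names."""
        def _date(v):
            return v if isinstance(v, dt.date) and not isinstance(v, dt.datetime) else pd.Timestamp(v).date()

        records = [
            DispensingRecord(
                patient_id=str(r.patient_id),
                birth_date=_date(r.birth_date),
                gender=str(r.gender),
                dispense_date=_date(r.dispense_date),
                atc_code=str(r.atc_code),
                n_packages=int(getattr(r, "n_packages", 1)),
                ddd_total=float(getattr(r, "ddd_total", 0.0)),
            )
            for r in df.itertuples(index=False)
        ]
        death_records = (
            [
                DeathRecord(str(r.patient_id), _date(r.death_date))
                for r in deaths.itertuples(index=False)
            ]
            if deaths is not None
            else []
        )
        return cls(records, death_records, **kwargs)

    def fit(self) -> "StudyResults":
        cfg = self.config
        profiles = build_profiles(self.records, self.deaths)
        cohort, ledger = select_naive_cohort(profiles, self.deaths, cfg)
        metformin_cohort, combination_initiators = refine_metformin_cohort(cohort, cfg)

        subgroups = {m.patient_id: m.subgroup for m in metformin_cohort}
        genders = {m.patient_id: m.profile.gender for m in metformin_cohort}

        comorbidity_profiles = [
            assign_comorbidities(m.profile, self.rx_risk_map, cfg.data_window)
            for m in metformin_cohort
        ]

        trajectories: list[TrajectoryLabel] = []
        for m in metformin_cohort:
            timeline = TherapyTimeline.from_member(m)
            trajectories.append(classify_first_intensification(timeline, cfg))

        adherence_results: list[AdherenceResult] = []
        for m in metformin_cohort:
            events = [
                e
                for e in m.profile.ad_events()
                if m.index_date <= e.dispense_date <= m.follow_up_end
            ]
            if (m.follow_up_end - m.index_date).days < 1:
                continue  # degenerate single-day window: CMA undefined
            adherence_results.append(
                compute_cma(
                    events,
                    (m.index_date, m.follow_up_end),
                    self.adherence_config,
                    patient_id=m.patient_id,
                )
            )

        return StudyResults(
            model=self,
            cohort=cohort,
            exclusions=ledger,
            metformin_cohort=metformin_cohort,
            combination_initiators=combination_initiators,
            comorbidity_profiles=comorbidity_profiles,
            trajectories=trajectories,
            adherence_results=adherence_results,
            subgroups=subgroups,
            genders=genders,
        )


@dataclass
class StudyResults:
    """Fitted study: cohorts, per-patient outputs and derived tables."""

    model: DrugUtilizationStudy
    cohort: list[CohortMember]
    exclusions: list[tuple[str, ExclusionReason]]
    metformin_cohort: list[CohortMember]
    combination_initiators: list[CohortMember]
    comorbidity_profiles: list
    trajectories: list[TrajectoryLabel]
    adherence_results: list[AdherenceResult]
    subgroups: dict[str, str]
    genders: dict[str, str]
    _tables: dict = field(default_factory=dict, repr=False)

    # -- derived tables ----------------------------------------------------

    @property
    def index_drug_distribution(self) -> pd.DataFrame:
        """Index-drug counts and percentages among single-index-drug patients."""
        if "index_drugs" not in self._tables:
            singles = [m for m in self.cohort if len(m.index_event.index_drugs) == 1]
            counts: dict[str, int] = {}
            for m in singles:
                code = next(iter(m.index_event.index_drugs))
                counts[code] = counts.get(code, 0) + 1
            n = len(singles)
            df = pd.DataFrame(
                [
                    {"atc_code": c, "n": k, "percent": round(100.0 * k / n, 1)}
                    for c, k in sorted(counts.items(), key=lambda kv: -kv[1])
                ]
            )
            self._tables["index_drugs"] = df
        return self._tables["index_drugs"]

    @property
    def subgroup_table(self) -> pd.DataFrame:
        """Cohort characteristics by subgroup, with chi-square / ANOVA tests."""
        if "subgroup_table" in self._tables:
            return self._tables["subgroup_table"]
        from .cohort import SUBGROUP_LABELS

        cfg = self.model.config
        rows = []
        labels = [sg for sg in SUBGROUP_LABELS if any(v == sg for v in self.subgroups.values())]
        n_total = len(self.metformin_cohort)
        members_by_sg = {
            sg: [m for m in self.metformin_cohort if m.subgroup == sg] for sg in labels
        }
        row_n = {"characteristic": "patients_n"}
        row_pct = {"characteristic": "patients_pct"}
        row_male = {"characteristic": "males_n"}
        row_age = {"characteristic": "age_median"}
        gender_counts, age_groups = [], []
        for sg in labels:
            ms = members_by_sg[sg]
            ages = [
                _age(m.profile.birth_date, cfg.age_reference_date) for m in ms
            ]
            n_male = sum(1 for m in ms if m.profile.gender == "male")
            row_n[sg] = len(ms)
            row_pct[sg] = round(100.0 * len(ms) / n_total, 1)
            row_male[sg] = n_male
            row_age[sg] = reporting.median_iqr(ages)[0] if ages else float("nan")
            gender_counts.append([n_male, len(ms) - n_male])
            age_groups.append(ages)
        rows.extend([row_n, row_pct, row_male, row_age])
        df = pd.DataFrame(rows)

        tests: dict[str, tuple[float, float]] = {}
        try:
            stat, _, p = reporting.chi_square_independence(gender_counts)
            tests["gender_chi2"] = (stat, p)
        except ValueError:
            pass
        if len([g for g in age_groups if g]) >= 2:
            f, _, p = reporting.one_way_anova([g for g in age_groups if g])
            tests["age_anova"] = (f, p)
        df.attrs["tests"] = tests
        self._tables["subgroup_table"] = df
        return df

    @property
    def atcl1_usage(self) -> pd.DataFrame:
        if "atcl1" not in self._tables:
            self._tables["atcl1"] = atcl1_usage_table(
                self.metformin_cohort, window=self.model.config.data_window
            )
        return self._tables["atcl1"]

    @property
    def comorbidity_prevalence(self) -> pd.DataFrame:
        if "comorbidity" not in self._tables:
            self._tables["comorbidity"] = prevalence_table(
                self.comorbidity_profiles, self.subgroups, self.model.rx_risk_map
            )
        return self._tables["comorbidity"]

    @property
    def intensification(self) -> pd.DataFrame:
        """First-change summary over the two-AD subgroup."""
        if "intensification" not in self._tables:
            two_ad = {m.patient_id for m in self.metformin_cohort if m.subgroup == "2"}
            labels = [t for t in self.trajectories if t.patient_id in two_ad]
            self._tables["intensification"] = intensification_summary(labels)
        return self._tables["intensification"]

    @property
    def adherence(self) -> pd.DataFrame:
        if "adherence" not in self._tables:
            self._tables["adherence"] = adherence_table(
                self.adherence_results,
                self.subgroups,
                self.genders,
                self.model.adherence_config,
            )
        return self._tables["adherence"]

    # -- summary -----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        n_input = len(self.cohort) + len(self.exclusions)
        lines = [
            "Drug-utilization study of treatment-naive antidiabetic initiators",
            "=" * 66,
            f"data window            : {cfg.data_window[0]} .. {cfg.data_window[1]}",
            f"wash-out / index year  : {cfg.washout_year} / {cfg.index_year}",
            f"patients screened      : {n_input}",
            f"naive cohort           : {len(self.cohort)}",
            f"  excluded             : {len(self.exclusions)}",
        ]
        by_reason: dict[str, int] = {}
        for _, reason in self.exclusions:
            by_reason[reason.value] = by_reason.get(reason.value, 0) + 1
        for reason, n in sorted(by_reason.items()):
            lines.append(f"    {reason:<20s}: {n}")
        lines += [
            f"metformin cohort       : {len(self.metformin_cohort)}",
            f"combination initiators : {len(self.combination_initiators)}",
        ]
        if not self.subgroup_table.empty:
            sizes = self.subgroup_table[self.subgroup_table.characteristic == "patients_n"]
            lines.append("subgroup sizes (distinct ADs): " + ", ".join(
                f"{c}={int(sizes.iloc[0][c])}" for c in sizes.columns[1:]
            ))
        changed = [t for t in self.trajectories if t.category != MONOTHERAPY]
        if changed:
            inten = self.intensification
            top = inten[inten.drug_class == "(all)"]
            lines.append("first intensification (two-AD subgroup): " + ", ".join(
                f"{r.category}={r.n} ({r.percent}%)" for r in top.itertuples()
            ))
        adh = self.adherence
        if not adh.empty:
            lines.append(
                "median CMA by subgroup : "
                + ", ".join(f"{r.subgroup}: {r.median}%" for r in adh.itertuples())
            )
            mm = adh.attrs.get("non_monotherapy_mean_median")
            if mm is not None:
                lines.append(f"mean of non-monotherapy subgroup medians: {mm}%")
        for name, (stat, p) in self.subgroup_table.attrs.get("tests", {}).items():
            lines.append(f"{name:<22s} : stat={stat:.3f}, p={reporting.format_p(p)}")
        return "\n".join(lines) + "\n"

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "index_drug_distribution": self.index_drug_distribution,
            "subgroup_characteristics": self.subgroup_table,
            "atcl1_usage": self.atcl1_usage,
            "comorbidity_prevalence": self.comorbidity_prevalence,
            "intensification": self.intensification,
            "adherence": self.adherence,
        }


def _age(birth: dt.date, at: dt.date) -> int:
    years = at.year - birth.year
    if (at.month, at.day) < (birth.month, birth.day):
        years -= 1
    return years
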