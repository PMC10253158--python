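"""First treatment-intensification classification for metformin initiators.

Only the first change in antidiabetic therapy is classified.  Let t* be the
date of the first non-metformin antidiabetic dispensation after the
first-line combination window.  The patient is labelled

* ``monotherapy`` when no such dispensation exists;
* ``add_on`` when the dispensed product is a metformin-containing fixed-dose
  combination, or when at least one plain-metformin dispensation occurs on or
  after t* (the second drug joins continuing metformin);
* ``switch`` otherwise (metformin is replaced);
* ``switch_then_discontinue`` for a switch after which the patient's last
  antidiabetic supply runs out at least one grace period before the study
  window closes, with no further dispensations.

Discontinuation after a switch is not defined by the data source itself; the
default grace period is the conventional 90-day refill gap and is
configurable.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import pandas as pd

from .cohort import CohortMember, StudyConfig
from .drugs import is_metformin_fdc, reporting_class
from .records import DispensingRecord, days_supplied, is_antidiabetic

logger = logging.getLogger(__name__)

__all__ = [
    "MONOTHERAPY",
    "ADD_ON",
    "SWITCH",
    "SWITCH_THEN_DISCONTINUE",
    "TherapyTimeline",
    "TrajectoryLabel",
    "classify_first_intensification",
    "intensification_class",
    "intensification_summary",
]

MONOTHERAPY = "monotherapy"
ADD_ON = "add_on"
SWITCH = "switch"
SWITCH_THEN_DISCONTINUE = "switch_then_discontinue"

CATEGORIES = (MONOTHERAPY, ADD_ON, SWITCH, SWITCH_THEN_DISCONTINUE)


@dataclass
class TherapyTimeline:
    """A metformin initiator's antidiabetic events split by product."""

    patient_id: str
    index_date: dt.date
    follow_up_end: dt.date
    metformin_events: list[DispensingRecord] = field(default_factory=list)
    other_ad_events: list[DispensingRecord] = field(default_factory=list)

    @classmethod
    def from_member(cls, member: CohortMember) -> "TherapyTimeline":
        # the baseline stream is plain metformin plus the index product itself
        # (a metformin-containing combination dispensed at index is baseline
        # therapy, not a change)
        baseline = {"A10BA02"} | set(member.index_event.index_drugs)
        met, other = [], []
        for ev in member.profile.ad_events():
            if not (member.index_date <= ev.dispense_date <= member.follow_up_end):
                continue
            (met if ev.atc_code in baseline else other).append(ev)
        if not met:
            raise ValueError(
                f"patient {member.patient_id} has no metformin events in follow-up"
            )
        return cls(member.patient_id, member.index_date, member.follow_up_end, met, other)

    def all_ad_events(self) -> list[DispensingRecord]:
        return sorted(
            self.metformin_events + self.other_ad_events, key=lambda e: e.dispense_date
        )


@dataclass(frozen=True)
class TrajectoryLabel:
    patient_id: str
    category: str
    change_date: dt.date | None = None
    change_atc: str | None = None

    def __post_init__(self) -> None:
        if (self.category == MONOTHERAPY) != (self.change_date is None):
            raise ValueError("change_date set iff a therapy change occurred")


def classify_first_intensification(
    timeline: TherapyTimeline,
    cfg: StudyConfig | None = None,
    discontinuation_gap_days: int = 90,
) -> TrajectoryLabel:
    """Classify the first therapy change of a metformin monotherapy initiator."""
    cfg = cfg or StudyConfig()
    if not timeline.metformin_events and not timeline.other_ad_events:
        raise ValueError("empty timeline")
    window_end = timeline.index_date + dt.timedelta(days=cfg.combination_window_days)
    candidates = [
        e for e in timeline.other_ad_events if e.dispense_date > window_end
    ]
    if not candidates:
        return TrajectoryLabel(timeline.patient_id, MONOTHERAPY)
    first = min(candidates, key=lambda e: e.dispense_date)
    t_star, code = first.dispense_date, first.atc_code

    if is_metformin_fdc(code):
        return TrajectoryLabel(timeline.patient_id, ADD_ON, t_star, code)
    metformin_continues = any(
        e.dispense_date >= t_star for e in timeline.metformin_events
    )
    if metformin_continues:
        return TrajectoryLabel(timeline.patient_id, ADD_ON, t_star, code)

    if _discontinued_after(timeline, cfg, discontinuation_gap_days):
        return TrajectoryLabel(timeline.patient_id, SWITCH_THEN_DISCONTINUE, t_star, code)
    return TrajectoryLabel(timeline.patient_id, SWITCH, t_star, code)


def _discontinued_after(
    timeline: TherapyTimeline, cfg: StudyConfig, gap_days: int
) -> bool:
    """True when the last antidiabetic supply runs out at least ``gap_days``
    before the study window closes."""
    last = max(timeline.all_ad_events(), key=lambda e: e.dispense_date)
    exhaustion = last.dispense_date + dt.timedelta(days=days_supplied(last))
    return (cfg.study_end - exhaustion).days >= gap_days


def intensification_class(label: TrajectoryLabel) -> str:
    """Reporting drug class of the change drug (ATC level-4 roll-up)."""
    if label.category == MONOTHERAPY or label.change_atc is None:
        raise ValueError("no therapy change to classify")
    if not is_antidiabetic(label.change_atc):
        raise ValueError(f"change drug is not an antidiabetic: {label.change_atc!r}")
    return reporting_class(label.change_atc)


def intensification_summary(labels: list[TrajectoryLabel]) -> pd.DataFrame:
    """Counts and percentages per category and per change drug class.

    Percentages are relative to the number of labelled patients, rounded to
    one decimal.  Patients labelled monotherapy are excluded with a warning
    (the summary describes the two-AD subgroup).
    """
    changed = [l for l in labels if l.category != MONOTHERAPY]
    if not changed:
        logger.warning("no therapy changes among %d labels; empty summary", len(labels))
        return pd.DataFrame(columns=["category", "drug_class", "n", "percent"])
    n_total = len(changed)
    rows = []
    for category in (ADD_ON, SWITCH, SWITCH_THEN_DISCONTINUE):
        in_cat = [l for l in changed if l.category == category]
        rows.append(
            {
                "category": category,
                "drug_class": "(all)",
                "n": len(in_cat),
                "percent": round(100.0 * len(in_cat) / n_total, 1),
            }
        )
        by_class: dict[str, int] = {}
        for l in in_cat:
            cls_name = intensification_class(l)
            by_class[cls_name] = by_class.get(cls_name, 0) + 1
        for cls_name, n in sorted(by_class.items(), key=lambda kv: -kv[1]):
            rows.append(
                {
                    "category": category,
                    "drug_class": cls_name,
                    "n": n,
                    "percent": round(100.0 * n / n_total, 1),
                }
            )
    return pd.DataFrame(rows)
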