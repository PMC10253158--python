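"""Medication adherence as continuous multiple-interval medication availability.

CMA is the fraction of the observation window covered by dispensed supply,
expressed as a percentage.  The default construction is the carry-over sweep:
dispensations are processed in date order and each one's supply starts at
whichever is later, its dispensation date or the end of the supply already
accumulated, and is truncated at the window end.  Oversupply therefore rolls
forward instead of being double counted, and the value cannot exceed 100%.

A simple supply/window ratio is kept as an explicit sensitivity-analysis
variant; with the cap disabled it can exceed 100% under stockpiling.

Patients are stratified as adherent (CMA >= 80%), partially adherent
(40% <= CMA < 80%) or non-adherent (CMA < 40%).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DispensingRecord, days_supplied

logger = logging.getLogger(__name__)

__all__ = [
    "CARRYOVER",
    "SIMPLE_RATIO",
    "ADHERENT",
    "PARTIALLY_ADHERENT",
    "NON_ADHERENT",
    "AdherenceConfig",
    "AdherenceResult",
    "compute_cma",
    "stratify",
    "adherence_table",
]

CARRYOVER = "carryover"
SIMPLE_RATIO = "simple_ratio"

ADHERENT = "adherent"
PARTIALLY_ADHERENT = "partially_adherent"
NON_ADHERENT = "non_adherent"

STRATA = (ADHERENT, PARTIALLY_ADHERENT, NON_ADHERENT)


@dataclass(frozen=True)
class AdherenceConfig:
    variant: str = CARRYOVER
    cap_at_100: bool = True
    adherent_threshold: float = 80.0
    partial_threshold: float = 40.0

    def __post_init__(self) -> None:
        if self.variant not in (CARRYOVER, SIMPLE_RATIO):
            raise ValueError(f"unknown CMA variant: {self.variant!r}")
        if not (0 < self.partial_threshold < self.adherent_threshold <= 100):
            raise ValueError("thresholds must satisfy 0 < partial < adherent <= 100")


@dataclass(frozen=True)
class AdherenceResult:
    patient_id: str
    cma_percent: float
    window: tuple[dt.date, dt.date]
    covered_days: float
    window_days: float
    stratum: str


def compute_cma(
    events: list[DispensingRecord],
    window: tuple[dt.date, dt.date],
    cfg: AdherenceConfig | None = None,
    patient_id: str | None = None,
) -> AdherenceResult:
    """CMA over ``window`` (closed-open, in whole days) from dated supplies.

    All antidiabetic supply is pooled into a single availability stream.  A
    dispensation on the window's last day contributes nothing: its supply
    lies outside the observable window.
    """
    cfg = cfg or AdherenceConfig()
    start, end = window
    window_days = (end - start).days
    if window_days < 1:
        raise ValueError("observation window must span at least one day")

    supplies = []
    for ev in sorted(events, key=lambda e: e.dispense_date):
        if not (start <= ev.dispense_date <= end):
            raise ValueError(
                f"event on {ev.dispense_date} outside window [{start}, {end}]"
            )
        d = days_supplied(ev)
        if d < 0:
            raise ValueError("negative days of supply")
        supplies.append(((ev.dispense_date - start).days, d))

    if cfg.variant == CARRYOVER:
        covered = 0.0
        cursor = 0.0  # end of accumulated supply, in days from window start
        for offset, supply in supplies:
            begin = max(float(offset), cursor)
            supply_end = min(begin + supply, float(window_days))
            if supply_end > begin:
                covered += supply_end - begin
            cursor = max(cursor, begin + supply)
        cma = 100.0 * covered / window_days
    else:
        if cfg.cap_at_100:
            total = sum(
                min(supply, window_days - offset) for offset, supply in supplies
            )
            covered = min(float(total), float(window_days))
        else:
            covered = float(sum(s for _, s in supplies))
        cma = 100.0 * covered / window_days

    pid = patient_id or (events[0].patient_id if events else "")
    return AdherenceResult(
        patient_id=pid,
        cma_percent=cma,
        window=window,
        covered_days=covered,
        window_days=float(window_days),
        stratum=stratify(cma, cfg),
    )


def stratify(cma_percent: float, cfg: AdherenceConfig | None = None) -> str:
    """Adherence band of a CMA value; bands are closed at their lower edge."""
    cfg = cfg or AdherenceConfig()
    if cma_percent >= cfg.adherent_threshold:
        return ADHERENT
    if cma_percent >= cfg.partial_threshold:
        return PARTIALLY_ADHERENT
    return NON_ADHERENT


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles with linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty collection")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def adherence_table(
    results: list[AdherenceResult],
    subgroups: dict[str, str],
    genders: dict[str, str] | None = None,
    cfg: AdherenceConfig | None = None,
) -> pd.DataFrame:
    """Per-subgroup adherence summary: median [IQR] overall and by gender,
    plus the percentage of patients in each adherence stratum.

    Returns one row per subgroup, in subgroup order; empty subgroups are
    omitted with a warning.  The frame's ``attrs["non_monotherapy_mean_median"]``
    carries the cross-subgroup mean of the medians excluding the first
    (monotherapy) subgroup — the usual single-number summary for patients on
    more than one antidiabetic.
    """
    from .cohort import SUBGROUP_LABELS

    cfg = cfg or AdherenceConfig()
    genders = genders or {}
    by_sg: dict[str, list[AdherenceResult]] = {}
    for r in results:
        sg = subgroups.get(r.patient_id)
        if sg is None:
            continue
        by_sg.setdefault(sg, []).append(r)

    rows = []
    for sg in SUBGROUP_LABELS:
        rs = by_sg.get(sg, [])
        if not rs:
            logger.warning("subgroup %s empty; omitted from adherence table", sg)
            continue
        cmas = [r.cma_percent for r in rs]
        med, q1, q3 = median_iqr(cmas)
        row = {
            "subgroup": sg,
            "n": len(rs),
            "median": round(med, 1),
            "q1": round(q1, 1),
            "q3": round(q3, 1),
        }
        for gender in ("male", "female"):
            g = [r.cma_percent for r in rs if genders.get(r.patient_id) == gender]
            if g:
                gmed, gq1, gq3 = median_iqr(g)
                row[f"median_{gender}"] = round(gmed, 1)
                row[f"q1_{gender}"] = round(gq1, 1)
                row[f"q3_{gender}"] = round(gq3, 1)
        for stratum in STRATA:
            n = sum(1 for r in rs if r.stratum == stratum)
            row[f"pct_{stratum}"] = round(100.0 * n / len(rs), 1)
        rows.append(row)

    df = pd.DataFrame(rows)
    if not df.empty and len(df) > 1:
        non_mono = df[df["subgroup"] != SUBGROUP_LABELS[0]]["median"]
        df.attrs["non_monotherapy_mean_median"] = round(float(non_mono.mean()), 1)
    return df
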