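"""Adapted Rx-Risk comorbidity index on ATC level-2 drug classes.

The Rx-Risk index infers treated conditions from dispensing data alone: one
dispensation of a drug in a condition's class set marks the patient as being
treated for that condition.  This adaptation works at ATC level 2 and
classifies each condition as diabetes-concordant (shared pathophysiologic
risk profile and management goals) or discordant, per Piette's definition.
Antidiabetic (A10) dispensations never contribute to any comorbidity flag.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import PatientProfile, atc_prefix, is_antidiabetic

logger = logging.getLogger(__name__)

__all__ = [
    "Condition",
    "RxRiskMap",
    "ComorbidityProfile",
    "DEFAULT_RX_RISK",
    "expand_atcl2_ranges",
    "assign_comorbidities",
    "atcl1_usage_table",
    "prevalence_table",
]

CONCORDANT = "concordant"
DISCORDANT = "discordant"

_RANGE_RE = re.compile(r"^([A-Z])(\d{2})(?:\s*[–-]\s*([A-Z])?(\d{2}))?$")


def expand_atcl2_ranges(spec: str) -> frozenset[str]:
    """Expand a comma-separated list of ATC level-2 codes and ranges.

    ``"J01–J07"`` expands numerically within the letter prefix; single codes
    pass through.  Example: ``"A03–A04, A06–A07"`` -> {A03, A04, A06, A07}.
    """
    codes: set[str] = set()
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        m = _RANGE_RE.match(token)
        if not m:
            raise ValueError(f"cannot parse ATCL2 token: {token!r}")
        letter, lo, letter2, hi = m.groups()
        if hi is None:
            codes.add(f"{letter}{lo}")
            continue
        if letter2 is not None and letter2 != letter:
            raise ValueError(f"range must stay within one letter prefix: {token!r}")
        for n in range(int(lo), int(hi) + 1):
            codes.add(f"{letter}{n:02d}")
    return frozenset(codes)


@dataclass(frozen=True)
class Condition:
    name: str
    atcl2_codes: frozenset[str]
    concordance: str  # CONCORDANT or DISCORDANT


@dataclass(frozen=True)
class RxRiskMap:
    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        seen: dict[str, str] = {}
        for cond in self.conditions:
            for code in cond.atcl2_codes:
                if code in seen:
                    raise ValueError(
                        f"ATCL2 code {code} maps to both {seen[code]!r} and {cond.name!r}"
                    )
                seen[code] = cond.name

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, str, str]]) -> "RxRiskMap":
        """Build from (condition name, code/range spec, concordance) triples."""
        return cls(
            tuple(
                Condition(name, expand_atcl2_ranges(spec), concordance)
                for name, spec, concordance in entries
            )
        )

    def condition_of(self, atcl2: str) -> Condition | None:
        for cond in self.conditions:
            if atcl2 in cond.atcl2_codes:
                return cond
        return None


# The default map: 21 conditions, 4 concordant and 17 discordant, with
# antithrombotics (B01) housed under the cardiovascular condition and
# C02/C03/C09 under hypertension.
DEFAULT_RX_RISK = RxRiskMap.from_entries(
    [
        ("cardiovascular/cerebrovascular and heart diseases", "C01, C04, C05, C07, C08, B01", CONCORDANT),
        ("hypertension", "C02, C03, C09", CONCORDANT),
        ("hyperlipidemia", "C10", CONCORDANT),
        ("hyperuricemia/gout", "M04", CONCORDANT),
        ("infectious diseases", "J01–J07", DISCORDANT),
        ("acid related disorders", "A02", DISCORDANT),
        ("inflammatory/rheumatic disorders", "M01–M03, M09", DISCORDANT),
        ("corticosteroid-responsive diseases", "H02", DISCORDANT),
        ("nutrition-related diseases", "A08–A09, A11–A16", DISCORDANT),
        ("pain, including migraine", "N02", DISCORDANT),
        ("depression and other mental disorders", "N06, N07", DISCORDANT),
        ("chronic obstructive airways diseases", "R03", DISCORDANT),
        ("gastrointestinal disorders and nausea", "A03–A04, A06–A07", DISCORDANT),
        ("anemia", "B03", DISCORDANT),
        ("genito-urinary diseases", "G01–G04", DISCORDANT),
        ("thyroid disorders", "H03", DISCORDANT),
        ("respiratory diseases", "R01–R02, R05–R07", DISCORDANT),
        ("epilepsy", "N03", DISCORDANT),
        ("dermatological diseases", "D01–D11", DISCORDANT),
        ("eye disorders, including glaucoma", "S01, S03", DISCORDANT),
        ("psychotic illnesses", "N05", DISCORDANT),
    ]
)


@dataclass
class ComorbidityProfile:
    patient_id: str
    flags: dict[str, bool]


def assign_comorbidities(
    profile: PatientProfile,
    rx_map: RxRiskMap = DEFAULT_RX_RISK,
    window: tuple[dt.date, dt.date] | None = None,
) -> ComorbidityProfile:
    """Flag each condition present in a patient's non-antidiabetic dispensations.

    A condition is flagged when at least one dispensation inside ``window``
    (default: all events) carries an ATC level-2 prefix in the condition's
    code set.  A10 dispensations are ignored entirely.
    """
    flags = {cond.name: False for cond in rx_map.conditions}
    for ev in profile.events:
        if window is not None and not (window[0] <= ev.dispense_date <= window[1]):
            continue
        if is_antidiabetic(ev.atc_code):
            continue
        cond = rx_map.condition_of(atc_prefix(ev.atc_code, 2))
        if cond is not None:
            flags[cond.name] = True
    return ComorbidityProfile(profile.patient_id, flags)


def atcl1_usage_table(
    members,  # list[CohortMember]
    min_prevalence: float = 10.0,
    window: tuple[dt.date, dt.date] | None = None,
) -> pd.DataFrame:
    """Per-subgroup percentage of patients with any dispensation in each ATC
    level-1 anatomical group, antidiabetic records excluded.

    Only groups reaching ``min_prevalence`` percent in at least one subgroup
    are reported.  Columns are subgroup labels, rows ATCL1 letters.
    """
    from .cohort import SUBGROUP_LABELS

    counts: dict[str, dict[str, int]] = {}
    sizes: dict[str, int] = {}
    for member in members:
        sg = member.subgroup
        sizes[sg] = sizes.get(sg, 0) + 1
        letters = set()
        for ev in member.profile.events:
            if window is not None and not (window[0] <= ev.dispense_date <= window[1]):
                continue
            if is_antidiabetic(ev.atc_code):
                continue
            letters.add(ev.atc_code[0])
        for letter in letters:
            counts.setdefault(letter, {}).setdefault(sg, 0)
            counts[letter][sg] += 1

    subgroups = [sg for sg in SUBGROUP_LABELS if sg in sizes]
    empty = [sg for sg in SUBGROUP_LABELS if sg not in sizes]
    if empty:
        logger.warning("empty subgroup(s) omitted from ATCL1 table: %s", empty)
    rows = {}
    for letter in sorted(counts):
        pct = {sg: 100.0 * counts[letter].get(sg, 0) / sizes[sg] for sg in subgroups}
        if any(v >= min_prevalence for v in pct.values()):
            rows[letter] = pct
    return pd.DataFrame.from_dict(rows, orient="index", columns=subgroups)


def prevalence_table(
    profiles: Sequence[ComorbidityProfile],
    subgroups: dict[str, str],
    rx_map: RxRiskMap = DEFAULT_RX_RISK,
    min_prevalence: float = 10.0,
    reference_subgroup: str = "1",
) -> pd.DataFrame:
    """Condition-by-subgroup prevalence table with the reporting filter.

    A condition row is kept iff its prevalence reaches ``min_prevalence``
    percent in at least one subgroup.  Rows are grouped by concordance
    (concordant first) and sorted by prevalence in the reference subgroup,
    descending.  ``subgroups`` maps patient_id to subgroup label.
    """
    from .cohort import SUBGROUP_LABELS

    labels = [sg for sg in SUBGROUP_LABELS if sg in set(subgroups.values())]
    sizes = {sg: sum(1 for v in subgroups.values() if v == sg) for sg in labels}

    rows = []
    for cond in rx_map.conditions:
        pct = {}
        for sg in labels:
            n = sum(
                1
                for p in profiles
                if subgroups.get(p.patient_id) == sg and p.flags.get(cond.name, False)
            )
            pct[sg] = 100.0 * n / sizes[sg]
        if any(v >= min_prevalence for v in pct.values()):
            rows.append(
                {"condition": cond.name, "concordance": cond.concordance, **pct}
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    ref = reference_subgroup if reference_subgroup in labels else labels[0]
    df["_block"] = (df["concordance"] != CONCORDANT).astype(int)
    df = df.sort_values(["_block", ref], ascending=[True, False]).drop(columns="_block")
    return df.reset_index(drop=True)
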