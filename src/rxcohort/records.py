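"""Dispensing-record data model, ATC code utilities and table I/O.

The unit of observation is one community-pharmacy dispensation: who received
it, when, which product (ATC level-5 code) and how much supply it carries,
expressed as a number of Defined Daily Doses (DDD).  One DDD is taken to be
one day of supply, the standard convention when converting dispensed quantity
into treatment days.

Dates are calendar dates; every interval in the package is closed on the left
and open on the right, measured in whole days.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ATC_PATTERN",
    "DispensingRecord",
    "DeathRecord",
    "PatientProfile",
    "Dialect",
    "ReadReport",
    "atc_prefix",
    "is_antidiabetic",
    "is_valid_atc",
    "days_supplied",
    "read_dispensing_table",
    "write_dispensing_table",
    "read_death_table",
    "write_death_table",
    "build_profiles",
]

# One letter (anatomical group), two digits (therapeutic subgroup), then up to
# two letters (pharmacological / chemical subgroup) and up to two digits
# (chemical substance).  Partial codes are valid at levels 1-4; a full
# level-5 code has 7 characters.
ATC_PATTERN = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")

#: Prefix length of each ATC hierarchy level.
_ATC_LEVEL_LEN = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

GENDERS = ("male", "female")


def is_valid_atc(code: str) -> bool:
    """True if ``code`` is structurally a valid (possibly partial) ATC code."""
    return isinstance(code, str) and bool(ATC_PATTERN.match(code))


def atc_prefix(code: str, level: int) -> str:
    """Truncate an ATC code to the prefix identifying hierarchy ``level``.

    Levels 1-5 correspond to prefixes of 1, 3, 4, 5 and 7 characters.

    >>> atc_prefix("A10BA02", 2)
    'A10'
    """
    if level not in _ATC_LEVEL_LEN:
        raise ValueError(f"ATC level must be in 1..5, got {level!r}")
    if not is_valid_atc(code):
        raise ValueError(f"malformed ATC code: {code!r}")
    n = _ATC_LEVEL_LEN[level]
    if len(code) < n:
        raise ValueError(f"code {code!r} too short for ATC level {level}")
    return code[:n]


def is_antidiabetic(code: str) -> bool:
    """True iff the code belongs to the antidiabetic group (ATC level 2 = A10)."""
    return atc_prefix(code, 2) == "A10"


@dataclass(frozen=True)
class DispensingRecord:
    """One dispensation event.

    ``ddd_total`` is the number of Defined Daily Doses in the dispensation,
    i.e. its days of supply at one DDD per day.
    """

    patient_id: str
    birth_date: dt.date
    gender: str
    dispense_date: dt.date
    atc_code: str
    n_packages: int = 1
    ddd_total: float = 0.0
    active_ingredient: str | None = None
    medication_name: str | None = None

    def __post_init__(self) -> None:
        if not is_valid_atc(self.atc_code):
            raise ValueError(f"malformed ATC code: {self.atc_code!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.n_packages < 1:
            raise ValueError("n_packages must be >= 1")
        if self.ddd_total < 0:
            raise ValueError("ddd_total must be >= 0")


@dataclass(frozen=True)
class DeathRecord:
    patient_id: str
    death_date: dt.date


@dataclass
class PatientProfile:
    """A patient's demographics plus their date-ordered dispensing timeline."""

    patient_id: str
    birth_date: dt.date
    gender: str
    events: list[DispensingRecord] = field(default_factory=list)
    death_date: dt.date | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda r: r.dispense_date)
        for ev in self.events:
            if ev.patient_id != self.patient_id:
                raise ValueError(
                    f"event patient_id {ev.patient_id!r} != profile {self.patient_id!r}"
                )

    def ad_events(self) -> list[DispensingRecord]:
        """The antidiabetic (A10) dispensations, in date order."""
        return [e for e in self.events if is_antidiabetic(e.atc_code)]


def days_supplied(
    record: DispensingRecord,
    ddd_per_unit: float | None = None,
    units_per_package: float | None = None,
) -> float:
    """Days of treatment supplied by one dispensation.

    The dispensed quantity divided by the DDD gives the duration in days.
    When the record carries its DDD total that value is used directly;
    otherwise the duration is reconstructed from package content as
    ``n_packages * units_per_package * ddd_per_unit``.
    """
    if record.ddd_total > 0:
        return float(record.ddd_total)
    if ddd_per_unit is not None and units_per_package is not None:
        return float(record.n_packages) * units_per_package * ddd_per_unit
    if record.ddd_total == 0 and ddd_per_unit is None:
        logger.warning(
            "record %s/%s on %s has zero days of supply",
            record.patient_id,
            record.atc_code,
            record.dispense_date,
        )
        return 0.0
    raise ValueError("no supply information available on record")


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_DISPENSING_COLUMNS = (
    "patient_id",
    "birth_date",
    "gender",
    "dispense_date",
    "atc_code",
    "n_packages",
    "ddd_total",
)
_OPTIONAL_COLUMNS = ("active_ingredient", "medication_name")


@dataclass
class Dialect:
    """How a delimited dispensing extract maps onto the record schema.

    ``column_map`` maps schema field names to the header names used in the
    file; fields absent from the map are assumed to use the schema name.
    """

    delimiter: str = ","
    date_format: str = "%Y-%m-%d"
    column_map: Mapping[str, str] = field(default_factory=dict)

    def source_name(self, field_name: str) -> str:
        return self.column_map.get(field_name, field_name)

    @classmethod
    def from_yaml(cls, path: str) -> "Dialect":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            delimiter=raw.get("delimiter", ","),
            date_format=raw.get("date_format", "%Y-%m-%d"),
            column_map=raw.get("column_map", {}),
        )


@dataclass
class ReadReport:
    n_read: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _parse_date(value, fmt: str) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.datetime.strptime(str(value).strip(), fmt).date()


def read_dispensing_table(
    path,
    dialect: Dialect | None = None,
    data_window: tuple[dt.date, dt.date] | None = None,
) -> tuple[list[DispensingRecord], ReadReport]:
    """Read a delimited dispensing extract into validated records.

    Rows with a malformed ATC code, an unparseable date, an unknown gender or
    a dispense date outside ``data_window`` are rejected and logged in the
    returned :class:`ReadReport`; a missing mandatory column is a hard error.
    Row order is preserved.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in _DISPENSING_COLUMNS if dialect.source_name(c) not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")

    report = ReadReport(n_read=len(df))
    records: list[DispensingRecord] = []
    for i in range(len(df)):
        raw = {c: df.iloc[i][dialect.source_name(c)] for c in _DISPENSING_COLUMNS}
        try:
            rec = DispensingRecord(
                patient_id=str(raw["patient_id"]),
                birth_date=_parse_date(raw["birth_date"], dialect.date_format),
                gender=str(raw["gender"]).strip().lower(),
                dispense_date=_parse_date(raw["dispense_date"], dialect.date_format),
                atc_code=str(raw["atc_code"]).strip(),
                n_packages=int(raw["n_packages"]),
                ddd_total=float(raw["ddd_total"]),
                active_ingredient=_opt(df, i, dialect, "active_ingredient"),
                medication_name=_opt(df, i, dialect, "medication_name"),
            )
            if data_window is not None and not (
                data_window[0] <= rec.dispense_date <= data_window[1]
            ):
                raise ValueError(
                    f"dispense_date {rec.dispense_date} outside data window"
                )
        except (ValueError, TypeError) as exc:
            report.rejected.append((i, str(exc)))
            logger.warning("row %d rejected: %s", i, exc)
            continue
        records.append(rec)
    report.n_accepted = len(records)
    return records, report


def _opt(df: pd.DataFrame, i: int, dialect: Dialect, name: str) -> str | None:
    col = dialect.source_name(name)
    if col in df.columns:
        v = df.iloc[i][col]
        return str(v) if str(v) else None
    return None


def write_dispensing_table(records: Iterable[DispensingRecord], path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    rows = []
    for r in records:
        rows.append(
            {
                dialect.source_name("patient_id"): r.patient_id,
                dialect.source_name("birth_date"): r.birth_date.strftime(dialect.date_format),
                dialect.source_name("gender"): r.gender,
                dialect.source_name("dispense_date"): r.dispense_date.strftime(dialect.date_format),
                dialect.source_name("atc_code"): r.atc_code,
                dialect.source_name("n_packages"): r.n_packages,
                dialect.source_name("ddd_total"): r.ddd_total,
                dialect.source_name("active_ingredient"): r.active_ingredient or "",
                dialect.source_name("medication_name"): r.medication_name or "",
            }
        )
    cols = [dialect.source_name(c) for c in _DISPENSING_COLUMNS + _OPTIONAL_COLUMNS]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=dialect.delimiter, index=False)


def read_death_table(path, dialect: Dialect | None = None) -> list[DeathRecord]:
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    for c in ("patient_id", "death_date"):
        if dialect.source_name(c) not in df.columns:
            raise ValueError(f"missing mandatory column: {c}")
    out = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = str(row[dialect.source_name("patient_id")])
        if pid in seen:
            raise ValueError(f"duplicate death record for patient {pid}")
        seen.add(pid)
        out.append(
            DeathRecord(pid, _parse_date(row[dialect.source_name("death_date")], dialect.date_format))
        )
    return out


def write_death_table(deaths: Iterable[DeathRecord], path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    df = pd.DataFrame(
        [
            {
                dialect.source_name("patient_id"): d.patient_id,
                dialect.source_name("death_date"): d.death_date.strftime(dialect.date_format),
            }
            for d in deaths
        ],
        columns=[dialect.source_name("patient_id"), dialect.source_name("death_date")],
    )
    df.to_csv(path, sep=dialect.delimiter, index=False)


def build_profiles(
    records: Sequence[DispensingRecord],
    deaths: Sequence[DeathRecord] = (),
) -> list[PatientProfile]:
    """Group dispensations into per-patient, date-ordered profiles.

    Demographics are taken from the patient's first record; the death
    registry is joined on patient id.
    """
    death_by_id = {d.patient_id: d.death_date for d in deaths}
    by_patient: dict[str, list[DispensingRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    profiles = []
    for pid, evs in by_patient.items():
        first = evs[0]
        profiles.append(
            PatientProfile(
                patient_id=pid,
                birth_date=first.birth_date,
                gender=first.gender,
                events=evs,
                death_date=death_by_id.get(pid),
            )
        )
    return profiles
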