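"""Core record types shared across the pipeline.

FAERS dates are plain digit strings with three levels of precision
(``YYYYMMDD``, ``YYYYMM``, ``YYYY``); :class:`PartialDate` keeps the
precision explicit instead of silently imputing a day.  A safety report
is one :class:`CaseReport`; several reports (``primaryid``) may be
versions of the same case (``caseid``).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional

ROLE_CODES = ("PS", "SS", "C", "I")
SEX_CODES = ("M", "F", "UNK")
OCCUPATION_CODES = ("MD", "PH", "OT", "CN", "LW", "HP", "UNK")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: hours per Julian year; weeks use the 365.25/7 convention
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1786,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_MAX_YEARS = 130.0


@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date known to year, month or day precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day precision requires a month")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def sort_key(self) -> tuple[int, int, int]:
        """Chronological key; unknown components sort first."""
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> Optional[datetime.date]:
        """The exact date, or None unless day-precision."""
        if self.day is None:
            return None
        return datetime.date(self.year, self.month, self.day)

    def to_faers(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_partial_date(text: object) -> Optional[PartialDate]:
    """Parse a FAERS date field; invalid or empty input returns None.

    8 digits give day precision, 6 month, 4 year.  Dates that do not
    exist on the calendar (e.g. ``20200230``) are treated as missing
    rather than rounded.
    """
    if text is None:
        return None
    s = str(text).strip()
    if not s.isdigit():
        return None
    try:
        if len(s) == 8:
            d = datetime.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
            return PartialDate(d.year, d.month, d.day)
        if len(s) == 6:
            year, month = int(s[:4]), int(s[4:6])
            if not 1 <= month <= 12:
                return None
            return PartialDate(year, month)
        if len(s) == 4:
            return PartialDate(int(s))
    except ValueError:
        return None
    return None


def age_to_years(value: object, unit_code: Optional[str]) -> Optional[float]:
    """Convert a raw AGE/AGE_COD pair to years.

    A missing unit with a value present is taken as years (the dominant
    FAERS convention).  Results outside [0, 130] years are treated as
    unusable and returned as missing.
    """
    if value is None:
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    unit = (unit_code or "YR").strip().upper() or "YR"
    factor = _AGE_FACTORS.get(unit)
    if factor is None:
        return None
    years = v * factor
    if years < 0 or years > AGE_MAX_YEARS:
        return None
    return years


@dataclass(frozen=True)
class DrugEntry:
    """One drug row on a report: verbatim name, role code, therapy start."""

    verbatim_name: str
    role: str
    therapy_start: Optional[PartialDate] = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown role code {self.role!r}")


@dataclass(frozen=True)
class CaseReport:
    """One safety report assembled across the seven FAERS tables.

    ``age`` / ``age_cod`` hold the raw strings as reported; ``age_years``
    is the normalized value (None when missing or implausible).
    """

    primaryid: str
    caseid: str
    receipt_date: PartialDate
    event_date: Optional[PartialDate] = None
    age: str = ""
    age_cod: str = ""
    age_years: Optional[float] = None
    sex: str = "UNK"
    occupation: str = "UNK"
    country: str = "UNK"
    outcomes: frozenset[str] = frozenset()
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[str, ...] = ()

    def ps_drug_names(self) -> tuple[str, ...]:
        return tuple(d.verbatim_name for d in self.drugs if d.role == "PS")


def primaryid_sort_key(primaryid: str) -> tuple[int, int, str]:
    """Numeric-then-lexicographic ordering used by the dedup tie-break."""
    s = primaryid.strip()
    if s.isdigit():
        return (1, int(s), "")
    return (0, 0, s)
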