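"""Time-to-onset analysis.

Onset is the number of whole days from the start of primary-suspect
therapy to the event date.  Both dates must be known to day precision;
cases with a missing or coarser date, or a negative interval, are
excluded with an explicit reason rather than imputed.  Summaries use the
lower-median convention for even n (the order statistic at ceil(n/2)),
and a fixed interval histogram (0-7, 8-14, 15-30, 31-60, 61-90, 91-180,
181-365, >365 days).
"""

from __future__ import annotations

import enum
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cases import CaseSet, DrugDictionary, match_drug
from .records import CaseReport

log = logging.getLogger(__name__)

HISTOGRAM_BINS: tuple[tuple[int, float], ...] = (
    (0, 7),
    (8, 14),
    (15, 30),
    (31, 60),
    (61, 90),
    (91, 180),
    (181, 365),
    (366, math.inf),
)

AGE_BIN_EDGES = ((0, 18), (18, 45), (45, 65), (65, math.inf))
AGE_BIN_LABELS = ("<18", "18-44", "45-64", ">=65")


class Exclusion(enum.Enum):
    MISSING_EVENT_DATE = "missing event date"
    COARSE_EVENT_DATE = "event date coarser than day"
    MISSING_THERAPY_START = "missing therapy start"
    COARSE_THERAPY_START = "therapy start coarser than day"
    NEGATIVE_INTERVAL = "event before therapy start"


@dataclass(frozen=True)
class OnsetRecord:
    caseid: str
    drug: str
    onset_days: int
    sex: str
    age_years: Optional[float]


def age_bin(age_years: Optional[float]) -> str:
    if age_years is None:
        return "unknown"
    for (lo, hi), label in zip(AGE_BIN_EDGES, AGE_BIN_LABELS):
        if lo <= age_years < hi:
            return label
    return "unknown"


def onset_days(
    case: CaseReport, drug: str, dictionary: DrugDictionary
) -> int | Exclusion:
    """Days from the earliest day-precision PS therapy start for *drug*
    to the event date, or the exclusion reason."""
    target = drug.upper()
    starts = [
        e.therapy_start
        for e in case.drugs
        if e.role == "PS" and match_drug(e.verbatim_name, dictionary) == target
    ]
    if not starts or all(s is None for s in starts):
        return Exclusion.MISSING_THERAPY_START
    day_starts = [s for s in starts if s is not None and s.precision == "day"]
    if not day_starts:
        return Exclusion.COARSE_THERAPY_START
    if case.event_date is None:
        return Exclusion.MISSING_EVENT_DATE
    if case.event_date.precision != "day":
        return Exclusion.COARSE_EVENT_DATE
    start = min(day_starts, key=lambda s: s.sort_key())
    delta = (case.event_date.to_date() - start.to_date()).days
    if delta < 0:
        return Exclusion.NEGATIVE_INTERVAL
    return delta


def collect_onsets(
    caseset: CaseSet, dictionary: DrugDictionary
) -> tuple[list[OnsetRecord], Counter]:
    """Onset records for every includable case plus exclusion tallies."""
    records: list[OnsetRecord] = []
    excluded: Counter = Counter()
    for case in caseset:
        result = onset_days(case, caseset.drug, dictionary)
        if isinstance(result, Exclusion):
            excluded[result] += 1
            continue
        records.append(
            OnsetRecord(
                caseid=case.caseid,
                drug=caseset.drug,
                onset_days=result,
                sex=case.sex,
                age_years=case.age_years,
            )
        )
    return records, excluded


def lower_median(values: Sequence[int]) -> int:
    """Order statistic at ceil(n/2); for odd n the ordinary median."""
    if not values:
        raise ValueError("median of empty sequence")
    ordered = sorted(values)
    return ordered[math.ceil(len(ordered) / 2) - 1]


def _histogram(values: Sequence[int]) -> dict[str, int]:
    out: dict[str, int] = {}
    for lo, hi in HISTOGRAM_BINS:
        label = f"{lo}-{int(hi)}" if math.isfinite(hi) else f">{lo - 1}"
        out[label] = sum(1 for v in values if lo <= v <= hi)
    return out


def summarize_onset(
    records: Iterable[OnsetRecord],
    strata: Sequence[str] = ("overall", "sex", "age"),
) -> pd.DataFrame:
    """Median onset and interval histogram per stratum.

    Strata: overall, by sex (M/F/UNK) and by age bin.  Empty strata are
    omitted with a log line; histogram counts always sum to the stratum
    size.
    """
    recs = list(records)
    groups: list[tuple[str, list[OnsetRecord]]] = []
    if "overall" in strata:
        groups.append(("overall", recs))
    if "sex" in strata:
        for sex in ("M", "F", "UNK"):
            groups.append((f"sex={sex}", [r for r in recs if r.sex == sex]))
    if "age" in strata:
        for label in (*AGE_BIN_LABELS, "unknown"):
            groups.append(
                (f"age={label}", [r for r in recs if age_bin(r.age_years) == label])
            )
    rows = []
    for label, members in groups:
        if not members:
            log.info("onset stratum %s empty, omitted", label)
            continue
        values = [r.onset_days for r in members]
        row = {
            "stratum": label,
            "n": len(values),
            "median_days": lower_median(values),
        }
        row.update(_histogram(values))
        rows.append(row)
    return pd.DataFrame(rows)
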