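"""Descriptive summaries of selected case sets.

Tables mirror the standard pharmacovigilance report: age bins, sex,
reporter occupation, annual reporting trend, country ranking and
outcome distribution.  Every table is deterministic given its input,
states its denominator, and shows the unknown category explicitly.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import pandas as pd

from .cases import CaseSet
from .onset import AGE_BIN_LABELS, age_bin
from .records import CaseReport

OCCUPATION_LABELS = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health-professional",
    "HP": "health-professional",
    "CN": "consumer",
    "LW": "lawyer",
    "UNK": "unknown",
}

SERIOUS_OUTCOMES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI"})


def _all_cases(casesets: Mapping[str, CaseSet] | Iterable[CaseSet]) -> list[CaseReport]:
    sets = casesets.values() if isinstance(casesets, Mapping) else casesets
    seen: dict[str, CaseReport] = {}
    for cs in sets:
        for case in cs:
            seen[case.primaryid] = case
    return list(seen.values())


def _pct(count: int, denom: int) -> float:
    return round(100.0 * count / denom, 2) if denom else 0.0


def _table(dimension: str, counts: Counter, order: Iterable[str], denom: int) -> pd.DataFrame:
    rows = [
        {
            "dimension": dimension,
            "category": cat,
            "count": counts.get(cat, 0),
            "pct": _pct(counts.get(cat, 0), denom),
            "denominator": denom,
        }
        for cat in order
    ]
    return pd.DataFrame(rows)


def demographic_summary(
    casesets: Mapping[str, CaseSet] | Iterable[CaseSet]
) -> dict[str, pd.DataFrame]:
    """Age-bin, sex and reporter-occupation tables over distinct reports.

    Denominator is the number of distinct selected reports; the unknown
    category is always shown.
    """
    cases = _all_cases(casesets)
    denom = len(cases)
    ages = Counter(age_bin(c.age_years) for c in cases)
    sexes = Counter(c.sex for c in cases)
    occ = Counter(c.occupation for c in cases)
    return {
        "age": _table("age", ages, (*AGE_BIN_LABELS, "unknown"), denom),
        "sex": _table("sex", sexes, ("M", "F", "UNK"), denom),
        "occupation": _table(
            "occupation", occ, ("MD", "PH", "OT", "HP", "CN", "LW", "UNK"), denom
        ),
    }


def annual_trend(
    casesets: Mapping[str, CaseSet] | Iterable[CaseSet]
) -> pd.DataFrame:
    """Report counts keyed by (drug, receipt year)."""
    sets = casesets.values() if isinstance(casesets, Mapping) else list(casesets)
    rows = []
    for cs in sets:
        years = Counter(c.receipt_date.year for c in cs)
        for year in sorted(years):
            rows.append({"drug": cs.drug, "year": year, "reports": years[year]})
    return pd.DataFrame(rows, columns=["drug", "year", "reports"])


def country_ranking(
    casesets: Mapping[str, CaseSet] | Iterable[CaseSet], top: int = 10
) -> pd.DataFrame:
    """Top reporting countries over distinct reports."""
    cases = _all_cases(casesets)
    denom = len(cases)
    counts = Counter(c.country for c in cases)
    rows = [
        {"country": country, "count": n, "pct": _pct(n, denom), "denominator": denom}
        for country, n in counts.most_common(top)
    ]
    return pd.DataFrame(rows, columns=["country", "count", "pct", "denominator"])


def outcome_distribution(
    casesets: Mapping[str, CaseSet] | Iterable[CaseSet]
) -> pd.DataFrame:
    """Outcome-code distribution over distinct reports.

    A report with several outcome codes contributes to each; reports
    with no outcome appear as ``none-reported``.  The ``serious`` rollup
    counts reports with at least one of DE/LT/HO/DS/CA/RI.
    """
    cases = _all_cases(casesets)
    denom = len(cases)
    counts: Counter = Counter()
    serious = 0
    for c in cases:
        if not c.outcomes:
            counts["none-reported"] += 1
        for code in c.outcomes:
            counts[code] += 1
        if c.outcomes & SERIOUS_OUTCOMES:
            serious += 1
    order = ["DE", "LT", "HO", "DS", "CA", "RI", "OT", "none-reported"]
    rows = [
        {
            "outcome": code,
            "count": counts.get(code, 0),
            "pct": _pct(counts.get(code, 0), denom),
            "denominator": denom,
        }
        for code in order
    ]
    rows.append(
        {
            "outcome": "serious (any of DE/LT/HO/DS/CA/RI)",
            "count": serious,
            "pct": _pct(serious, denom),
            "denominator": denom,
        }
    )
    return pd.DataFrame(rows, columns=["outcome", "count", "pct", "denominator"])
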