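"""Disproportionality statistics on the classic 2x2 report table.

For a target drug D and event set E the deduplicated report universe is
partitioned into

    a = reports with D as primary suspect and the event
    b = reports with D as primary suspect, other events
    c = other reports with the event
    d = other reports, other events

and four signal statistics are computed:

* ROR = ad/bc with a Wald 95% CI on the log scale,
* PRR = (a/(a+b)) / (c/(c+d)) with the Pearson chi-squared statistic,
* the BCPNN information component IC = log2( a·N / ((a+c)(a+b)) ) with
  IC025 from a credibility-bound approximation
  IC − 3.3·a^(−1/2) − 2·a^(−3/2),
* EBGM = a·N / ((a+c)(a+b)) (the observed/expected relative reporting
  ratio, i.e. 2^IC) with a log-normal-style 95% interval using the same
  standard error as the ROR.

Signal criteria (the conventional screening thresholds): ROR lower CI
bound > 1 with a >= 3; PRR >= 2 with chi2 >= 4 and a >= 3; IC025 > 0;
EBGM05 > 2 with a > 0.  A pair is called a positive signal when all four
criteria agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cases import CaseSet, DrugDictionary, SMQTermSet, case_has_drug, match_drug
from .records import CaseReport

Z95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """a/b/c/d report counts; N = a+b+c+d."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def haldane(self) -> tuple[float, float, float, float]:
        """Cells with the 0.5 continuity correction applied to all four."""
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class SignalStats:
    drug: str
    table: ContingencyTable
    ror: Optional[float] = None
    ror_lo95: Optional[float] = None
    ror_hi95: Optional[float] = None
    prr: Optional[float] = None
    chi2: Optional[float] = None
    ic: Optional[float] = None
    ic025: Optional[float] = None
    ebgm: Optional[float] = None
    ebgm05: Optional[float] = None
    ebgm95: Optional[float] = None
    ror_signal: bool = False
    prr_signal: bool = False
    bcpnn_signal: bool = False
    mgps_signal: bool = False
    corrected: bool = False
    reasons: tuple[str, ...] = ()

    @property
    def positive_signal(self) -> bool:
        return (
            self.ror_signal
            and self.prr_signal
            and self.bcpnn_signal
            and self.mgps_signal
        )


def build_table(
    all_cases: Iterable[CaseReport],
    event_cases: Iterable[CaseReport] | Iterable[str] | frozenset[str],
    target_drug: str,
    dictionary: DrugDictionary,
) -> ContingencyTable:
    """Partition the deduplicated universe by (PS drug is target) x
    (report is an event report).

    *event_cases* may be CaseReports or primaryid strings and must be a
    subset of *all_cases*.
    """
    event_ids = frozenset(
        c.primaryid if isinstance(c, CaseReport) else str(c) for c in event_cases
    )
    a = b = c_ = d = 0
    total = 0
    for case in all_cases:
        total += 1
        is_target = case_has_drug(case, target_drug.upper(), dictionary)
        is_event = case.primaryid in event_ids
        if is_target and is_event:
            a += 1
        elif is_target:
            b += 1
        elif is_event:
            c_ += 1
        else:
            d += 1
    if total == 0:
        raise ValueError("empty report universe")
    return ContingencyTable(a, b, c_, d)


def _wald_se(a: float, b: float, c: float, d: float) -> float:
    return math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def compute_ror(
    t: ContingencyTable,
) -> tuple[Optional[float], Optional[float], Optional[float], bool]:
    """(ROR, lo95, hi95, corrected); Haldane 0.5 applied on zero cells."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        return None, None, None, False
    corrected = t.has_zero_cell
    a, b, c, d = t.haldane() if corrected else (t.a, t.b, t.c, t.d)
    ror = (a * d) / (b * c)
    se = _wald_se(a, b, c, d)
    lo = ror * math.exp(-Z95 * se)
    hi = ror * math.exp(Z95 * se)
    return ror, lo, hi, corrected


def compute_prr_chi2(
    t: ContingencyTable,
) -> tuple[Optional[float], Optional[float]]:
    """PRR and the (uncorrected) Pearson chi-squared statistic."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    if a + b == 0 or c + d == 0 or c == 0:
        return None, None
    prr = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = ((a * d - b * c) ** 2 * n) / denom if denom else None
    return prr, chi2


def ic_lcb(ic: float, a: float) -> float:
    """Lower 95% credibility bound approximation for the information
    component: IC − 3.3·a^(−1/2) − 2·a^(−3/2)."""
    return ic - 3.3 * a ** -0.5 - 2.0 * a ** -1.5


def compute_ic(t: ContingencyTable) -> tuple[Optional[float], Optional[float]]:
    """Information component log2(a·N/((a+c)(a+b))) and IC025."""
    if t.a == 0:
        return None, None
    ic = math.log2(t.a * t.n / ((t.a + t.c) * (t.a + t.b)))
    return ic, ic_lcb(ic, t.a)


def compute_ebgm(
    t: ContingencyTable,
) -> tuple[Optional[float], Optional[float], Optional[float], bool]:
    """(EBGM, EBGM05, EBGM95, corrected).

    EBGM here is the observed/expected relative reporting ratio
    a·N/((a+c)(a+b)) — identically 2^IC — with interval bounds
    exp(ln EBGM ± 1.96·se) where se is the Wald standard error of the
    2x2 table (zero cells Haldane-corrected for the interval only).
    """
    if t.a == 0:
        return None, None, None, False
    ebgm = t.a * t.n / ((t.a + t.c) * (t.a + t.b))
    corrected = t.has_zero_cell
    a, b, c, d = t.haldane() if corrected else (t.a, t.b, t.c, t.d)
    se = _wald_se(a, b, c, d)
    return ebgm, ebgm * math.exp(-Z95 * se), ebgm * math.exp(Z95 * se), corrected


def evaluate_criteria(stats: SignalStats) -> SignalStats:
    """Apply the four screening thresholds and set the per-method flags."""
    t = stats.table
    ror_sig = (
        stats.ror_lo95 is not None and stats.ror_lo95 > 1.0 and t.a >= 3
    )
    prr_sig = (
        stats.prr is not None
        and stats.chi2 is not None
        and stats.prr >= 2.0
        and stats.chi2 >= 4.0
        and t.a >= 3
    )
    bcpnn_sig = stats.ic025 is not None and stats.ic025 > 0.0
    mgps_sig = stats.ebgm05 is not None and stats.ebgm05 > 2.0 and t.a > 0
    return replace(
        stats,
        ror_signal=ror_sig,
        prr_signal=prr_sig,
        bcpnn_signal=bcpnn_sig,
        mgps_signal=mgps_sig,
    )


def signal_stats(t: ContingencyTable, drug: str = "") -> SignalStats:
    """All four statistics with bounds and flags for one table."""
    reasons: list[str] = []
    ror, lo, hi, corr_r = compute_ror(t)
    if ror is None:
        reasons.append("ror undefined: empty margin")
    prr, chi2 = compute_prr_chi2(t)
    if prr is None:
        reasons.append("prr undefined: zero denominator")
    ic, ic025 = compute_ic(t)
    if ic is None:
        reasons.append("ic undefined: a = 0")
    ebgm, eb05, eb95, corr_e = compute_ebgm(t)
    if ebgm is None:
        reasons.append("ebgm undefined: a = 0")
    stats = SignalStats(
        drug=drug,
        table=t,
        ror=ror,
        ror_lo95=lo,
        ror_hi95=hi,
        prr=prr,
        chi2=chi2,
        ic=ic,
        ic025=ic025,
        ebgm=ebgm,
        ebgm05=eb05,
        ebgm95=eb95,
        corrected=corr_r or corr_e,
        reasons=tuple(reasons),
    )
    return evaluate_criteria(stats)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal-style half-up rounding used for display columns."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def run_screen(
    universe: Sequence[CaseReport],
    casesets: Mapping[str, CaseSet] | Iterable[CaseSet],
    dictionary: DrugDictionary,
    smq: SMQTermSet,
) -> pd.DataFrame:
    """One row of statistics and flags per target drug.

    The event side of each 2x2 table is every report in *universe* with
    at least one SMQ-matched reaction (not merely the target drug's
    cases), so c counts the background event frequency.  Full-precision
    columns plus 2-decimal half-up display columns (suffix ``_2dp``);
    the ``n`` column equals the case-set size (= a).
    """
    if isinstance(casesets, Mapping):
        sets = list(casesets.values())
    else:
        sets = list(casesets)
    event_ids = frozenset(
        c.primaryid
        for c in universe
        if any(pt in smq for pt in c.reactions)
    )
    rows = []
    for cs in sets:
        t = build_table(universe, event_ids, cs.drug, dictionary)
        s = signal_stats(t, drug=cs.drug)
        row = {
            "drug": cs.drug,
            "n": t.a,
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
            "ror": s.ror,
            "ror_lo95": s.ror_lo95,
            "ror_hi95": s.ror_hi95,
            "prr": s.prr,
            "chi2": s.chi2,
            "ic": s.ic,
            "ic025": s.ic025,
            "ebgm": s.ebgm,
            "ebgm05": s.ebgm05,
            "ebgm95": s.ebgm95,
            "ror_signal": s.ror_signal,
            "prr_signal": s.prr_signal,
            "bcpnn_signal": s.bcpnn_signal,
            "mgps_signal": s.mgps_signal,
            "positive_signal": s.positive_signal,
            "correction_flag": s.corrected,
        }
        for col in ("ror", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05"):
            v = row[col]
            row[f"{col}_2dp"] = round_half_up(v, 2) if v is not None else None
        rows.append(row)
    return pd.DataFrame(rows)


def contingency_grid(
    cases: Sequence[CaseReport],
    drugs: Sequence[str],
    events: Sequence[str],
    smq_norm: Optional[SMQTermSet] = None,
) -> dict[tuple[str, str], ContingencyTable]:
    """2x2 tables for every (drug, event PT) pair in one pass.

    Drug membership is exact-name on the PS entries (suitable for
    synthetic corpora where names are canonical); event membership is
    PT-string equality after the -aemia/-emia normalization.  Used for
    large calibration screens where per-pair table construction would
    be quadratic.
    """
    from .cases import _norm_pt  # shared PT normalization

    n = len(cases)
    drug_idx = {d.upper(): i for i, d in enumerate(drugs)}
    event_idx = {_norm_pt(e): j for j, e in enumerate(events)}
    dmat = np.zeros((n, len(drugs)), dtype=bool)
    emat = np.zeros((n, len(events)), dtype=bool)
    for i, case in enumerate(cases):
        for entry in case.drugs:
            if entry.role == "PS":
                k = drug_idx.get(entry.verbatim_name.upper())
                if k is not None:
                    dmat[i, k] = True
        for pt in case.reactions:
            j = event_idx.get(_norm_pt(pt))
            if j is not None:
                emat[i, j] = True
    a = dmat.T.astype(np.int64) @ emat.astype(np.int64)
    n_drug = dmat.sum(axis=0)
    n_event = emat.sum(axis=0)
    out: dict[tuple[str, str], ContingencyTable] = {}
    for d, i in drug_idx.items():
        for e_orig, j in zip(events, range(len(events))):
            aa = int(a[i, j])
            bb = int(n_drug[i]) - aa
            cc = int(n_event[j]) - aa
            dd = n - aa - bb - cc
            out[(d, e_orig)] = ContingencyTable(aa, bb, cc, dd)
    return out
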