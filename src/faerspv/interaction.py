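"""Drug-drug interaction screening with the Omega shrinkage measure.

Reports are stratified by presence/absence of two drugs: drug 1 as
primary suspect, drug 2 as a concomitant/secondary medication (roles SS,
C or I).  With n_ij. the report count in stratum (i, j) and n_ij1 the
events among them, the observed event rates are f_ij = n_ij1 / n_ij. and
the no-interaction expectation for the double-exposed stratum follows
the inverse-rate ("1/g") model

    1 / f11_0 = 1/f10 + 1/f01 - 1/f00

(floored at max(f10, f01) when the inverse combination is non-positive).
The expected count is E111 = n_11. * f11_0, and the shrinkage-
regularized interaction statistic is

    Omega    = log2( (n111 + 0.5) / (E111 + 0.5) )
    Omega025 = Omega - 1.96 / (ln 2 * sqrt(n111))

A combination is called a positive interaction signal when Omega025 > 0.
The +0.5 terms shrink small-count estimates toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cases import DrugDictionary, SMQTermSet, case_has_drug
from .records import CaseReport

LN2 = math.log(2.0)
CONCOMITANT_ROLES = ("SS", "C", "I")
LOW_COUNT_THRESHOLD = 3


@dataclass(frozen=True)
class InteractionCounts:
    """2x2x2 stratified counts: n_ij_dot reports, n_ij_1 with the event."""

    n11_dot: int
    n10_dot: int
    n01_dot: int
    n00_dot: int
    n11_1: int
    n10_1: int
    n01_1: int
    n00_1: int

    def __post_init__(self) -> None:
        for ij in ("11", "10", "01", "00"):
            tot = getattr(self, f"n{ij}_dot")
            ev = getattr(self, f"n{ij}_1")
            if ev < 0 or tot < 0 or ev > tot:
                raise ValueError(f"stratum {ij}: need 0 <= n{ij}_1 <= n{ij}_dot")

    @property
    def n111(self) -> int:
        return self.n11_1

    @property
    def total(self) -> int:
        return self.n11_dot + self.n10_dot + self.n01_dot + self.n00_dot


@dataclass(frozen=True)
class InteractionStats:
    drug1: str
    drug2: str
    counts: InteractionCounts
    e111: float
    omega: float
    omega025: Optional[float]
    low_count_flag: bool

    @property
    def positive_signal(self) -> bool:
        return self.omega025 is not None and self.omega025 > 0.0


def omega_lcb(omega: float, n111: float) -> float:
    """Lower 95% credibility bound: Omega - 1.96/(ln 2 * sqrt(n111))."""
    return omega - 1.96 / (LN2 * math.sqrt(n111))


def build_interaction_counts(
    universe: Iterable[CaseReport],
    drug1: str,
    drug2: str,
    event_pts: SMQTermSet | frozenset[str],
    dictionary: DrugDictionary,
    drug2_dictionary: Optional[DrugDictionary] = None,
) -> InteractionCounts:
    """Stratify the deduplicated universe by (drug1 as PS) x (drug2 as
    concomitant) and count event reports per stratum.

    *drug2* need not be in the main dictionary; by default it is matched
    through a single-entry dictionary built from its own name.
    """
    if drug2_dictionary is None:
        drug2_dictionary = DrugDictionary(synonyms={drug2.upper(): ()})
    if isinstance(event_pts, SMQTermSet):
        def is_event(case: CaseReport) -> bool:
            return any(pt in event_pts for pt in case.reactions)
    else:
        pts = frozenset(p.lower() for p in event_pts)

        def is_event(case: CaseReport) -> bool:
            return any(pt.lower() in pts for pt in case.reactions)

    dots = {"11": 0, "10": 0, "01": 0, "00": 0}
    ones = {"11": 0, "10": 0, "01": 0, "00": 0}
    for case in universe:
        i = int(case_has_drug(case, drug1.upper(), dictionary, roles=("PS",)))
        j = int(
            case_has_drug(
                case, drug2.upper(), drug2_dictionary, roles=CONCOMITANT_ROLES
            )
        )
        key = f"{i}{j}"
        dots[key] += 1
        if is_event(case):
            ones[key] += 1
    return InteractionCounts(
        n11_dot=dots["11"],
        n10_dot=dots["10"],
        n01_dot=dots["01"],
        n00_dot=dots["00"],
        n11_1=ones["11"],
        n10_1=ones["10"],
        n01_1=ones["01"],
        n00_1=ones["00"],
    )


def expected_rate(f10: float, f01: float, f00: float) -> float:
    """No-interaction event rate for the double-exposed stratum.

    Inverse-rate combination 1/f11_0 = 1/f10 + 1/f01 - 1/f00, floored at
    max(f10, f01) when the combination is non-positive or undefined
    (e.g. a zero single-exposure rate).
    """
    floor = max(f10, f01)
    if f10 <= 0.0 or f01 <= 0.0:
        return floor
    if f00 <= 0.0:
        inv = 1.0 / f10 + 1.0 / f01
    else:
        inv = 1.0 / f10 + 1.0 / f01 - 1.0 / f00
    if inv <= 0.0:
        return floor
    return min(1.0 / inv, 1.0)  # a rate cannot exceed 1


def compute_omega(
    counts: InteractionCounts, drug1: str = "", drug2: str = ""
) -> InteractionStats:
    """Omega, Omega025 and E111 for one stratified count set.

    Requires every stratum to be populated (n_ij_dot > 0).  With
    n111 = 0 the point estimate is still defined through the +0.5
    shrinkage but the credibility bound is not (returned as None).
    """
    for ij in ("11", "10", "01", "00"):
        if getattr(counts, f"n{ij}_dot") == 0:
            raise ValueError(f"empty stratum {ij}: cannot estimate rates")
    f10 = counts.n10_1 / counts.n10_dot
    f01 = counts.n01_1 / counts.n01_dot
    f00 = counts.n00_1 / counts.n00_dot
    f11_0 = expected_rate(f10, f01, f00)
    e111 = counts.n11_dot * f11_0
    omega = math.log2((counts.n111 + 0.5) / (e111 + 0.5))
    omega025 = omega_lcb(omega, counts.n111) if counts.n111 > 0 else None
    return InteractionStats(
        drug1=drug1,
        drug2=drug2,
        counts=counts,
        e111=e111,
        omega=omega,
        omega025=omega025,
        low_count_flag=counts.n111 < LOW_COUNT_THRESHOLD,
    )


def interaction_grid(
    cases: Sequence[CaseReport],
    drugs1: Sequence[str],
    drugs2: Sequence[str],
    event_pts: frozenset[str] | set[str],
) -> dict[tuple[str, str], InteractionCounts]:
    """Stratified counts for every (drug1, drug2) combination in one pass.

    Exact-name matching on verbatim drug names (suitable for synthetic
    corpora with canonical names): drug1 membership needs role PS, drug2
    membership any of SS/C/I.  Used for large calibration screens where
    per-combination counting would be quadratic.
    """
    import numpy as np

    n = len(cases)
    idx1 = {d.upper(): i for i, d in enumerate(drugs1)}
    idx2 = {d.upper(): j for j, d in enumerate(drugs2)}
    pts = frozenset(p.lower() for p in event_pts)
    m1 = np.zeros((n, len(drugs1)), dtype=np.int64)
    m2 = np.zeros((n, len(drugs2)), dtype=np.int64)
    ev = np.zeros(n, dtype=np.int64)
    for r, case in enumerate(cases):
        for entry in case.drugs:
            name = entry.verbatim_name.upper()
            if entry.role == "PS":
                i = idx1.get(name)
                if i is not None:
                    m1[r, i] = 1
            elif entry.role in CONCOMITANT_ROLES:
                j = idx2.get(name)
                if j is not None:
                    m2[r, j] = 1
        if any(pt.lower() in pts for pt in case.reactions):
            ev[r] = 1
    n11 = m1.T @ m2
    n11e = (m1 * ev[:, None]).T @ m2
    r1 = m1.sum(axis=0)
    r1e = (m1 * ev[:, None]).sum(axis=0)
    c2 = m2.sum(axis=0)
    c2e = (m2 * ev[:, None]).sum(axis=0)
    tot, tote = n, int(ev.sum())
    out: dict[tuple[str, str], InteractionCounts] = {}
    for d1, i in idx1.items():
        for d2, j in idx2.items():
            a_dot = int(n11[i, j])
            a_ev = int(n11e[i, j])
            n10_dot = int(r1[i]) - a_dot
            n10_ev = int(r1e[i]) - a_ev
            n01_dot = int(c2[j]) - a_dot
            n01_ev = int(c2e[j]) - a_ev
            n00_dot = tot - a_dot - n10_dot - n01_dot
            n00_ev = tote - a_ev - n10_ev - n01_ev
            out[(d1, d2)] = InteractionCounts(
                n11_dot=a_dot,
                n10_dot=n10_dot,
                n01_dot=n01_dot,
                n00_dot=n00_dot,
                n11_1=a_ev,
                n10_1=n10_ev,
                n01_1=n01_ev,
                n00_1=n00_ev,
            )
    return out


def interaction_screen(
    universe: Sequence[CaseReport],
    drug1: str,
    partners: Sequence[str],
    event_pts: SMQTermSet | frozenset[str],
    dictionary: DrugDictionary,
) -> pd.DataFrame:
    """Omega statistics for drug1 against each candidate partner."""
    rows = []
    for drug2 in partners:
        c = build_interaction_counts(universe, drug1, drug2, event_pts, dictionary)
        try:
            s = compute_omega(c, drug1=drug1.upper(), drug2=drug2.upper())
        except ValueError as exc:
            rows.append(
                {
                    "drug1": drug1.upper(),
                    "drug2": drug2.upper(),
                    "n111": c.n111,
                    "e111": None,
                    "omega": None,
                    "omega025": None,
                    "low_count_flag": True,
                    "reason": str(exc),
                }
            )
            continue
        rows.append(
            {
                "drug1": s.drug1,
                "drug2": s.drug2,
                "n111": c.n111,
                "e111": s.e111,
                "omega": s.omega,
                "omega025": s.omega025,
                "low_count_flag": s.low_count_flag,
                "reason": "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug1",
            "drug2",
            "n111",
            "e111",
            "omega",
            "omega025",
            "low_count_flag",
            "reason",
        ],
    )
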