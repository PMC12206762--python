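"""Case definition: SMQ term matching and target-drug selection.

Hyponatremia cases are defined by the narrow scope of the MedDRA
"Hyponatremia (SMQ)" — 15 preferred terms shipped with the package —
among deduplicated reports whose *primary suspect* (role PS) drug is one
of the target PD-1/PD-L1 inhibitors.  Matching is case-insensitive and
tolerant of the British/American -aemia/-emia spelling split; drug names
are matched by whole-token containment against a small editable synonym
dictionary (trade names and development codes).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .records import CaseReport

_TOKEN_RE = re.compile(r"[A-Z0-9]+")


def _norm_pt(term: str) -> str:
    """Canonical key for PT comparison: lowercase, -aemia → -emia."""
    t = term.strip().lower()
    t = t.replace("aemia", "emia").replace("aemic", "emic")
    return t


def _tokens(name: str) -> tuple[str, ...]:
    return tuple(_TOKEN_RE.findall(name.upper()))


@dataclass(frozen=True)
class SMQTermSet:
    """A named set of MedDRA preferred terms with codes."""

    name: str
    terms: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.terms]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate MedDRA codes in SMQ term set")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def preferred_terms(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.terms)

    def match(self, reported_term: str) -> Optional[int]:
        """MedDRA code of the matching PT, or None."""
        key = _norm_pt(reported_term)
        return self._index().get(key)

    def __contains__(self, reported_term: str) -> bool:
        return self.match(reported_term) is not None

    def _index(self) -> Mapping[str, int]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {_norm_pt(t): c for c, t in self.terms}
            object.__setattr__(self, "_idx", idx)
        return idx


def load_smq() -> SMQTermSet:
    """The narrow-scope Hyponatremia (SMQ) term set (15 PTs)."""
    src = resources.files("faerspv.data") / "hyponatremia_smq_narrow.csv"
    with src.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return SMQTermSet(
        name="Hyponatremia (SMQ), narrow",
        terms=tuple((int(r["code"]), r["preferred_term"]) for r in rows),
    )


@dataclass(frozen=True)
class DrugDictionary:
    """Canonical drug name → synonym set, matched token-wise."""

    synonyms: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for canon, syns in self.synonyms.items():
            for s in (canon, *syns):
                key = " ".join(_tokens(s))
                if key in seen and seen[key] != canon:
                    raise ValueError(
                        f"synonym {s!r} maps to both {seen[key]} and {canon}"
                    )
                seen[key] = canon

    def canonical_names(self) -> tuple[str, ...]:
        return tuple(self.synonyms)

    def patterns(self) -> list[tuple[tuple[str, ...], str]]:
        pats = getattr(self, "_patterns", None)
        if pats is None:
            pats = []
            for canon, syns in self.synonyms.items():
                for s in (canon, *syns):
                    pats.append((_tokens(s), canon))
            object.__setattr__(self, "_patterns", pats)
        return pats

    def _memo(self) -> dict:
        memo = getattr(self, "_match_memo", None)
        if memo is None:
            memo = {}
            object.__setattr__(self, "_match_memo", memo)
        return memo


def load_drug_dictionary(path: str | Path | None = None) -> DrugDictionary:
    """Load the synonym dictionary (packaged default, or a YAML file)."""
    if path is None:
        src = resources.files("faerspv.data") / "drug_synonyms.yaml"
        with src.open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    return DrugDictionary(
        synonyms={
            str(k).upper(): tuple(str(v).upper() for v in (vals or ()))
            for k, vals in data.items()
        }
    )


def _contains_subseq(hay: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    if not needle:
        return False
    n = len(needle)
    return any(hay[i : i + n] == needle for i in range(len(hay) - n + 1))


def match_drug(verbatim_name: str, dictionary: DrugDictionary) -> Optional[str]:
    """Map a verbatim drug-name string to a canonical name, or None.

    The verbatim string is uppercased and punctuation-split into tokens;
    a canonical name or synonym matches when its tokens appear as a
    contiguous run ("OPDIVO 240 MG" → NIVOLUMAB, and a combination
    string like "NIVOLUMAB AND IPILIMUMAB" still matches NIVOLUMAB).
    """
    memo = dictionary._memo()
    if verbatim_name in memo:
        return memo[verbatim_name]
    hay = _tokens(verbatim_name)
    result = None
    if hay:
        for needle, canon in dictionary.patterns():
            if _contains_subseq(hay, needle):
                result = canon
                break
    memo[verbatim_name] = result
    return result


def case_has_drug(
    case: CaseReport,
    target: str,
    dictionary: DrugDictionary,
    roles: Iterable[str] = ("PS",),
) -> bool:
    roles = tuple(roles)
    for entry in case.drugs:
        if entry.role in roles and match_drug(entry.verbatim_name, dictionary) == target:
            return True
    return False


@dataclass
class CaseSet:
    """Cases selected for one target drug, with their matched SMQ PTs."""

    drug: str
    cases: list[CaseReport] = field(default_factory=list)
    matched_pts: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def primaryids(self) -> frozenset[str]:
        return frozenset(c.primaryid for c in self.cases)


def select_cases(
    cases: Iterable[CaseReport],
    smq: SMQTermSet,
    dictionary: DrugDictionary,
    target_drug: str,
    roles: Iterable[str] = ("PS",),
) -> CaseSet:
    """Select reports with the target drug in a qualifying role and at
    least one SMQ-matched reaction PT.

    A case is counted once however many SMQ PTs it lists; the matched
    PTs (duplicates within a case collapsed) are recorded per case.
    """
    target = target_drug.upper()
    out = CaseSet(drug=target)
    for case in cases:
        if not case_has_drug(case, target, dictionary, roles):
            continue
        matched = frozenset(
            pt for pt in case.reactions if pt in smq
        )
        if not matched:
            continue
        out.cases.append(case)
        out.matched_pts[case.primaryid] = frozenset(
            _canonical_pt(smq, pt) for pt in matched
        )
    return out


def _canonical_pt(smq: SMQTermSet, reported: str) -> str:
    code = smq.match(reported)
    for c, t in smq.terms:
        if c == code:
            return t
    return reported


def pt_breakdown(caseset: CaseSet) -> pd.DataFrame:
    """Per-PT report counts and proportions within one drug's case set.

    A case matching k SMQ PTs contributes to k rows, so the count column
    can sum to more than the case count; proportions use the number of
    cases as denominator (mirroring per-drug percentage reporting).
    """
    n = len(caseset)
    counts: dict[str, int] = {}
    for pts in caseset.matched_pts.values():
        for pt in pts:
            counts[pt] = counts.get(pt, 0) + 1
    rows = [
        {
            "drug": caseset.drug,
            "preferred_term": pt,
            "reports": cnt,
            "proportion_pct": round(100.0 * cnt / n, 2) if n else 0.0,
        }
        for pt, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(
        rows, columns=["drug", "preferred_term", "reports", "proportion_pct"]
    )
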