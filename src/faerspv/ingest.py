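"""Reading FAERS-format quarterly ASCII files and assembling case reports.

FAERS quarterly extracts are ``$``-delimited text tables with a header
row.  Seven tables share the ``primaryid`` report key: DEMO (one row per
report), DRUG, REAC, THER, OUTC, INDI and RPSR.  This module parses the
files, joins them into :class:`~faerspv.records.CaseReport` objects and
applies the standard FAERS deduplication rule (one version per case:
latest FDA receipt date, ties broken on the larger primaryid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .records import (
    CaseReport,
    DrugEntry,
    PartialDate,
    ROLE_CODES,
    age_to_years,
    parse_partial_date,
    primaryid_sort_key,
)

log = logging.getLogger(__name__)

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "THER", "OUTC", "INDI", "RPSR")
REQUIRED_TABLES = ("DEMO", "DRUG", "REAC")

#: minimum columns each table must expose (the canonical post-2012 dialect)
REQUIRED_COLUMNS = {
    "DEMO": ("primaryid", "caseid", "fda_dt"),
    "DRUG": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "caseid", "pt"),
    "THER": ("primaryid", "caseid", "dsg_drug_seq", "start_dt"),
    "OUTC": ("primaryid", "caseid", "outc_cod"),
    "INDI": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
    "RPSR": ("primaryid", "caseid", "rpsr_cod"),
}


class FaersFormatError(ValueError):
    """Raised when a quarter directory does not look like FAERS output."""


@dataclass
class RawQuarter:
    """Parsed rows of one quarter, keyed by table name."""

    tables: dict[str, list[dict[str, str]]] = field(default_factory=dict)
    skipped_rows: dict[str, int] = field(default_factory=dict)
    source: Optional[Path] = None

    def rows(self, name: str) -> list[dict[str, str]]:
        return self.tables.get(name, [])


@dataclass
class AssembledCases:
    """Case collection plus join bookkeeping (orphan rows excluded)."""

    cases: list[CaseReport]
    orphan_rows: dict[str, int] = field(default_factory=dict)

    def __iter__(self) -> Iterator[CaseReport]:
        return iter(self.cases)

    def __len__(self) -> int:
        return len(self.cases)

    def __getitem__(self, i):
        return self.cases[i]


def _parse_file(path: Path, table: str) -> tuple[list[dict[str, str]], int]:
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n").rstrip("\r")
        if not header_line:
            raise FaersFormatError(f"{path}: empty file")
        header = [h.strip().lower() for h in header_line.split("$")]
        missing = [c for c in REQUIRED_COLUMNS[table] if c not in header]
        if missing:
            raise FaersFormatError(
                f"{path}: header lacks required columns {missing}; "
                f"got {header}"
            )
        rows: list[dict[str, str]] = []
        skipped = 0
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("$")
            if len(parts) != len(header):
                skipped += 1
                continue
            rows.append(dict(zip(header, parts)))
    if skipped:
        log.warning("%s: skipped %d malformed rows", path, skipped)
    return rows, skipped


def read_quarter(directory: str | Path) -> RawQuarter:
    """Read all FAERS tables found in *directory*.

    DEMO, DRUG and REAC are mandatory; the others default to empty.
    Rows whose field count disagrees with the header are skipped and
    counted in :attr:`RawQuarter.skipped_rows`.
    """
    directory = Path(directory)
    raw = RawQuarter(source=directory)
    for table in TABLE_NAMES:
        paths = sorted(directory.glob(f"{table}*.txt")) + sorted(
            directory.glob(f"{table.lower()}*.txt")
        )
        if not paths:
            if table in REQUIRED_TABLES:
                raise FaersFormatError(
                    f"{directory}: no {table}*.txt file found"
                )
            raw.tables[table] = []
            raw.skipped_rows[table] = 0
            continue
        rows: list[dict[str, str]] = []
        skipped = 0
        for p in paths:
            r, s = _parse_file(p, table)
            rows.extend(r)
            skipped += s
        raw.tables[table] = rows
        raw.skipped_rows[table] = skipped
    return raw


def _norm_code(value: str, allowed: Sequence[str]) -> str:
    v = (value or "").strip().upper()
    return v if v in allowed else "UNK"


def assemble_cases(*raws: RawQuarter) -> AssembledCases:
    """Join the seven tables into one CaseReport per primaryid.

    Ages are normalized through :func:`age_to_years`, dates through
    :func:`parse_partial_date`.  DRUG/REAC/OUTC rows whose primaryid has
    no DEMO row are orphans: they are excluded and counted.
    """
    demo: dict[str, dict[str, str]] = {}
    for raw in raws:
        for row in raw.rows("DEMO"):
            demo[row["primaryid"]] = row

    drugs: dict[str, list[dict[str, str]]] = {}
    reacs: dict[str, list[str]] = {}
    thers: dict[tuple[str, str], Optional[PartialDate]] = {}
    outcomes: dict[str, set[str]] = {}
    orphans = {"DRUG": 0, "REAC": 0, "OUTC": 0, "THER": 0}

    for raw in raws:
        for row in raw.rows("DRUG"):
            pid = row["primaryid"]
            if pid not in demo:
                orphans["DRUG"] += 1
                continue
            drugs.setdefault(pid, []).append(row)
        for row in raw.rows("REAC"):
            pid = row["primaryid"]
            if pid not in demo:
                orphans["REAC"] += 1
                continue
            reacs.setdefault(pid, []).append(row["pt"].strip())
        for row in raw.rows("THER"):
            pid = row["primaryid"]
            if pid not in demo:
                orphans["THER"] += 1
                continue
            thers[(pid, row["dsg_drug_seq"].strip())] = parse_partial_date(
                row["start_dt"]
            )
        for row in raw.rows("OUTC"):
            pid = row["primaryid"]
            if pid not in demo:
                orphans["OUTC"] += 1
                continue
            code = row["outc_cod"].strip().upper()
            if code:
                outcomes.setdefault(pid, set()).add(code)

    cases: list[CaseReport] = []
    for pid, drow in demo.items():
        receipt = parse_partial_date(drow.get("fda_dt", ""))
        if receipt is None:
            # a report without a receipt date cannot be deduplicated
            log.warning("primaryid %s: unparseable fda_dt, skipped", pid)
            continue
        entries: list[DrugEntry] = []
        drug_rows = drugs.get(pid, [])
        drug_rows.sort(key=lambda r: _seq_key(r.get("drug_seq", "")))
        for row in drug_rows:
            role = row.get("role_cod", "").strip().upper()
            if role not in ROLE_CODES:
                role = "C"
            entries.append(
                DrugEntry(
                    verbatim_name=row.get("drugname", "").strip(),
                    role=role,
                    therapy_start=thers.get(
                        (pid, row.get("drug_seq", "").strip())
                    ),
                )
            )
        age_raw = drow.get("age", "").strip()
        age_cod = drow.get("age_cod", "").strip().upper()
        cases.append(
            CaseReport(
                primaryid=pid,
                caseid=drow.get("caseid", "").strip(),
                receipt_date=receipt,
                event_date=parse_partial_date(drow.get("event_dt", "")),
                age=age_raw,
                age_cod=age_cod,
                age_years=age_to_years(age_raw, age_cod or None),
                sex=_norm_code(drow.get("sex", ""), ("M", "F")),
                occupation=_norm_code(
                    drow.get("occp_cod", ""), ("MD", "PH", "OT", "CN", "LW", "HP")
                ),
                country=(drow.get("occr_country", "").strip().upper() or "UNK"),
                outcomes=frozenset(outcomes.get(pid, ())),
                drugs=tuple(entries),
                reactions=tuple(reacs.get(pid, ())),
            )
        )
    cases.sort(key=lambda c: primaryid_sort_key(c.primaryid))
    return AssembledCases(cases=cases, orphan_rows=orphans)


def _seq_key(seq: str) -> tuple[int, int, str]:
    s = seq.strip()
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def deduplicate_cases(cases: Iterable[CaseReport]) -> list[CaseReport]:
    """Keep one version per caseid: latest receipt date, then largest
    primaryid (numeric comparison when both ids are numeric).

    Idempotent: applying it to already-unique collections is a no-op.
    """
    best: dict[str, CaseReport] = {}
    for case in cases:
        key = case.caseid
        prev = best.get(key)
        if prev is None:
            best[key] = case
            continue
        cand = (case.receipt_date.sort_key(), primaryid_sort_key(case.primaryid))
        incumbent = (
            prev.receipt_date.sort_key(),
            primaryid_sort_key(prev.primaryid),
        )
        if cand > incumbent:
            best[key] = case
    out = list(best.values())
    out.sort(key=lambda c: primaryid_sort_key(c.primaryid))
    return out
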