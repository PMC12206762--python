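"""Synthetic FAERS-like report generator with planted signals.

Real FAERS extracts cannot be redistributed, and headline counts depend
on a 20-year corpus; every downstream stage is therefore exercised on
generated report sets whose drug-event association strengths, onset
distributions, demographics, duplicate-version structure and missing-
data patterns are known exactly ("planted").

Generative model, per underlying case:

* each catalog drug appears independently with its marginal probability,
  and draws a role code (PS/SS/C/I) from its role distribution;
* each catalog event occurs independently with probability
  ``min(1, background x prod(RR of PS drugs for that event))`` — the
  planted relative reporting rate multiplies the background only when
  the drug is primary suspect, matching the 2x2 analyses downstream;
* onset days for the anchor (first) PS drug follow a log-normal with a
  configured median and log-scale sigma; the event date is the anchor
  therapy start plus the onset, and the FDA receipt date trails the
  event by a 7-120 day reporting delay;
* demographics (age with unit-code noise, sex, occupation, country,
  outcomes) are drawn from configured categorical distributions;
* a configurable fraction of cases is re-emitted as a second version
  (new primaryid, same caseid, receipt date 1-90 days later) to
  exercise deduplication, and dates/fields go missing or lose precision
  at configured rates.

The returned collection is built through the same normalization helpers
the ingest module uses, so generate -> write -> read -> assemble is an
exact round trip.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .ingest import AssembledCases
from .records import (
    CaseReport,
    DrugEntry,
    PartialDate,
    age_to_years,
    primaryid_sort_key,
)

DEFAULT_SEED = 20240612

#: filler (non-catalog, non-SMQ) reaction PTs so every report has >= 1
NOISE_PTS = ("Nausea", "Fatigue", "Pyrexia", "Diarrhoea", "Headache", "Rash")

#: verbatim-name variants used when name noise is enabled
NAME_VARIANTS: Mapping[str, tuple[str, ...]] = {
    "NIVOLUMAB": ("OPDIVO", "NIVOLUMAB 240 MG"),
    "PEMBROLIZUMAB": ("KEYTRUDA", "PEMBROLIZUMAB (MK-3475)"),
    "ATEZOLIZUMAB": ("TECENTRIQ", "ATEZOLIZUMAB 1200 MG"),
}

AGE_BIN_RANGES = {"<18": (1, 17), "18-44": (18, 44), "45-64": (45, 64), ">=65": (65, 90)}


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


def _check_dist(name: str, dist: Mapping[str, float]) -> None:
    if not dist:
        raise ValueError(f"{name} must be a non-empty distribution")
    for k, v in dist.items():
        _check_prob(f"{name}[{k!r}]", v)
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {sum(dist.values())})")


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: marginal appearance probability and role mix."""

    name: str
    p_report: float
    role_dist: Mapping[str, float] = field(
        default_factory=lambda: {"PS": 0.70, "SS": 0.10, "C": 0.15, "I": 0.05}
    )


@dataclass(frozen=True)
class EventSpec:
    """One catalog event PT and its background per-report probability."""

    pt: str
    background: float


@dataclass(frozen=True)
class OnsetSpec:
    """Log-normal onset model parameterized by median days and log-sigma."""

    median_days: float
    sigma: float = 1.0


@dataclass(frozen=True)
class Demographics:
    age_bin_dist: Mapping[str, float] = field(
        default_factory=lambda: {"<18": 0.01, "18-44": 0.11, "45-64": 0.31, ">=65": 0.57}
    )
    age_unit_noise: float = 0.10
    sex_dist: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.5518, "F": 0.3838, "UNK": 0.0644}
    )
    occupation_dist: Mapping[str, float] = field(
        default_factory=lambda: {
            "MD": 0.4733,
            "PH": 0.1868,
            "OT": 0.1500,
            "HP": 0.0400,
            "CN": 0.1200,
            "LW": 0.0100,
            "UNK": 0.0199,
        }
    )
    country_dist: Mapping[str, float] = field(
        default_factory=lambda: {
            "US": 0.3179,
            "JP": 0.2849,
            "FR": 0.0600,
            "DE": 0.0500,
            "GB": 0.0400,
            "CA": 0.0300,
            "IT": 0.0300,
            "ES": 0.0250,
            "AU": 0.0200,
            "CN": 0.0200,
            "UNK": 0.1222,
        }
    )
    #: distribution of the primary outcome per report ("none" = no OUTC row)
    outcome_dist: Mapping[str, float] = field(
        default_factory=lambda: {
            "HO": 0.400,
            "OT": 0.200,
            "DE": 0.120,
            "LT": 0.040,
            "DS": 0.020,
            "RI": 0.020,
            "CA": 0.005,
            "none": 0.195,
        }
    )
    #: probability a report carries a second, distinct outcome code
    second_outcome_rate: float = 0.10


def _default_drug_catalog() -> tuple[DrugSpec, ...]:
    target_roles = {"PS": 0.90, "SS": 0.04, "C": 0.05, "I": 0.01}
    conc_roles = {"PS": 0.15, "SS": 0.25, "C": 0.55, "I": 0.05}
    background_roles = {"PS": 0.30, "SS": 0.10, "C": 0.55, "I": 0.05}
    return (
        DrugSpec("NIVOLUMAB", 0.030, target_roles),
        DrugSpec("PEMBROLIZUMAB", 0.025, target_roles),
        DrugSpec("ATEZOLIZUMAB", 0.012, target_roles),
        DrugSpec("IPILIMUMAB", 0.020, conc_roles),
        DrugSpec("CABOZANTINIB", 0.005, conc_roles),
        DrugSpec("LENVATINIB", 0.006, conc_roles),
        DrugSpec("BEVACIZUMAB", 0.015, conc_roles),
        DrugSpec("ASPIRIN", 0.080, background_roles),
        DrugSpec("METFORMIN", 0.060, background_roles),
        DrugSpec("FUROSEMIDE", 0.040, background_roles),
    )


def _default_event_catalog() -> tuple[EventSpec, ...]:
    return (
        EventSpec("Hyponatremia", 0.0040),
        EventSpec("Blood sodium decreased", 0.0015),
        EventSpec("Inappropriate antidiuretic hormone secretion", 0.0008),
        EventSpec("Blood sodium abnormal", 0.0004),
    )


def _default_planted_rr() -> dict[tuple[str, str], float]:
    # association strengths on the study's scale: observed/expected
    # reporting ratios of roughly 2.5, 2.25 and 4.3 for the three drugs
    return {
        ("NIVOLUMAB", "Hyponatremia"): 2.56,
        ("PEMBROLIZUMAB", "Hyponatremia"): 2.25,
        ("ATEZOLIZUMAB", "Hyponatremia"): 4.28,
        ("NIVOLUMAB", "Blood sodium decreased"): 2.56,
        ("PEMBROLIZUMAB", "Blood sodium decreased"): 2.25,
        ("ATEZOLIZUMAB", "Blood sodium decreased"): 4.28,
    }


def _default_onset_models() -> dict[str, OnsetSpec]:
    return {
        "NIVOLUMAB": OnsetSpec(42.0),
        "PEMBROLIZUMAB": OnsetSpec(35.0),
        "ATEZOLIZUMAB": OnsetSpec(20.0),
    }


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic corpus."""

    n_reports: int = 20_000
    quarter_range: tuple[tuple[int, int], tuple[int, int]] = ((2019, 1), (2024, 2))
    drug_catalog: Sequence[DrugSpec] = field(default_factory=_default_drug_catalog)
    event_catalog: Sequence[EventSpec] = field(default_factory=_default_event_catalog)
    planted_rr: Mapping[tuple[str, str], float] = field(
        default_factory=_default_planted_rr
    )
    onset_models: Mapping[str, OnsetSpec] = field(default_factory=_default_onset_models)
    default_onset: OnsetSpec = OnsetSpec(60.0, 1.0)
    demographics: Demographics = field(default_factory=Demographics)
    duplicate_rate: float = 0.05
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.05,
            "event_dt": 0.12,
            "ther_start": 0.15,
        }
    )
    #: probability a surviving date is truncated to month / year precision
    date_month_rate: float = 0.05
    date_year_rate: float = 0.02
    #: probability a target drug is written under a trade-name variant
    name_noise: float = 0.10
    noise_pt_rate: float = 0.50
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        (y0, q0), (y1, q1) = self.quarter_range
        for q in (q0, q1):
            if q not in (1, 2, 3, 4):
                raise ValueError("quarter_range quarters must be in 1..4")
        if (y0, q0) > (y1, q1):
            raise ValueError("quarter_range start must not exceed end")
        names = [d.name.upper() for d in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ValueError("drug_catalog names must be unique")
        for d in self.drug_catalog:
            _check_prob(f"drug_catalog[{d.name}].p_report", d.p_report)
            _check_dist(f"drug_catalog[{d.name}].role_dist", d.role_dist)
            extra = set(d.role_dist) - {"PS", "SS", "C", "I"}
            if extra:
                raise ValueError(
                    f"drug_catalog[{d.name}].role_dist has unknown roles {extra}"
                )
        pts = [e.pt for e in self.event_catalog]
        if len(set(pts)) != len(pts):
            raise ValueError("event_catalog PTs must be unique")
        for e in self.event_catalog:
            _check_prob(f"event_catalog[{e.pt}].background", e.background)
        for (dn, pt), rr in self.planted_rr.items():
            if rr < 0:
                raise ValueError(f"planted_rr[{dn},{pt}] must be >= 0")
            if dn.upper() not in names:
                raise ValueError(f"planted_rr drug {dn!r} not in drug_catalog")
            if pt not in pts:
                raise ValueError(f"planted_rr event {pt!r} not in event_catalog")
        for m in self.onset_models.values():
            if m.median_days <= 0 or m.sigma <= 0:
                raise ValueError("onset_models require positive median and sigma")
        d = self.demographics
        _check_dist("demographics.age_bin_dist", d.age_bin_dist)
        if set(d.age_bin_dist) != set(AGE_BIN_RANGES):
            raise ValueError(
                f"demographics.age_bin_dist must cover bins {sorted(AGE_BIN_RANGES)}"
            )
        _check_dist("demographics.sex_dist", d.sex_dist)
        _check_dist("demographics.occupation_dist", d.occupation_dist)
        _check_dist("demographics.country_dist", d.country_dist)
        _check_dist("demographics.outcome_dist", d.outcome_dist)
        _check_prob("demographics.age_unit_noise", d.age_unit_noise)
        _check_prob("demographics.second_outcome_rate", d.second_outcome_rate)
        _check_prob("duplicate_rate", self.duplicate_rate)
        for k, v in self.missing_rates.items():
            _check_prob(f"missing_rates[{k}]", v)
        _check_prob("date_month_rate", self.date_month_rate)
        _check_prob("date_year_rate", self.date_year_rate)
        _check_prob("name_noise", self.name_noise)
        _check_prob("noise_pt_rate", self.noise_pt_rate)

    def rr(self, drug: str, event: str) -> float:
        return float(self.planted_rr.get((drug.upper(), event), 1.0))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in (
            "n_reports",
            "duplicate_rate",
            "date_month_rate",
            "date_year_rate",
            "name_noise",
            "noise_pt_rate",
            "seed",
            "missing_rates",
        ):
            if key in data:
                kwargs[key] = data[key]
        if "quarter_range" in data:
            (y0, q0), (y1, q1) = data["quarter_range"]
            kwargs["quarter_range"] = ((int(y0), int(q0)), (int(y1), int(q1)))
        if "drug_catalog" in data:
            kwargs["drug_catalog"] = tuple(
                DrugSpec(d["name"], d["p_report"], d.get("role_dist", DrugSpec("x", 0).role_dist))
                for d in data["drug_catalog"]
            )
        if "event_catalog" in data:
            kwargs["event_catalog"] = tuple(
                EventSpec(e["pt"], e["background"]) for e in data["event_catalog"]
            )
        if "planted_rr" in data:
            kwargs["planted_rr"] = {
                (p["drug"], p["event"]): p["rr"] for p in data["planted_rr"]
            }
        if "onset_models" in data:
            kwargs["onset_models"] = {
                k: OnsetSpec(v["median_days"], v.get("sigma", 1.0))
                for k, v in data["onset_models"].items()
            }
        return cls(**kwargs)


@dataclass(frozen=True)
class ExpectedTable:
    """Closed-form expected 2x2 cells (real-valued)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass
class GroundTruth:
    """Realized planted parameters of one generated corpus."""

    n_reports: int
    p_ps: dict[str, float]
    backgrounds: dict[str, float]
    planted_rr: dict[tuple[str, str], float]
    onset_medians: dict[str, float]
    duplicate_map: dict[str, list[str]]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_reports": self.n_reports,
            "p_ps": self.p_ps,
            "backgrounds": self.backgrounds,
            "planted_rr": [
                {"drug": d, "event": e, "rr": rr}
                for (d, e), rr in self.planted_rr.items()
            ],
            "onset_medians": self.onset_medians,
            "duplicate_map": self.duplicate_map,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def planted_contingency(truth: GroundTruth, drug: str, event: str) -> ExpectedTable:
    """Expected a/b/c/d under the generative model.

    a = N x P(drug as PS) x min(1, background x RR); the remaining cells
    follow from the margins, so a+b+c+d = N exactly.
    """
    drug = drug.upper()
    if drug not in truth.p_ps:
        raise KeyError(f"unknown drug {drug!r}")
    if event not in truth.backgrounds:
        raise KeyError(f"unknown event {event!r}")
    n = truth.n_reports
    p = truth.p_ps[drug]
    bg = truth.backgrounds[event]
    rr = truth.planted_rr.get((drug, event), 1.0)
    p_event = min(1.0, bg * rr)
    a = n * p * p_event
    b = n * p * (1.0 - p_event)
    c = n * (1.0 - p) * bg
    d = n * (1.0 - p) * (1.0 - bg)
    return ExpectedTable(a, b, c, d)


def _quarter_bounds(quarter_range) -> tuple[int, int]:
    (y0, q0), (y1, q1) = quarter_range
    start = datetime.date(y0, 3 * (q0 - 1) + 1, 1).toordinal()
    if q1 == 4:
        end = datetime.date(y1 + 1, 1, 1).toordinal() - 1
    else:
        end = datetime.date(y1, 3 * q1 + 1, 1).toordinal() - 1
    return start, end


def _pd_from_ordinal(
    ordinal: int, fate: float, p_missing: float, p_month: float, p_year: float
) -> Optional[PartialDate]:
    """Apply the missing/truncation fate drawn for one date."""
    if fate < p_missing:
        return None
    d = datetime.date.fromordinal(max(int(ordinal), 1))
    if fate < p_missing + p_month:
        return PartialDate(d.year, d.month)
    if fate < p_missing + p_month + p_year:
        return PartialDate(d.year)
    return PartialDate(d.year, d.month, d.day)


def _categorical(rng: np.random.Generator, dist: Mapping[str, float], size: int):
    keys = list(dist.keys())
    probs = np.asarray(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def generate_reports(
    config: SimulationConfig,
) -> tuple[AssembledCases, GroundTruth]:
    """Generate the corpus; duplicates add versions, not cases.

    Returns the report collection (pre-deduplication, sorted by
    primaryid) and the realized ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = list(config.drug_catalog)
    events = list(config.event_catalog)
    nK, nE = len(drugs), len(events)
    demo = config.demographics

    present = rng.random((n, nK)) < np.array([d.p_report for d in drugs])
    roles = np.empty((n, nK), dtype="<U2")
    for k, d in enumerate(drugs):
        codes = list(d.role_dist.keys())
        probs = np.asarray(list(d.role_dist.values()), dtype=float)
        roles[:, k] = np.array(codes, dtype="<U2")[
            rng.choice(len(codes), size=n, p=probs / probs.sum())
        ]
    ps = present & (roles == "PS")

    prob = np.broadcast_to(
        np.array([e.background for e in events]), (n, nE)
    ).copy()
    name_to_k = {d.name.upper(): k for k, d in enumerate(drugs)}
    pt_to_j = {e.pt: j for j, e in enumerate(events)}
    for (dn, pt), rr in config.planted_rr.items():
        k = name_to_k[dn.upper()]
        j = pt_to_j[pt]
        prob[:, j] = np.where(
            ps[:, k], np.minimum(1.0, prob[:, j] * rr), prob[:, j]
        )
    ev = rng.random((n, nE)) < prob

    start_ord, end_ord = _quarter_bounds(config.quarter_range)
    fda_ord = rng.integers(start_ord, end_ord + 1, size=n)

    med = np.full(n, config.default_onset.median_days)
    sig = np.full(n, config.default_onset.sigma)
    assigned = np.zeros(n, dtype=bool)
    for k, d in enumerate(drugs):
        model = config.onset_models.get(d.name.upper())
        if model is None:
            continue
        m = ps[:, k] & ~assigned
        med[m] = model.median_days
        sig[m] = model.sigma
        assigned |= m
    onset = np.maximum(
        0, np.rint(np.exp(rng.normal(np.log(med), sig)))
    ).astype(np.int64)
    delay = rng.integers(7, 121, size=n)
    fallback_gap = rng.integers(0, 61, size=n)
    has_ps = ps.any(axis=1)
    has_event = ev.any(axis=1)
    anchored = has_ps & has_event
    event_ord = np.where(anchored, fda_ord - delay, fda_ord - fallback_gap)
    anchor_start_ord = event_ord - onset
    other_start_off = rng.integers(15, 400, size=(n, nK))
    anchor_k = np.where(has_ps, ps.argmax(axis=1), -1)

    # demographics
    bin_labels = list(demo.age_bin_dist.keys())
    bin_idx = rng.choice(
        len(bin_labels),
        size=n,
        p=np.asarray(list(demo.age_bin_dist.values()))
        / sum(demo.age_bin_dist.values()),
    )
    age_years_int = np.empty(n, dtype=np.int64)
    for b, label in enumerate(bin_labels):
        lo, hi = AGE_BIN_RANGES[label]
        m = bin_idx == b
        age_years_int[m] = rng.integers(lo, hi + 1, size=int(m.sum()))
    unit_u = rng.random(n)
    extra_months = rng.integers(0, 12, size=n)
    sexes = _categorical(rng, demo.sex_dist, n)
    occupations = _categorical(rng, demo.occupation_dist, n)
    countries = _categorical(rng, demo.country_dist, n)
    primary_outcome = _categorical(rng, demo.outcome_dist, n)
    second_u = rng.random(n)
    codes_only = {k: v for k, v in demo.outcome_dist.items() if k != "none"}
    second_outcome = _categorical(rng, codes_only, n)

    # missing / precision fates
    mr = config.missing_rates
    p_age_missing = mr.get("age", 0.0)
    p_ev_missing = mr.get("event_dt", 0.0)
    p_ther_missing = mr.get("ther_start", 0.0)
    age_u = rng.random(n)
    event_fate = rng.random(n)
    ther_fate = rng.random((n, nK))
    name_u = rng.random((n, nK))
    variant_pick = rng.integers(0, 4, size=(n, nK))
    noise_u = rng.random(n)
    noise_pick = rng.integers(0, len(NOISE_PTS), size=n)

    n_dup = int(round(config.duplicate_rate * n))
    dup_idx = set(
        rng.choice(n, size=n_dup, replace=False).tolist()
    ) if n_dup else set()
    dup_offset = rng.integers(1, 91, size=n)

    reports: list[CaseReport] = []
    duplicate_map: dict[str, list[str]] = {}
    pm, py = config.date_month_rate, config.date_year_rate

    for i in range(n):
        caseid = str(9_000_000 + i)
        receipt = datetime.date.fromordinal(int(fda_ord[i]))

        entries: list[DrugEntry] = []
        for k in range(nK):
            if not present[i, k]:
                continue
            name = drugs[k].name.upper()
            verbatim = name
            variants = NAME_VARIANTS.get(name)
            if variants and name_u[i, k] < config.name_noise:
                verbatim = variants[variant_pick[i, k] % len(variants)]
            if k == anchor_k[i] and anchored[i]:
                s_ord = int(anchor_start_ord[i])
            else:
                s_ord = int(fda_ord[i] - other_start_off[i, k])
            start = _pd_from_ordinal(
                s_ord, float(ther_fate[i, k]), p_ther_missing, pm, py
            )
            entries.append(
                DrugEntry(verbatim_name=verbatim, role=str(roles[i, k]), therapy_start=start)
            )

        reactions = [events[j].pt for j in range(nE) if ev[i, j]]
        if not reactions or noise_u[i] < config.noise_pt_rate:
            reactions.append(NOISE_PTS[noise_pick[i]])

        if age_u[i] < p_age_missing:
            age_str, age_cod = "", ""
        else:
            years = int(age_years_int[i])
            if unit_u[i] < demo.age_unit_noise / 2:
                age_str, age_cod = f"{years / 10:.1f}", "DEC"
            elif unit_u[i] < demo.age_unit_noise and years < 12:
                age_str, age_cod = str(years * 12 + int(extra_months[i])), "MON"
            else:
                age_str, age_cod = str(years), "YR"

        outcome_set: set[str] = set()
        if primary_outcome[i] != "none":
            outcome_set.add(primary_outcome[i])
            if second_u[i] < demo.second_outcome_rate:
                outcome_set.add(second_outcome[i])

        event_date = _pd_from_ordinal(
            int(event_ord[i]), float(event_fate[i]), p_ev_missing, pm, py
        )
        base = dict(
            caseid=caseid,
            event_date=event_date,
            age=age_str,
            age_cod=age_cod,
            age_years=age_to_years(age_str or None, age_cod or None),
            sex=sexes[i],
            occupation=occupations[i],
            country=countries[i],
            outcomes=frozenset(outcome_set),
            drugs=tuple(entries),
            reactions=tuple(reactions),
        )
        reports.append(
            CaseReport(
                primaryid=caseid + "1",
                receipt_date=PartialDate(receipt.year, receipt.month, receipt.day),
                **base,
            )
        )
        if i in dup_idx:
            receipt2 = datetime.date.fromordinal(int(fda_ord[i] + dup_offset[i]))
            reports.append(
                CaseReport(
                    primaryid=caseid + "2",
                    receipt_date=PartialDate(
                        receipt2.year, receipt2.month, receipt2.day
                    ),
                    **base,
                )
            )
            duplicate_map[caseid] = [caseid + "1", caseid + "2"]

    reports.sort(key=lambda c: primaryid_sort_key(c.primaryid))
    truth = GroundTruth(
        n_reports=n,
        p_ps={
            d.name.upper(): d.p_report * d.role_dist.get("PS", 0.0) for d in drugs
        },
        backgrounds={e.pt: e.background for e in events},
        planted_rr={
            (dn.upper(), pt): float(rr) for (dn, pt), rr in config.planted_rr.items()
        },
        onset_medians={
            k.upper(): m.median_days for k, m in config.onset_models.items()
        },
        duplicate_map=duplicate_map,
        seed=config.seed,
    )
    return AssembledCases(cases=reports), truth


# ---------------------------------------------------------------------------
# FAERS-dialect writer

_HEADERS = {
    "DEMO": (
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "occp_cod",
        "occr_country",
    ),
    "DRUG": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "caseid", "pt"),
    "THER": ("primaryid", "caseid", "dsg_drug_seq", "start_dt"),
    "OUTC": ("primaryid", "caseid", "outc_cod"),
    "INDI": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
    "RPSR": ("primaryid", "caseid", "rpsr_cod"),
}


def _blank_unk(code: str) -> str:
    return "" if code == "UNK" else code


def _quarter_of(pd_: PartialDate) -> tuple[int, int]:
    return pd_.year, ((pd_.month or 1) - 1) // 3 + 1


def write_quarter_files(
    reports: AssembledCases | Sequence[CaseReport], directory: str | Path
) -> list[Path]:
    """Write reports as $-delimited quarterly FAERS tables.

    One file per table per receipt quarter (``DEMO24Q1.txt`` etc.).
    Reading the files back through the ingest module reproduces the
    collection exactly.
    """
    cases = list(reports)
    if not cases:
        raise ValueError("no reports to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    by_quarter: dict[tuple[int, int], list[CaseReport]] = {}
    for case in cases:
        by_quarter.setdefault(_quarter_of(case.receipt_date), []).append(case)

    written: list[Path] = []
    for (year, q), members in sorted(by_quarter.items()):
        tag = f"{year % 100:02d}Q{q}"
        rows: dict[str, list[tuple[str, ...]]] = {t: [] for t in _HEADERS}
        for case in members:
            pid, cid = case.primaryid, case.caseid
            rows["DEMO"].append(
                (
                    pid,
                    cid,
                    case.receipt_date.to_faers(),
                    case.event_date.to_faers() if case.event_date else "",
                    case.age,
                    case.age_cod,
                    _blank_unk(case.sex),
                    _blank_unk(case.occupation),
                    _blank_unk(case.country),
                )
            )
            for seq, entry in enumerate(case.drugs, start=1):
                rows["DRUG"].append(
                    (pid, cid, str(seq), entry.role, entry.verbatim_name)
                )
                if entry.therapy_start is not None:
                    rows["THER"].append(
                        (pid, cid, str(seq), entry.therapy_start.to_faers())
                    )
            for pt in case.reactions:
                rows["REAC"].append((pid, cid, pt))
            for code in sorted(case.outcomes):
                rows["OUTC"].append((pid, cid, code))
            if case.drugs:
                # structural placeholder rows: one oncology indication per
                # report and a report-source code derived from the country
                rows["INDI"].append((pid, cid, "1", "Malignant neoplasm"))
            rows["RPSR"].append(
                (pid, cid, "HP" if case.country == "US" else "FGN")
            )
        for table, header in _HEADERS.items():
            path = directory / f"{table}{tag}.txt"
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                fh.write("$".join(header) + "\n")
                for row in rows[table]:
                    fh.write("$".join(row) + "\n")
            written.append(path)
    return written
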