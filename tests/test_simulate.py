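"""Synthetic corpus generator: determinism, closed forms, round trips."""

import dataclasses

import pytest

from faerspv.ingest import assemble_cases, deduplicate_cases, read_quarter
from faerspv.simulate import (
    Demographics,
    DrugSpec,
    EventSpec,
    SimulationConfig,
    generate_reports,
    planted_contingency,
    write_quarter_files,
)


def one_drug_config(**kw):
    """One fully-PS target drug against a background drug."""
    defaults = dict(
        n_reports=10_000,
        drug_catalog=(
            DrugSpec("DRUGA", 0.05, {"PS": 1.0}),
            DrugSpec("OTHER", 0.30, {"PS": 0.5, "C": 0.5}),
        ),
        event_catalog=(EventSpec("EventX", 0.01),),
        planted_rr={},
        onset_models={},
        duplicate_rate=0.0,
        missing_rates={},
        date_month_rate=0.0,
        date_year_rate=0.0,
        name_noise=0.0,
        seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestValidation:
    @pytest.mark.parametrize(
        "patch, fragment",
        [
            (dict(n_reports=0), "n_reports"),
            (dict(duplicate_rate=1.5), "duplicate_rate"),
            (dict(quarter_range=((2024, 1), (2020, 1))), "quarter_range"),
            (dict(quarter_range=((2024, 5), (2024, 5))), "quarter"),
            (dict(planted_rr={("NOPE", "Hyponatremia"): 2.0}), "NOPE"),
            (dict(planted_rr={("NIVOLUMAB", "NopeEvent"): 2.0}), "NopeEvent"),
            (dict(planted_rr={("NIVOLUMAB", "Hyponatremia"): -1.0}), "planted_rr"),
            (dict(date_month_rate=2.0), "date_month_rate"),
        ],
    )
    def test_invalid_config_names_the_field(self, patch, fragment):
        cfg = SimulationConfig(**patch)
        with pytest.raises(ValueError, match=fragment):
            cfg.validate()

    def test_bad_distribution_rejected(self):
        cfg = SimulationConfig(
            demographics=Demographics(sex_dist={"M": 0.7, "F": 0.7})
        )
        with pytest.raises(ValueError, match="sex_dist"):
            cfg.validate()


def test_same_seed_same_output(tmp_path):
    cfg = SimulationConfig(n_reports=300, seed=7)
    r1, _ = generate_reports(cfg)
    r2, _ = generate_reports(cfg)
    assert list(r1) == list(r2)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = write_quarter_files(r1, d1)
    p2 = write_quarter_files(r2, d2)
    for a, b in zip(sorted(p1), sorted(p2)):
        assert a.read_bytes() == b.read_bytes()


def test_different_seed_differs():
    r1, _ = generate_reports(SimulationConfig(n_reports=300, seed=1))
    r2, _ = generate_reports(SimulationConfig(n_reports=300, seed=2))
    assert list(r1) != list(r2)


def test_case_count_and_duplicates():
    """Duplicates add versions, never cases."""
    cfg = SimulationConfig(n_reports=1_000, duplicate_rate=0.10, seed=3)
    reports, truth = generate_reports(cfg)
    assert len(reports) == 1_000 + 100
    assert len({c.caseid for c in reports}) == 1_000
    assert len(truth.duplicate_map) == 100
    for caseid, pids in truth.duplicate_map.items():
        versions = [c for c in reports if c.caseid == caseid]
        assert sorted(c.primaryid for c in versions) == sorted(pids)
        v1, v2 = sorted(versions, key=lambda c: c.primaryid)
        # later receipt date on the duplicate version, 1-90 days on
        assert v1.receipt_date.to_date() < v2.receipt_date.to_date()
        assert (v2.receipt_date.to_date() - v1.receipt_date.to_date()).days <= 90


def test_every_report_has_a_reaction():
    reports, _ = generate_reports(SimulationConfig(n_reports=2_000, seed=4))
    assert all(len(c.reactions) >= 1 for c in reports)


class TestPlantedContingency:
    def test_null_rr_closed_form(self):
        _, truth = generate_reports(one_drug_config(n_reports=10_000))
        t = planted_contingency(truth, "DRUGA", "EventX")
        assert t.a == pytest.approx(5.0)
        assert t.n == pytest.approx(10_000)

    def test_rr_multiplies_a(self):
        _, truth = generate_reports(
            one_drug_config(planted_rr={("DRUGA", "EventX"): 2.5})
        )
        t = planted_contingency(truth, "DRUGA", "EventX")
        assert t.a == pytest.approx(12.5)
        assert t.a + t.b + t.c + t.d == pytest.approx(10_000)

    def test_unknown_pair_raises(self):
        _, truth = generate_reports(one_drug_config(n_reports=10))
        with pytest.raises(KeyError):
            planted_contingency(truth, "GHOST", "EventX")
        with pytest.raises(KeyError):
            planted_contingency(truth, "DRUGA", "GhostEvent")


class TestWriter:
    def test_minimal_row_counts(self, tmp_path):
        cfg = one_drug_config(
            n_reports=1,
            drug_catalog=(DrugSpec("DRUGA", 1.0, {"PS": 1.0}),),
            event_catalog=(EventSpec("EventX", 1.0),),
            noise_pt_rate=0.0,
        )
        reports, _ = generate_reports(cfg)
        write_quarter_files(reports, tmp_path)
        raw = read_quarter(tmp_path)
        assert len(raw.rows("DEMO")) == 1
        assert len(raw.rows("DRUG")) == 1
        assert len(raw.rows("REAC")) == 1

    def test_one_reac_row_per_reaction(self, tmp_path):
        cfg = one_drug_config(
            n_reports=1,
            drug_catalog=(DrugSpec("DRUGA", 1.0, {"PS": 1.0}),),
            event_catalog=(
                EventSpec("E1", 1.0),
                EventSpec("E2", 1.0),
                EventSpec("E3", 1.0),
            ),
            noise_pt_rate=0.0,
        )
        reports, _ = generate_reports(cfg)
        write_quarter_files(reports, tmp_path)
        raw = read_quarter(tmp_path)
        reac = raw.rows("REAC")
        assert len(reac) == 3
        assert len({r["primaryid"] for r in reac}) == 1

    def test_round_trip_equality(self, tmp_path):
        cfg = SimulationConfig(n_reports=400, seed=11)
        reports, _ = generate_reports(cfg)
        write_quarter_files(reports, tmp_path)
        back = assemble_cases(read_quarter(tmp_path))
        assert list(back) == list(reports)
        # and dedup after the round trip equals dedup before
        assert deduplicate_cases(back) == deduplicate_cases(reports)

    def test_empty_collection_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_quarter_files([], tmp_path)


def test_partial_dates_and_missingness_show_up():
    cfg = SimulationConfig(
        n_reports=3_000,
        missing_rates={"age": 0.2, "event_dt": 0.2, "ther_start": 0.2},
        date_month_rate=0.15,
        date_year_rate=0.05,
        seed=5,
    )
    reports, _ = generate_reports(cfg)
    event_dates = [c.event_date for c in reports]
    assert any(d is None for d in event_dates)
    precisions = {d.precision for d in event_dates if d is not None}
    assert {"day", "month", "year"} <= precisions
    assert any(c.age_years is None for c in reports)
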