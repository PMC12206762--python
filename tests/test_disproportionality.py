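"""2x2 statistics: worked values, identities, oracles, criteria."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.cases import DrugDictionary
from faerspv.disproportionality import (
    ContingencyTable,
    build_table,
    compute_ebgm,
    compute_ic,
    compute_prr_chi2,
    compute_ror,
    contingency_grid,
    round_half_up,
    signal_stats,
)

from conftest import conc, make_case, ps

TABLE = ContingencyTable(10, 90, 100, 9900)
NULL = ContingencyTable(1, 1, 1, 1)

cells = st.integers(min_value=1, max_value=10**6)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


class TestBuildTable:
    DICT = DrugDictionary(synonyms={"TARGET": ()})

    def universe(self):
        cases = []
        for i in range(20):
            target = i < 8
            event = i % 2 == 0
            cases.append(
                make_case(
                    primaryid=str(i),
                    caseid=str(i),
                    drugs=[ps("TARGET") if target else ps("OTHER")],
                    reactions=["EventX"] if event else ["Nausea"],
                )
            )
        return cases

    def test_partition_arithmetic(self):
        universe = self.universe()
        event_ids = [c.primaryid for c in universe if "EventX" in c.reactions]
        t = build_table(universe, event_ids, "TARGET", self.DICT)
        assert (t.a, t.b, t.c, t.d) == (4, 4, 6, 6)
        assert t.n == len(universe)

    def test_no_event_reports(self):
        universe = self.universe()
        t = build_table(universe, [], "TARGET", self.DICT)
        assert t.a == 0 and t.c == 0
        assert t.n == len(universe)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            build_table([], [], "TARGET", self.DICT)


class TestWorkedValues:
    """Hand-computed values for the (10, 90, 100, 9900) table."""

    def test_ror_and_ci(self):
        ror, lo, hi, corrected = compute_ror(TABLE)
        assert ror == pytest.approx(11.0)
        assert lo == pytest.approx(5.56, abs=0.01)
        assert hi == pytest.approx(21.77, abs=0.01)
        assert not corrected

    def test_prr_chi2(self):
        prr, chi2 = compute_prr_chi2(TABLE)
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.45, abs=0.01)

    def test_ic(self):
        ic, ic025 = compute_ic(TABLE)
        assert ic == pytest.approx(3.20, abs=0.005)
        assert ic025 == pytest.approx(2.09, abs=0.005)

    def test_ebgm(self):
        ebgm, eb05, _, corrected = compute_ebgm(TABLE)
        assert ebgm == pytest.approx(9.18, abs=0.005)
        assert eb05 == pytest.approx(4.64, abs=0.005)
        assert not corrected

    def test_all_flags_positive(self):
        s = signal_stats(TABLE)
        assert s.ror_signal and s.prr_signal and s.bcpnn_signal and s.mgps_signal
        assert s.positive_signal


class TestDegenerate:
    def test_symmetric_null_table(self):
        s = signal_stats(NULL)
        assert s.ror == pytest.approx(1.0)
        assert s.prr == pytest.approx(1.0)
        assert s.chi2 == pytest.approx(0.0)
        assert s.ic == pytest.approx(0.0)
        assert s.ebgm == pytest.approx(1.0)
        assert not (
            s.ror_signal or s.prr_signal or s.bcpnn_signal or s.mgps_signal
        )

    def test_zero_cell_continuity_correction(self):
        t = ContingencyTable(3, 0, 5, 100)
        ror, lo, hi, corrected = compute_ror(t)
        assert corrected
        a, b, c, d = 3.5, 0.5, 5.5, 100.5
        assert ror == pytest.approx(a * d / (b * c))

    def test_a_zero_returns_missing(self):
        t = ContingencyTable(0, 10, 10, 100)
        assert compute_ic(t) == (None, None)
        assert compute_ebgm(t)[0] is None

    def test_small_a_blocks_ror_and_prr_flags(self):
        # huge association but a = 2: count threshold fails
        s = signal_stats(ContingencyTable(2, 1, 1, 10_000))
        assert s.ror is not None and s.ror > 100
        assert not s.ror_signal and not s.prr_signal


class TestIdentities:
    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_ebgm_equals_two_to_the_ic(self, t):
        """The relative-reporting-ratio forms of EBGM and IC coincide."""
        ic, _ = compute_ic(t)
        ebgm, _, _, _ = compute_ebgm(t)
        assert ebgm == pytest.approx(2.0**ic, rel=1e-12)

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_chi2_matches_pearson_expected_cell_form(self, t):
        _, chi2 = compute_prr_chi2(t)
        obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        pearson = ((obs - exp) ** 2 / exp).sum()
        assert chi2 == pytest.approx(pearson, rel=1e-9)

    def test_monotone_in_a(self):
        """More target-event reports with the other cells fixed: ROR and
        PRR increase unconditionally; the observed/expected statistics
        (IC, EBGM) increase throughout the rare-event regime where both
        margins stay dominated by the other cells."""
        prev = signal_stats(ContingencyTable(5, 500, 600, 50_000))
        for a in (10, 20, 40, 80):
            cur = signal_stats(ContingencyTable(a, 500, 600, 50_000))
            assert cur.ror > prev.ror
            assert cur.prr > prev.prr
            assert cur.ic > prev.ic
            assert cur.ebgm > prev.ebgm
            prev = cur
        # ROR/PRR keep increasing even when a dominates its margins
        dense_prev = signal_stats(ContingencyTable(40, 50, 60, 5000))
        dense_cur = signal_stats(ContingencyTable(80, 50, 60, 5000))
        assert dense_cur.ror > dense_prev.ror
        assert dense_cur.prr > dense_prev.prr


def test_round_half_up():
    assert round_half_up(2.555, 2) == 2.56
    assert round_half_up(2.545, 2) == 2.55
    assert round_half_up(-1.165, 2) == -1.17
    assert round_half_up(1.0, 2) == 1.0


def test_contingency_grid_matches_build_table():
    """The vectorized all-pairs grid agrees with per-pair construction."""
    rng = np.random.default_rng(0)
    drugs = ["D1", "D2", "D3"]
    events = ["E1", "E2"]
    cases = []
    for i in range(400):
        dlist = [ps(d) for d in drugs if rng.random() < 0.2]
        rlist = [e for e in events if rng.random() < 0.1] or ["Nausea"]
        cases.append(
            make_case(primaryid=str(i), caseid=str(i), drugs=dlist, reactions=rlist)
        )
    grid = contingency_grid(cases, drugs, events)
    for d in drugs:
        dic = DrugDictionary(synonyms={d: ()})
        for e in events:
            event_ids = [c.primaryid for c in cases if e in c.reactions]
            assert grid[(d, e)] == build_table(cases, event_ids, d, dic)


def test_run_screen_uses_background_event_universe(smq, drug_dict):
    """The comparator cell c counts SMQ event reports among non-target
    drugs, not just the target's own cases."""
    from faerspv.cases import select_cases
    from faerspv.disproportionality import run_screen

    cases = [
        make_case(
            primaryid="1", caseid="1",
            drugs=[ps("NIVOLUMAB")], reactions=["Hyponatremia"],
        ),
        make_case(
            primaryid="2", caseid="2",
            drugs=[ps("NIVOLUMAB")], reactions=["Nausea"],
        ),
    ] + [
        make_case(
            primaryid=str(i), caseid=str(i),
            drugs=[ps("FUROSEMIDE")],
            reactions=["Hyponatremia"] if i < 8 else ["Nausea"],
        )
        for i in range(3, 13)
    ]
    cs = select_cases(cases, smq, drug_dict, "NIVOLUMAB")
    frame = run_screen(cases, {"NIVOLUMAB": cs}, drug_dict, smq)
    row = frame.iloc[0]
    assert row["a"] == 1 and row["n"] == len(cs)
    assert row["b"] == 1
    assert row["c"] == 5  # furosemide hyponatremia reports
    assert row["d"] == 5
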