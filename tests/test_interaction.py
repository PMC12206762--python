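"""Omega shrinkage interaction statistic."""

import math

import pytest

from faerspv.cases import DrugDictionary
from faerspv.interaction import (
    InteractionCounts,
    build_interaction_counts,
    compute_omega,
    expected_rate,
    omega_lcb,
)

from conftest import conc, make_case, ps

DICT = DrugDictionary(synonyms={"DRUG1": ()})


def counts(**kw):
    base = dict(
        n11_dot=200,
        n10_dot=500,
        n01_dot=400,
        n00_dot=1000,
        n11_1=40,
        n10_1=50,
        n01_1=20,
        n00_1=50,
    )
    base.update(kw)
    return InteractionCounts(**base)


class TestComputeOmega:
    def test_worked_example(self):
        """f10=0.10, f01=0.05, f00=0.05 -> f11_0=0.10, E111=20."""
        s = compute_omega(counts())
        assert s.e111 == pytest.approx(20.0)
        assert s.omega == pytest.approx(math.log2(40.5 / 20.5), abs=1e-12)
        assert s.omega == pytest.approx(0.98, abs=0.005)
        assert s.omega025 == pytest.approx(0.54, abs=0.005)

    def test_observed_equals_expected_gives_zero(self):
        s = compute_omega(counts(n11_1=20))
        assert s.omega == 0.0

    def test_interval_width_law(self):
        s = compute_omega(counts())
        width = 1.96 / (math.log(2) * math.sqrt(counts().n111))
        assert s.omega - s.omega025 == pytest.approx(width, abs=1e-12)

    def test_shrinkage_pulls_toward_zero(self):
        """For n111 < E111 the +0.5 terms make Omega exceed the raw
        log-ratio."""
        c = counts(n11_1=10)
        s = compute_omega(c)
        assert s.counts.n111 < s.e111
        assert s.omega > math.log2(c.n111 / s.e111)

    def test_zero_n111_has_no_bound(self):
        s = compute_omega(counts(n11_1=0))
        assert s.omega < 0
        assert s.omega025 is None

    def test_low_count_flag(self):
        assert compute_omega(counts(n11_1=2)).low_count_flag
        assert not compute_omega(counts(n11_1=3)).low_count_flag

    def test_empty_stratum_is_error(self):
        with pytest.raises(ValueError, match="stratum"):
            compute_omega(counts(n01_dot=0, n01_1=0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            InteractionCounts(10, 10, 10, 10, 11, 0, 0, 0)


class TestExpectedRate:
    def test_inverse_rate_combination(self):
        assert expected_rate(0.10, 0.05, 0.05) == pytest.approx(0.10)

    def test_floor_when_inverse_nonpositive(self):
        # large f00 makes the inverse combination negative
        assert expected_rate(0.01, 0.01, 0.004) == pytest.approx(0.01)

    def test_zero_single_exposure_rate_floors(self):
        assert expected_rate(0.0, 0.05, 0.01) == pytest.approx(0.05)

    def test_rate_capped_at_one(self):
        assert expected_rate(0.9, 0.9, 0.5) <= 1.0


class TestPrintedPairs:
    """The credibility-bound width reproduces published worked values."""

    @pytest.mark.parametrize(
        "n111, omega, omega025",
        [
            (107, -0.89, -1.16),
            (12, -0.51, -1.33),
            (81, -0.23, -0.54),
            (17, -1.68, -2.36),
        ],
    )
    def test_width_reproduces_bound(self, n111, omega, omega025):
        assert omega_lcb(omega, n111) == pytest.approx(omega025, abs=0.01)


class TestBuildCounts:
    def universe(self):
        cases = []
        spec = [
            # (drug1 as PS, drug2 concomitant, event) x count
            ((True, True, True), 4),
            ((True, True, False), 6),
            ((True, False, True), 5),
            ((True, False, False), 15),
            ((False, True, True), 2),
            ((False, True, False), 8),
            ((False, False, True), 10),
            ((False, False, False), 50),
        ]
        i = 0
        for (d1, d2, ev), k in spec:
            for _ in range(k):
                drugs = []
                if d1:
                    drugs.append(ps("DRUG1"))
                if d2:
                    drugs.append(conc("DRUG2"))
                if not drugs:
                    drugs.append(ps("FILLER"))
                cases.append(
                    make_case(
                        primaryid=str(i),
                        caseid=str(i),
                        drugs=drugs,
                        reactions=["EventX"] if ev else ["Nausea"],
                    )
                )
                i += 1
        return cases

    def test_exact_stratified_counts(self):
        c = build_interaction_counts(
            self.universe(), "DRUG1", "DRUG2", frozenset({"EventX"}), DICT
        )
        assert (c.n11_dot, c.n10_dot, c.n01_dot, c.n00_dot) == (10, 20, 10, 60)
        assert (c.n11_1, c.n10_1, c.n01_1, c.n00_1) == (4, 5, 2, 10)
        assert c.total == 100

    def test_partition_conserves_universe(self):
        u = self.universe()
        c = build_interaction_counts(
            u, "DRUG1", "DRUG2", frozenset({"EventX"}), DICT
        )
        assert c.total == len(u)

    def test_absent_drug_empties_exposed_strata(self):
        c = build_interaction_counts(
            self.universe(), "GHOST", "DRUG2", frozenset({"EventX"}), DICT
        )
        assert c.n11_dot == 0 and c.n10_dot == 0


def test_interaction_grid_matches_per_combination_counts():
    """The vectorized all-combinations counter agrees with the direct
    per-combination builder."""
    import numpy as np

    from faerspv.interaction import interaction_grid

    rng = np.random.default_rng(3)
    drugs1 = ["A1", "A2"]
    drugs2 = ["B1", "B2", "B3"]
    cases = []
    for i in range(600):
        drugs = []
        for d in drugs1:
            if rng.random() < 0.15:
                drugs.append(ps(d))
        for d in drugs2:
            if rng.random() < 0.2:
                drugs.append(conc(d))
        reactions = ["EventX"] if rng.random() < 0.1 else ["Nausea"]
        cases.append(
            make_case(primaryid=str(i), caseid=str(i), drugs=drugs, reactions=reactions)
        )
    grid = interaction_grid(cases, drugs1, drugs2, {"EventX"})
    for d1 in drugs1:
        for d2 in drugs2:
            direct = build_interaction_counts(
                cases,
                d1,
                d2,
                frozenset({"EventX"}),
                DrugDictionary(synonyms={d1: ()}),
            )
            assert grid[(d1, d2)] == direct
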