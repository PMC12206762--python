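import pytest

from faerspv.records import CaseReport, DrugEntry, PartialDate


def make_case(
    primaryid="1001",
    caseid="100",
    fda=(2023, 1, 5),
    event=None,
    drugs=(),
    reactions=(),
    sex="M",
    age_years=None,
    outcomes=(),
    country="US",
    occupation="MD",
):
    """Compact CaseReport factory for hand-built fixtures."""
    return CaseReport(
        primaryid=primaryid,
        caseid=caseid,
        receipt_date=PartialDate(*fda),
        event_date=PartialDate(*event) if event else None,
        age=("" if age_years is None else str(age_years)),
        age_cod=("" if age_years is None else "YR"),
        age_years=age_years,
        sex=sex,
        occupation=occupation,
        country=country,
        outcomes=frozenset(outcomes),
        drugs=tuple(drugs),
        reactions=tuple(reactions),
    )


def ps(name, start=None):
    return DrugEntry(name, "PS", PartialDate(*start) if start else None)


def conc(name, role="C", start=None):
    return DrugEntry(name, role, PartialDate(*start) if start else None)


@pytest.fixture(scope="session")
def smq():
    from faerspv.cases import load_smq

    return load_smq()


@pytest.fixture(scope="session")
def drug_dict():
    from faerspv.cases import load_drug_dictionary

    return load_drug_dictionary()


@pytest.fixture(scope="session")
def small_corpus():
    """A 5,000-report default-config corpus shared across tests."""
    from faerspv.simulate import SimulationConfig, generate_reports

    cfg = SimulationConfig(n_reports=5_000)
    return generate_reports(cfg)
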