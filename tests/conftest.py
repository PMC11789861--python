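import datetime as dt

import pytest

from pvsignal.contingency import ContingencyTable
from pvsignal.records import DrugMention, DrugRole, ReactionMention, ReportRecord


def make_report(
    case_id,
    drugs=(("capmatinib", DrugRole.PRIMARY_SUSPECT),),
    pts=("pt0001",),
    version=1,
    date=dt.date(2021, 6, 1),
    sex="unknown",
    age=None,
    country=None,
):
    return ReportRecord(
        case_id=case_id,
        version=version,
        receipt_date=date,
        sex=sex,
        age_years=age,
        country=country,
        drugs=tuple(DrugMention(n, r) for n, r in drugs),
        reactions=tuple(ReactionMention(p) for p in pts),
    )


def table(a, b, c, d, drug="capmatinib", pt="pt0001"):
    return ContingencyTable(drug, pt, a, b, c, d, a + b + c + d)


@pytest.fixture
def four_cell_corpus():
    """One report per contingency cell: (a,b,c,d) = (1,1,1,1)."""
    other = (("otherdrug", DrugRole.PRIMARY_SUSPECT),)
    return [
        make_report("c1", pts=("pt0001",)),
        make_report("c2", pts=("pt0002",)),
        make_report("c3", drugs=other, pts=("pt0001",)),
        make_report("c4", drugs=other, pts=("pt0002",)),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """Deterministic 2,000-report synthetic corpus with one strong
    injected pair, shared across tests that only read it."""
    import numpy as np

    from pvsignal.synthetic import SyntheticConfig, generate_reports

    rates = np.full(50, 0.02)
    rates[7] = 0.004
    config = SyntheticConfig(
        n_reports=2000,
        n_pts=50,
        n_socs=10,
        background_pt_rates=rates,
        injected_pairs=((7, 20.0),),
        target_drug_prevalence=0.05,
        seed=42,
    )
    reports, truth = generate_reports(config)
    return config, reports, truth
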