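import datetime as dt

import pytest

from pvsignal import MedDRADictionary, SynonymTable
from pvsignal.reports import DrugEntry, Reaction, SafetyReport


def make_report(
    case_id,
    pts=("Abscess",),
    version=1,
    receipt="2020-01-15",
    drug="ustekinumab",
    role="suspect",
    indication="Crohn's disease",
    sex="female",
    age=45.0,
    country="US",
    reporter="consumer",
    outcomes=(),
    event_date=None,
    therapy_start=None,
    route=None,
):
    """Compact SafetyReport factory for fixtures."""
    rd = dt.date.fromisoformat(receipt) if receipt else None
    drugs = []
    if drug is not None:
        drugs = [
            DrugEntry(
                name=drug,
                role=role,
                route=route,
                indication_pt=indication,
                therapy_start=therapy_start,
            )
        ]
    return SafetyReport(
        case_id=case_id,
        case_version=version,
        receipt_date=rd,
        report_year=rd.year if rd else None,
        drugs=drugs,
        reactions=[Reaction(pt=p, event_date=event_date) for p in pts],
        sex=sex,
        age_years=age,
        country=country,
        reporter=reporter,
        outcomes=frozenset(outcomes),
    )


@pytest.fixture(scope="session")
def toy_dictionary():
    return MedDRADictionary(
        {
            "Abscess": "Infections and infestations",
            "Pneumonia": "Infections and infestations",
            "Abdominal pain": "Gastrointestinal disorders",
            "Nausea": "Gastrointestinal disorders",
            "Myocardial infarction": "Cardiac disorders",
            "Cholangitis": "Hepatobiliary disorders",
            "Headache": "Nervous system disorders",
        }
    )


@pytest.fixture(scope="session")
def synonyms():
    return SynonymTable({"STELARA": "ustekinumab", "REMICADE": "infliximab"})
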