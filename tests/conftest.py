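from pathlib import Path

import pandas as pd
import pytest

from pvsignal import (
    DrugDictionary,
    EventDefinition,
    ReportCollection,
    TermHierarchy,
    default_dictionary,
    default_hierarchy,
)
from pvsignal.report_store import DEMO_COLUMNS, DRUG_COLUMNS, PT_COLUMNS, assign_region

DATA = Path(__file__).parent / "data"
FIXTURE50 = DATA / "fixture50"


@pytest.fixture(scope="session")
def hierarchy() -> TermHierarchy:
    return default_hierarchy()


@pytest.fixture(scope="session")
def dictionary() -> DrugDictionary:
    return default_dictionary()


@pytest.fixture(scope="session")
def event_def() -> EventDefinition:
    return EventDefinition()


def make_collection(rows) -> ReportCollection:
    """Build a collection from compact per-report dicts.

    Keys: report_id (required); version, sex, age_group, country,
    receipt_year, receipt_quarter, outcomes (scalar, defaulted); drugs as
    [(verbatim, role), ...]; reactions / indications as [pt, ...].
    """
    demo, drugs, reac, indi = [], [], [], []
    for r in rows:
        demo.append(
            {
                "report_id": r["report_id"],
                "version": r.get("version", 1),
                "sex": r.get("sex", "male"),
                "age_group": r.get("age_group", "45-64"),
                "country": r.get("country", "US"),
                "region": assign_region(r.get("country", "US")),
                "receipt_year": r.get("receipt_year", 2010),
                "receipt_quarter": r.get("receipt_quarter", 1),
                "outcomes": r.get("outcomes", ""),
            }
        )
        for verbatim, role in r.get("drugs", []):
            drugs.append(
                {
                    "report_id": r["report_id"],
                    "verbatim_name": verbatim,
                    "generic_name": None,
                    "role": role,
                }
            )
        for pt in r.get("reactions", []):
            reac.append({"report_id": r["report_id"], "pt_code": pt})
        for pt in r.get("indications", []):
            indi.append({"report_id": r["report_id"], "pt_code": pt})
    return ReportCollection(
        pd.DataFrame(demo, columns=DEMO_COLUMNS),
        pd.DataFrame(drugs, columns=DRUG_COLUMNS),
        pd.DataFrame(reac, columns=PT_COLUMNS),
        pd.DataFrame(indi, columns=PT_COLUMNS),
    )
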