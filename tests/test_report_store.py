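import math

import pandas as pd
import pytest

import pvsignal as pv
from pvsignal._util import SchemaError
from pvsignal.report_store import assign_region, bin_age, clean, read_tables

from conftest import make_collection


def _write_tables(tmp_path, demo_rows, drug_rows, reac_rows, indi_rows=(), sep="\t"):
    paths = {}
    for name, header, rows in [
        ("demo", "report_id\tversion\tsex\tage_group\tcountry\treceipt_year\treceipt_quarter\toutcomes", demo_rows),
        ("drug", "report_id\tverbatim_name\trole", drug_rows),
        ("reac", "report_id\tpt_code", reac_rows),
        ("indi", "report_id\tpt_code", indi_rows),
    ]:
        p = tmp_path / f"{name}.tsv"
        p.write_text("\n".join([header.replace("\t", sep)] + [r.replace("\t", sep) for r in rows]) + "\n")
        paths[name] = p
    return paths


THREE_REPORT_DEMO = [
    "A\t1\tfemale\t45-64\tUS\t2010\t2\thospitalization",
    "B\t1\tmale\t>75\tDE\t2015\t4\t",
    "C\t2\tunknown\tunknown\tunknown\t2006\t1\tdeath;disability",
]
THREE_REPORT_DRUGS = [
    "A\tLISINOPRIL 10MG\tsuspect",
    "A\tHCTZ\tconcomitant",
    "B\tRAMIPRIL\tsuspect",
    "C\tIRBESARTAN\tinteracting",
]
THREE_REPORT_REACS = [
    "A\tlung_adenocarcinoma",
    "B\tcough",
    "B\theadache",
    "C\tnausea",
]


def test_read_tables_joins_three_report_fixture(tmp_path):
    p = _write_tables(tmp_path, THREE_REPORT_DEMO, THREE_REPORT_DRUGS, THREE_REPORT_REACS)
    col = read_tables(p["demo"], p["drug"], p["reac"], p["indi"])
    assert len(col) == 3
    a = col.get("A")
    assert a.sex == "female" and a.region == "America"
    assert {m.verbatim_name for m in a.drugs} == {"LISINOPRIL 10MG", "HCTZ"}
    b = col.get("B")
    assert b.reactions == ("cough", "headache") and b.region == "Europe"
    c = col.get("C")
    assert c.version == 2 and c.serious_outcomes == frozenset({"death", "disability"})


def test_orphan_rows_dropped_and_counted(tmp_path):
    p = _write_tables(
        tmp_path, THREE_REPORT_DEMO,
        THREE_REPORT_DRUGS + ["ZZZ\tENALAPRIL\tsuspect"],
        THREE_REPORT_REACS,
    )
    col = read_tables(p["demo"], p["drug"], p["reac"], p["indi"])
    assert col.provenance["orphan_drug_rows"] == 1
    assert "ZZZ" not in set(col.drugs["report_id"])


def test_schema_config_remaps_columns_and_delimiter(tmp_path):
    rows = ["A,1,female,45-64,US,2010,2,"]
    (tmp_path / "demo.csv").write_text(
        "primaryid,version,sex,age_group,country,receipt_year,receipt_quarter,outcomes\n"
        + "\n".join(rows) + "\n"
    )
    (tmp_path / "drug.csv").write_text("primaryid,drugname,role\nA,LISINOPRIL,suspect\n")
    (tmp_path / "reac.csv").write_text("primaryid,pt\nA,cough\n")
    schema = {
        "delimiter": ",",
        "demo": {"report_id": "primaryid"},
        "drug": {"report_id": "primaryid", "verbatim_name": "drugname"},
        "reac": {"report_id": "primaryid", "pt_code": "pt"},
    }
    col = read_tables(
        tmp_path / "demo.csv", tmp_path / "drug.csv", tmp_path / "reac.csv",
        schema_config=schema,
    )
    assert len(col) == 1 and col.get("A").drugs[0].verbatim_name == "LISINOPRIL"


def test_missing_mandatory_column_is_schema_error(tmp_path):
    (tmp_path / "demo.tsv").write_text("report_id\tsex\tcountry\treceipt_year\nA\tmale\tUS\t2010\n")
    (tmp_path / "drug.tsv").write_text("report_id\tverbatim_name\trole\n")
    (tmp_path / "reac.tsv").write_text("report_id\tpt_code\n")
    with pytest.raises(SchemaError, match="receipt_quarter"):
        read_tables(tmp_path / "demo.tsv", tmp_path / "drug.tsv", tmp_path / "reac.tsv")


def test_missing_file_is_fatal(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_tables(tmp_path / "no.tsv", tmp_path / "no.tsv", tmp_path / "no.tsv")


def test_raw_age_column_binned(tmp_path):
    (tmp_path / "demo.tsv").write_text(
        "report_id\tsex\tage\tcountry\treceipt_year\treceipt_quarter\n"
        "A\tmale\t75\tUS\t2010\t1\nB\tfemale\t64\tUS\t2010\t1\nC\tmale\t\tUS\t2010\t1\n"
    )
    (tmp_path / "drug.tsv").write_text("report_id\tverbatim_name\trole\nA\tX\tsuspect\n")
    (tmp_path / "reac.tsv").write_text("report_id\tpt_code\nA\tcough\n")
    col = read_tables(tmp_path / "demo.tsv", tmp_path / "drug.tsv", tmp_path / "reac.tsv")
    ages = dict(zip(col.demo["report_id"], col.demo["age_group"]))
    assert ages == {"A": ">75", "B": "45-64", "C": "unknown"}


@pytest.mark.parametrize(
    "age,group",
    [(0, "<18"), (17.9, "<18"), (18, "18-44"), (44, "18-44"), (45, "45-64"),
     (64.9, "45-64"), (65, "65-74"), (74, "65-74"), (75, ">75"), (90, ">75"),
     (math.nan, "unknown")],
)
def test_age_bin_edges_are_left_closed(age, group):
    assert bin_age(age) == group


@pytest.mark.parametrize(
    "country,region",
    [("US", "America"), ("DE", "Europe"), ("JP", "Asia"), ("AU", "Oceania"),
     ("ZA", "Africa"), ("", "unknown"), ("XX", "unknown"), (None, "unknown"),
     ("de", "Europe")],
)
def test_assign_region_total_function(country, region):
    assert assign_region(country) == region


def test_clean_removes_reports_without_drugs_or_reactions():
    col = make_collection(
        [
            {"report_id": "A", "drugs": [("LISINOPRIL", "suspect")], "reactions": ["cough"]},
            {"report_id": "B", "drugs": [("LISINOPRIL", "suspect")]},  # no reactions
            {"report_id": "C", "reactions": ["cough"]},  # no drugs
        ]
    )
    out = clean(col)
    assert list(out.report_ids) == ["A"]
    assert out.provenance["removed_missing_data"] == 2


def test_clean_window_filter():
    col = make_collection(
        [
            {"report_id": "A", "receipt_year": 2003, "receipt_quarter": 4,
             "drugs": [("X", "suspect")], "reactions": ["cough"]},
            {"report_id": "B", "receipt_year": 2004, "receipt_quarter": 1,
             "drugs": [("X", "suspect")], "reactions": ["headache"]},
            {"report_id": "C", "receipt_year": 2020, "receipt_quarter": 2,
             "drugs": [("X", "suspect")], "reactions": ["nausea"]},
        ]
    )
    out = clean(col, window_start=(2004, 1), window_end=(2020, 1))
    assert list(out.report_ids) == ["B"]
    assert out.provenance["removed_out_of_window"] == 2


def test_clean_keeps_highest_version():
    col = make_collection(
        [
            {"report_id": "A", "version": 1, "sex": "male",
             "drugs": [("X", "suspect")], "reactions": ["cough"]},
            {"report_id": "A", "version": 2, "sex": "female",
             "drugs": [("X", "suspect")], "reactions": ["cough"]},
        ]
    )
    out = clean(col)
    assert len(out) == 1
    assert out.demo["version"].iloc[0] == 2
    assert out.provenance["removed_older_version"] == 1


def test_field_duplicates_keep_first_by_file_order(dictionary):
    base = {
        "sex": "female", "age_group": "65-74", "country": "CA",
        "receipt_year": 2012, "receipt_quarter": 3,
        "reactions": ["cough", "lung_adenocarcinoma"],
    }
    col = make_collection(
        [
            {"report_id": "A", "drugs": [("LISINOPRIL 10MG", "suspect")], **base},
            # same generic set under a different spelling: still a duplicate
            {"report_id": "B", "drugs": [("ZESTRIL", "suspect")], **base},
            {"report_id": "C", "drugs": [("RAMIPRIL", "suspect")], **base},
        ]
    )
    out = clean(col, resolver=dictionary.resolve)
    assert set(out.report_ids) == {"A", "C"}  # B removed, last member C kept
    assert out.provenance["removed_field_duplicate"] == 1
    # switchable off
    assert len(clean(col, dedup=False, resolver=dictionary.resolve)) == 3


def test_clean_is_idempotent_and_reconciles_on_synthetic_data(dictionary):
    cfg = pv.SynthConfig(
        n_reports=5000, dup_rate=0.05, seed=7,
        missing_rates={"sex": 0.05, "age_group": 0.05},
    )
    col, truth = pv.generate(cfg)
    out = clean(col, resolver=dictionary.resolve)
    p = out.provenance
    removed = (
        p["removed_missing_data"] + p["removed_out_of_window"]
        + p["removed_older_version"] + p["removed_field_duplicate"]
    )
    assert p["output_reports"] + removed == p["input_reports"]
    # exactly the injected duplicates are removed
    assert len(out) == cfg.n_reports
    assert p["removed_field_duplicate"] == int(truth["is_duplicate"].sum())
    again = clean(out, resolver=dictionary.resolve)
    assert len(again) == len(out)
    assert list(again.report_ids) == list(out.report_ids)


def test_round_trip_write_then_read(tmp_path):
    cfg = pv.SynthConfig(n_reports=2000, dup_rate=0.02, seed=3)
    col, _ = pv.generate(cfg)
    pv.write_tables(col, tmp_path)
    back = read_tables(
        tmp_path / "demo.tsv", tmp_path / "drug.tsv",
        tmp_path / "reac.tsv", tmp_path / "indi.tsv",
    )
    assert col.equals(back)
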