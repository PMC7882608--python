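import numpy as np
import pandas as pd
import pytest

import pvsignal as pv
from pvsignal._util import ConfigError
from pvsignal.case_definition import classify
from pvsignal.disproportionality import ContingencyTable, compute_signal, results_frame
from pvsignal.strata import (
    ALL_REPORTS,
    Clause,
    StratumSpec,
    apply_stratum,
    default_strata,
    diabetes_report_ids,
    run_panel,
)

from conftest import make_collection

DRUGS = ("lisinopril", "ramipril")


def _mixed_fixture():
    return make_collection(
        [
            {"report_id": "F1", "sex": "female", "country": "US",
             "drugs": [("LISINOPRIL", "suspect")], "reactions": ["lung_adenocarcinoma"]},
            {"report_id": "M1", "sex": "male", "country": "DE",
             "drugs": [("LISINOPRIL", "suspect")], "reactions": ["cough"]},
            {"report_id": "U1", "sex": "unknown", "country": "unknown",
             "drugs": [("HCTZ", "suspect")], "reactions": ["non_small_cell_lung_cancer"]},
            {"report_id": "F2", "sex": "female", "country": "FR", "receipt_year": 2015,
             "drugs": [("OMEPRAZOLE", "suspect")], "reactions": ["nausea"],
             "indications": ["type_2_diabetes_mellitus"]},
        ]
    )


def test_sex_clause_filters(event_def):
    col = _mixed_fixture()
    out = apply_stratum(col, StratumSpec("female", (Clause("sex", "eq", "female"),)))
    assert set(out.report_ids) == {"F1", "F2"}


def test_region_ne_retains_unknown_region():
    col = _mixed_fixture()
    out = apply_stratum(col, StratumSpec("non_eu", (Clause("region", "ne", "Europe"),)))
    # DE and FR (Europe) removed; unknown-region report retained
    assert set(out.report_ids) == {"F1", "U1"}


def test_clause_matches_set_builder_oracle():
    col, _ = pv.generate(pv.SynthConfig(n_reports=3000, seed=17))
    spec = StratumSpec(
        "us_recent",
        (Clause("country", "eq", "US"), Clause("receipt_year", "ge", 2012)),
    )
    out = apply_stratum(col, spec)
    demo = col.demo
    oracle = set(
        demo.loc[(demo["country"] == "US") & (demo["receipt_year"] >= 2012), "report_id"]
    )
    assert set(out.report_ids) == oracle


def test_year_clause_matches_generator_bookkeeping():
    col, truth = pv.generate(pv.SynthConfig(n_reports=3000, seed=19))
    out = apply_stratum(col, StratumSpec("early", (Clause("receipt_year", "le", 2011),)))
    expected = int((col.demo["receipt_year"] <= 2011).sum())
    assert len(out) == expected


def test_unknown_field_or_op_is_config_error():
    with pytest.raises(ConfigError):
        Clause("weight", "eq", 80)
    with pytest.raises(ConfigError):
        Clause("sex", "matches", "f.*")


def test_diabetes_proxy_uses_indications_and_comedication(dictionary):
    col = make_collection(
        [
            {"report_id": "A", "indications": ["type_2_diabetes_mellitus"],
             "drugs": [("LISINOPRIL", "suspect")], "reactions": ["cough"]},
            {"report_id": "B", "drugs": [("METFORMIN", "concomitant"), ("HCTZ", "suspect")],
             "reactions": ["cough"]},
            {"report_id": "C", "drugs": [("LISINOPRIL", "suspect")], "reactions": ["cough"]},
        ]
    )
    assert diabetes_report_ids(col, dictionary) == {"A", "B"}
    out = apply_stratum(col, StratumSpec("dm", (Clause("diabetes", "eq", True),)), dictionary)
    assert set(out.report_ids) == {"A", "B"}


def test_extra_pt_exclusion_reclassify_vs_drop(event_def, dictionary, hierarchy):
    col = _mixed_fixture()
    reclass = StratumSpec(
        "excl_nsclc",
        case_pt_exclusions_extra=frozenset({"non_small_cell_lung_cancer"}),
    )
    panel = run_panel(col, event_def, DRUGS, [reclass], dictionary, hierarchy)
    row = panel[panel.label == "ACEI"].iloc[0]
    # U1 stays in the comparator but is no longer a case
    assert row.a + row.b + row.c + row.d == 4
    assert row.a + row.c == 1  # only F1 remains a case
    dropped = StratumSpec(
        "excl_nsclc_drop",
        case_pt_exclusions_extra=frozenset({"non_small_cell_lung_cancer"}),
        extra_excluded_mode="drop",
    )
    panel2 = run_panel(col, event_def, DRUGS, [dropped], dictionary, hierarchy)
    row2 = panel2[panel2.label == "ACEI"].iloc[0]
    assert row2.a + row2.b + row2.c + row2.d == 3  # U1 removed entirely


def test_panel_single_stratum_equals_direct_computation(event_def, dictionary, hierarchy):
    col, _ = pv.generate(pv.SynthConfig(n_reports=5000, seed=23))
    panel = run_panel(col, event_def, DRUGS, [ALL_REPORTS], dictionary, hierarchy)
    labeled = classify(col, event_def, "ACEI", dictionary, hierarchy)
    direct = compute_signal(ContingencyTable.from_labeled(labeled), label="ACEI")
    row = panel[(panel.label == "ACEI") & (panel.stratum == "all")].iloc[0]
    assert (row.a, row.b, row.c, row.d) == (
        direct.table.a, direct.table.b, direct.table.c, direct.table.d
    )
    expected_frame = results_frame([direct], stratum="all")
    assert row.ROR == expected_frame.ROR.iloc[0]
    assert bool(row.signal) == bool(direct.signal)


def test_sex_partition_cells_sum_to_unstratified(event_def, dictionary, hierarchy):
    col, _ = pv.generate(pv.SynthConfig(n_reports=8000, seed=29))
    strata = [
        ALL_REPORTS,
        StratumSpec("female", (Clause("sex", "eq", "female"),)),
        StratumSpec("male", (Clause("sex", "eq", "male"),)),
        StratumSpec("unknown", (Clause("sex", "eq", "unknown"),)),
    ]
    panel = run_panel(col, event_def, DRUGS, strata, dictionary, hierarchy)
    cls = panel[panel.label == "ACEI"].set_index("stratum")
    for cell in ["a", "b", "c", "d"]:
        assert (
            cls.loc["female", cell] + cls.loc["male", cell] + cls.loc["unknown", cell]
            == cls.loc["all", cell]
        )


def test_filters_never_increase_cells(event_def, dictionary, hierarchy):
    col, _ = pv.generate(pv.SynthConfig(n_reports=8000, seed=31))
    panel = run_panel(
        col, event_def, DRUGS,
        [ALL_REPORTS, StratumSpec("us", (Clause("country", "eq", "US"),))],
        dictionary, hierarchy,
    )
    cls = panel[panel.label == "ACEI"].set_index("stratum")
    for cell in ["a", "b", "c", "d"]:
        assert cls.loc["us", cell] <= cls.loc["all", cell]


def test_panel_row_order_and_determinism(event_def, dictionary, hierarchy):
    col, _ = pv.generate(pv.SynthConfig(n_reports=4000, seed=37))
    strata = default_strata()
    p1 = run_panel(col, event_def, DRUGS, strata, dictionary, hierarchy)
    p2 = run_panel(col, event_def, DRUGS, strata, dictionary, hierarchy)
    assert p1.to_csv(sep="\t", index=False) == p2.to_csv(sep="\t", index=False)
    first_block = p1[p1.stratum == "all"]["label"].tolist()
    assert first_block == ["ACEI", "lisinopril", "ramipril"]
    assert p1["stratum"].unique().tolist() == [s.name for s in strata]


def test_zero_report_stratum_emits_undefined_rows(event_def, dictionary, hierarchy):
    col = _mixed_fixture()
    spec = StratumSpec("nobody", (Clause("country", "eq", "JP"),))
    panel = run_panel(col, event_def, DRUGS, [spec], dictionary, hierarchy)
    assert len(panel) == 3
    assert (panel["signal"] == False).all()  # noqa: E712
    assert panel["ROR"].isna().all()


def test_duplicate_stratum_names_rejected(event_def):
    col = _mixed_fixture()
    with pytest.raises(ConfigError):
        run_panel(col, event_def, DRUGS, [ALL_REPORTS, StratumSpec("all")])


def test_sex_specific_effect_recovered(event_def, dictionary, hierarchy):
    """Injected female-only effect: female stratum estimate exceeds the
    male stratum estimate, each interval covering its own truth."""
    cfg = pv.SynthConfig(
        n_reports=150_000,
        true_or={"ACEI": {"female": 2.0, "male": 1.0, "unknown": 1.0}},
        seed=41,
    )
    col, _ = pv.generate(cfg)
    strata = [
        StratumSpec("female", (Clause("sex", "eq", "female"),)),
        StratumSpec("male", (Clause("sex", "eq", "male"),)),
    ]
    panel = run_panel(col, event_def, DRUGS, strata, dictionary, hierarchy)
    cls = panel[panel.label == "ACEI"].set_index("stratum")
    assert cls.loc["female", "ROR"] > cls.loc["male", "ROR"]
    assert cls.loc["female", "ROR_low"] <= 2.0 <= cls.loc["female", "ROR_high"]
    assert cls.loc["male", "ROR_low"] <= 1.0 <= cls.loc["male", "ROR_high"]
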