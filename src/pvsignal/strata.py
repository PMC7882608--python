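"""Subset and sensitivity reruns of the disproportionality analysis.

A stratum is a named, declarative filter over report demographics (AND of
(field, op, value) clauses), optionally extending the event definition
with extra excluded PTs.  Built-in strata cover the standard reruns for a
drug–event pair: gender subsets, removal of one reporting region,
reclassification (or removal) of a histology PT, restriction to a
comorbid subgroup identified by indication or co-medication, and a
narrower reporting-year window.  :func:`run_panel` reruns the full 2×2
computation per (drug-or-class × stratum) with a deterministic row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import ConfigError
from .case_definition import (
    DrugDictionary,
    EventDefinition,
    TermHierarchy,
    classify,
    default_dictionary,
    default_hierarchy,
    exposed_report_ids,
)
from .disproportionality import (
    DEFAULT_CRITERIA,
    ContingencyTable,
    CriteriaConfig,
    compute_signal,
    results_frame,
)
from .report_store import ReportCollection

#: Indication PTs identifying diabetic subjects (proxy; spontaneous-report
#: data carry no diagnosis table).
DIABETES_PTS = frozenset(
    {"diabetes_mellitus", "type_1_diabetes_mellitus", "type_2_diabetes_mellitus"}
)
ANTIDIABETIC_CLASS = "antidiabetic"

_OPS = {
    "eq": lambda s, v: s == v,
    "ne": lambda s, v: s != v,
    "lt": lambda s, v: s < v,
    "le": lambda s, v: s <= v,
    "gt": lambda s, v: s > v,
    "ge": lambda s, v: s >= v,
    "in": lambda s, v: s.isin(list(v)),
    "not_in": lambda s, v: ~s.isin(list(v)),
}

_FIELDS = {
    "sex", "age_group", "country", "region", "receipt_year", "receipt_quarter",
    "diabetes",
}


@dataclass(frozen=True)
class Clause:
    field: str
    op: str
    value: object

    def __post_init__(self) -> None:
        if self.field not in _FIELDS:
            raise ConfigError(f"unknown stratum filter field {self.field!r}")
        if self.op not in _OPS:
            raise ConfigError(f"unknown stratum filter op {self.op!r}")


@dataclass(frozen=True)
class StratumSpec:
    """Named pure filter with optional extra case exclusions.

    ``extra_excluded_mode`` controls how reports carrying an extra excluded
    PT are handled: ``"reclassify"`` (default) demotes them to non-cases by
    extending the event exclusion list; ``"drop"`` removes them from the
    stratum entirely.
    """

    name: str
    clauses: tuple[Clause, ...] = ()
    case_pt_exclusions_extra: frozenset[str] = frozenset()
    extra_excluded_mode: str = "reclassify"

    def __post_init__(self) -> None:
        if self.extra_excluded_mode not in ("reclassify", "drop"):
            raise ConfigError(
                f"unknown extra_excluded_mode {self.extra_excluded_mode!r}"
            )


ALL_REPORTS = StratumSpec("all")


def default_strata(event_def: EventDefinition | None = None) -> list[StratumSpec]:
    """The standard panel: overall, gender subsets, non-Europe, histology
    reclassification, diabetic subgroup, early-window restriction."""
    return [
        ALL_REPORTS,
        StratumSpec("female", (Clause("sex", "eq", "female"),)),
        StratumSpec("male", (Clause("sex", "eq", "male"),)),
        StratumSpec("non_europe", (Clause("region", "ne", "Europe"),)),
        StratumSpec(
            "excl_nsclc",
            case_pt_exclusions_extra=frozenset({"non_small_cell_lung_cancer"}),
        ),
        StratumSpec("diabetes", (Clause("diabetes", "eq", True),)),
        StratumSpec("2004_2011", (Clause("receipt_year", "le", 2011),)),
    ]


def diabetes_report_ids(
    collection: ReportCollection,
    dictionary: DrugDictionary | None = None,
) -> set[str]:
    """Reports flagged diabetic: a diabetes indication PT or an
    antidiabetic drug mention (any role)."""
    dictionary = dictionary or default_dictionary()
    indi = collection.indications
    by_indication = set(
        indi.loc[indi["pt_code"].isin(DIABETES_PTS), "report_id"]
    )
    by_drug = exposed_report_ids(collection, ANTIDIABETIC_CLASS, dictionary)
    return by_indication | by_drug


def apply_stratum(
    collection: ReportCollection,
    spec: StratumSpec,
    dictionary: DrugDictionary | None = None,
    hierarchy: TermHierarchy | None = None,
) -> ReportCollection:
    """Reports satisfying every clause of ``spec`` (pure; input unchanged).

    Filters on ``region`` with op ``ne`` naturally retain unknown-region
    reports, so removing one region never silently shrinks the unknown
    stratum.  In ``"drop"`` mode, reports carrying any extra excluded PT
    are removed here as well.
    """
    demo = collection.demo
    mask = pd.Series(True, index=demo.index)
    for cl in spec.clauses:
        if cl.field == "diabetes":
            flagged = demo["report_id"].isin(diabetes_report_ids(collection, dictionary))
            mask &= _OPS[cl.op](flagged, cl.value)
        else:
            mask &= _OPS[cl.op](demo[cl.field], cl.value)
    ids = set(demo.loc[mask, "report_id"])
    if spec.case_pt_exclusions_extra and spec.extra_excluded_mode == "drop":
        reac = collection.reactions
        carrying = set(
            reac.loc[reac["pt_code"].isin(spec.case_pt_exclusions_extra), "report_id"]
        )
        ids -= carrying
    return collection.subset(ids)


def effective_event_def(event_def: EventDefinition, spec: StratumSpec) -> EventDefinition:
    if spec.case_pt_exclusions_extra and spec.extra_excluded_mode == "reclassify":
        return event_def.with_extra_exclusions(spec.case_pt_exclusions_extra)
    return event_def


def run_panel(
    collection: ReportCollection,
    event_def: EventDefinition,
    drug_list,
    strata_list=None,
    dictionary: DrugDictionary | None = None,
    hierarchy: TermHierarchy | None = None,
    class_query: str = "ACEI",
    criteria: CriteriaConfig = DEFAULT_CRITERIA,
    alpha: float = 0.05,
    ic_method: str = "normal",
) -> pd.DataFrame:
    """Signal table over (class + each drug) × strata.

    Row order is deterministic: strata in list order; within a stratum the
    class row first, then drugs alphabetically.  A stratum with zero
    exposed reports still emits its row (ROR flagged corrected/undefined as
    the zero cells dictate) rather than being dropped.
    """
    dictionary = dictionary or default_dictionary()
    hierarchy = hierarchy or default_hierarchy()
    strata_list = list(strata_list) if strata_list is not None else [ALL_REPORTS]
    names = [s.name for s in strata_list]
    if len(set(names)) != len(names):
        raise ConfigError("stratum names must be unique within a run")

    frames = []
    for spec in strata_list:
        sub = apply_stratum(collection, spec, dictionary, hierarchy)
        edef = effective_event_def(event_def, spec)
        queries = [(class_query, class_query)] + [
            (d, d) for d in sorted(drug_list)
        ]
        results = []
        empty_labels = []
        for label, query in queries:
            if len(sub) == 0:
                empty_labels.append(label)
                continue
            labeled = classify(sub, edef, query, dictionary, hierarchy)
            table = ContingencyTable.from_labeled(labeled)
            results.append(
                compute_signal(
                    table, label=label, alpha=alpha, criteria=criteria,
                    ic_method=ic_method,
                )
            )
        frame = results_frame(results, stratum=spec.name)
        if empty_labels:
            # empty stratum: emit undefined-marker rows rather than dropping
            filler = pd.DataFrame(
                [
                    {"label": lb, "stratum": spec.name, "a": 0, "b": 0, "c": 0,
                     "d": 0, "expected": float("nan"), "ROR": float("nan"),
                     "ROR_low": float("nan"), "ROR_high": float("nan"),
                     "IC": float("nan"), "IC_low": float("nan"),
                     "IC_high": float("nan"), "signal": False,
                     "criteria_detail": "none", "corrected": False}
                    for lb in empty_labels
                ]
            )
            frame = pd.concat([filler, frame], ignore_index=True) if frame.empty else pd.concat([frame, filler], ignore_index=True)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
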