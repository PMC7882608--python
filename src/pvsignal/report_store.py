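"""Ingest, validate, clean and deduplicate spontaneous adverse-event reports.

A report collection mirrors the four-table layout of FAERS quarterly data:
demographics (one row per report version), drug mentions, reaction terms and
indication terms, all keyed by ``report_id``.  The collection is held as four
pandas DataFrames; :class:`AEReport` provides a per-report object view.

Cleaning follows standard pharmacovigilance practice for spontaneous
reporting systems: drop reports with no drug or no reaction (uninterpretable
for a case/non-case analysis), restrict to the study window, and
deduplicate — first by case versioning (a resubmitted report supersedes
earlier versions of the same ``report_id``), then by exact agreement on a
demographic + drug-set + reaction-set fingerprint, which catches the common
FAERS failure mode of the same case arriving under distinct identifiers.
Demographic missingness (unknown sex, age or country) is *not* a removal
criterion: unknown strata are retained and reported as such.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterator, Mapping

import pandas as pd
import yaml

from ._util import SchemaError, data_path

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "unknown")
AGE_GROUPS = ("<18", "18-44", "45-64", "65-74", ">75", "unknown")
REGIONS = ("America", "Europe", "Asia", "Oceania", "Africa", "unknown")
ROLES = ("suspect", "interacting", "concomitant")
OUTCOMES = ("hospitalization", "disability", "life-threatening", "death")

#: Left-closed age bin edges; an age equal to an edge falls in the older bin.
AGE_BIN_EDGES = (18, 45, 65, 75)

DEMO_COLUMNS = [
    "report_id", "version", "sex", "age_group", "country", "region",
    "receipt_year", "receipt_quarter", "outcomes",
]
DRUG_COLUMNS = ["report_id", "verbatim_name", "generic_name", "role"]
PT_COLUMNS = ["report_id", "pt_code"]


@dataclass(frozen=True)
class DrugMention:
    """One drug row of a report: the reported name, its resolved generic
    (``None`` until dictionary resolution) and its reporting role."""

    verbatim_name: str
    generic_name: str | None
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown drug role {self.role!r}")


@dataclass(frozen=True)
class AEReport:
    """Object view of one spontaneous report."""

    report_id: str
    version: int
    sex: str
    age_group: str
    country: str
    region: str
    receipt_year: int
    receipt_quarter: int
    drugs: tuple[DrugMention, ...]
    reactions: tuple[str, ...]
    indications: tuple[str, ...] = ()
    serious_outcomes: frozenset[str] = frozenset()


@lru_cache(maxsize=1)
def _region_map() -> dict[str, str]:
    with data_path("country_region.tsv").open() as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return {r["country"]: r["region"] for r in rows}


def assign_region(country_code: str | None) -> str:
    """Map an ISO-3166 alpha-2 country code to a reporting region.

    Total function: ``None``, empty, ``"unknown"`` or unmapped codes all
    yield ``"unknown"``.
    """
    if not country_code or country_code == "unknown":
        return "unknown"
    return _region_map().get(str(country_code).upper(), "unknown")


def bin_age(age: float, edges: tuple[int, ...] = AGE_BIN_EDGES) -> str:
    """Assign a raw age (years) to its group; edges are left-closed, so an
    age exactly on an edge goes to the older group (75 -> ``>75``)."""
    if age != age or age is None:  # NaN
        return "unknown"
    e = edges
    if age < e[0]:
        return "<18"
    if age < e[1]:
        return "18-44"
    if age < e[2]:
        return "45-64"
    if age < e[3]:
        return "65-74"
    return ">75"


class ReportCollection:
    """Four joined report tables plus a provenance log of cleaning counts.

    Parameters
    ----------
    demo, drugs, reactions, indications
        DataFrames with the canonical columns (`DEMO_COLUMNS` etc.).
    provenance
        Counts in/out per ingest or cleaning rule.  After :func:`clean`,
        ``output_reports + sum(removed_*) == input_reports`` exactly.
    """

    def __init__(
        self,
        demo: pd.DataFrame,
        drugs: pd.DataFrame,
        reactions: pd.DataFrame,
        indications: pd.DataFrame | None = None,
        provenance: Mapping[str, int] | None = None,
    ) -> None:
        self.demo = demo.reset_index(drop=True)
        self.drugs = drugs.reset_index(drop=True)
        self.reactions = reactions.reset_index(drop=True)
        if indications is None:
            indications = pd.DataFrame(columns=PT_COLUMNS)
        self.indications = indications.reset_index(drop=True)
        self.provenance: dict[str, int] = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.demo)

    @property
    def report_ids(self) -> pd.Series:
        return self.demo["report_id"]

    def subset(self, report_ids) -> "ReportCollection":
        """Collection restricted to ``report_ids`` (order of ``demo`` kept)."""
        ids = set(report_ids)
        return ReportCollection(
            self.demo[self.demo["report_id"].isin(ids)],
            self.drugs[self.drugs["report_id"].isin(ids)],
            self.reactions[self.reactions["report_id"].isin(ids)],
            self.indications[self.indications["report_id"].isin(ids)],
            provenance=self.provenance,
        )

    def iter_reports(self) -> Iterator[AEReport]:
        drug_rows = _group_rows(self.drugs, ["verbatim_name", "generic_name", "role"])
        reac_rows = _group_values(self.reactions)
        indi_rows = _group_values(self.indications)
        for row in self.demo.itertuples(index=False):
            rid = row.report_id
            drugs = tuple(
                DrugMention(v, None if g != g or g in (None, "") else g, r)
                for v, g, r in drug_rows.get(rid, ())
            )
            outcomes = frozenset(
                o for o in str(row.outcomes).split(";") if o and o != "nan"
            )
            yield AEReport(
                report_id=rid,
                version=int(row.version),
                sex=row.sex,
                age_group=row.age_group,
                country=row.country,
                region=row.region,
                receipt_year=int(row.receipt_year),
                receipt_quarter=int(row.receipt_quarter),
                drugs=drugs,
                reactions=tuple(reac_rows.get(rid, ())),
                indications=tuple(indi_rows.get(rid, ())),
                serious_outcomes=outcomes,
            )

    def get(self, report_id: str) -> AEReport:
        sub = self.subset([report_id])
        for rep in sub.iter_reports():
            return rep
        raise KeyError(report_id)

    def equals(self, other: "ReportCollection") -> bool:
        """Content equality ignoring row order and provenance."""
        def norm(df: pd.DataFrame, keys) -> pd.DataFrame:
            out = df.copy()
            for c in out.columns:
                out[c] = out[c].astype(object)
                out[c] = out[c].where(out[c].notna(), "")
            return out.sort_values(list(keys)).reset_index(drop=True)

        try:
            pd.testing.assert_frame_equal(
                norm(self.demo, DEMO_COLUMNS[:2]), norm(other.demo, DEMO_COLUMNS[:2]),
                check_dtype=False)
            pd.testing.assert_frame_equal(
                norm(self.drugs, DRUG_COLUMNS), norm(other.drugs, DRUG_COLUMNS),
                check_dtype=False)
            pd.testing.assert_frame_equal(
                norm(self.reactions, PT_COLUMNS), norm(other.reactions, PT_COLUMNS),
                check_dtype=False)
            pd.testing.assert_frame_equal(
                norm(self.indications, PT_COLUMNS), norm(other.indications, PT_COLUMNS),
                check_dtype=False)
        except AssertionError:
            return False
        return True

    def to_tables(self, out_dir, sep: str = "\t") -> dict[str, Path]:
        """Write the four canonical tables (``demo/drug/reac/indi.tsv``)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        demo = self.demo.drop(columns=["region"])  # derived, not serialized
        for name, df in [
            ("demo", demo),
            ("drug", self.drugs.drop(columns=["generic_name"])),
            ("reac", self.reactions),
            ("indi", self.indications),
        ]:
            p = out / f"{name}.tsv"
            df.to_csv(p, sep=sep, index=False)
            paths[name] = p
        return paths


def _group_rows(df: pd.DataFrame, cols) -> dict[str, list[tuple]]:
    out: dict[str, list[tuple]] = {}
    for row in df[["report_id", *cols]].itertuples(index=False):
        out.setdefault(row[0], []).append(tuple(row[1:]))
    return out


def _group_values(df: pd.DataFrame) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for rid, pt in df[["report_id", "pt_code"]].itertuples(index=False):
        out.setdefault(rid, []).append(pt)
    return out


# ---------------------------------------------------------------- ingest ---

_MANDATORY = {
    "demo": ["report_id", "sex", "country", "receipt_year", "receipt_quarter"],
    "drug": ["report_id", "verbatim_name", "role"],
    "reac": ["report_id", "pt_code"],
    "indi": ["report_id", "pt_code"],
}


def _load_schema(schema_config) -> dict:
    if schema_config is None:
        return {}
    if isinstance(schema_config, (str, Path)):
        with open(schema_config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(schema_config)


def _read_one(path, table: str, cfg: dict, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} table not found: {path}")
    rename = {v: k for k, v in (cfg.get(table) or {}).items()}
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = df.rename(columns=rename)
    for col in _MANDATORY[table]:
        if col == "sex" and "sex" not in df.columns:
            continue  # validated below with age alternatives
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing mandatory column {col!r}")
    return df


def read_tables(
    demo_path,
    drug_path,
    reac_path,
    indi_path=None,
    schema_config=None,
    sep: str | None = None,
) -> ReportCollection:
    """Read the four delimited report tables and join them into a collection.

    ``schema_config`` (dict or YAML path) may remap column names per table,
    e.g. ``{"demo": {"report_id": "primaryid"}}`` (canonical -> actual), and
    set ``delimiter``.  Rows in the drug/reaction/indication tables whose
    ``report_id`` is absent from demographics are dropped and counted as
    orphans; demographic rows with unparseable year/quarter are dropped and
    counted; only the first row per ``(report_id, version)`` is kept.
    """
    cfg = _load_schema(schema_config)
    sep = sep if sep is not None else cfg.get("delimiter", "\t")
    prov: dict[str, int] = {}

    demo = _read_one(demo_path, "demo", cfg, sep)
    prov["demo_rows_in"] = len(demo)
    if "sex" not in demo.columns:
        raise SchemaError("demo table is missing mandatory column 'sex'")
    if "age_group" not in demo.columns and "age" not in demo.columns:
        raise SchemaError("demo table needs an 'age' or 'age_group' column")

    if "version" not in demo.columns:
        demo["version"] = "1"
    demo["version"] = pd.to_numeric(demo["version"], errors="coerce")
    demo["receipt_year"] = pd.to_numeric(demo["receipt_year"], errors="coerce")
    demo["receipt_quarter"] = pd.to_numeric(demo["receipt_quarter"], errors="coerce")
    bad = (
        demo["receipt_year"].isna()
        | demo["receipt_quarter"].isna()
        | ~demo["receipt_quarter"].isin([1, 2, 3, 4])
        | demo["version"].isna()
        | (demo["report_id"].astype(str).str.len() == 0)
    )
    prov["unparseable_demo_rows"] = int(bad.sum())
    if bad.any():
        logger.warning("dropped %d unparseable demographic rows", bad.sum())
    demo = demo[~bad].copy()

    demo["sex"] = demo["sex"].str.strip().str.lower().where(
        demo["sex"].str.strip().str.lower().isin(SEXES[:2]), "unknown"
    )
    if "age_group" in demo.columns:
        demo["age_group"] = demo["age_group"].where(
            demo["age_group"].isin(AGE_GROUPS), "unknown"
        )
    else:
        ages = pd.to_numeric(demo["age"], errors="coerce")
        demo["age_group"] = [bin_age(a) for a in ages]
        demo = demo.drop(columns=["age"])
    demo["country"] = (
        demo["country"].str.strip().str.upper()
        .replace({"": "unknown", "UNKNOWN": "unknown"})
    )
    demo["region"] = demo["country"].map(assign_region)
    if "outcomes" not in demo.columns:
        demo["outcomes"] = ""
    demo["version"] = demo["version"].astype(int)
    demo["receipt_year"] = demo["receipt_year"].astype(int)
    demo["receipt_quarter"] = demo["receipt_quarter"].astype(int)

    dup_key = demo.duplicated(subset=["report_id", "version"], keep="first")
    prov["duplicate_key_demo_rows"] = int(dup_key.sum())
    demo = demo[~dup_key]
    demo = demo[DEMO_COLUMNS]

    known = set(demo["report_id"])

    def attach(df: pd.DataFrame | None, table: str, columns) -> pd.DataFrame:
        if df is None:
            return pd.DataFrame(columns=columns)
        orphan = ~df["report_id"].isin(known)
        prov[f"orphan_{table}_rows"] = int(orphan.sum())
        if orphan.any():
            logger.warning("dropped %d orphan %s rows", orphan.sum(), table)
        return df[~orphan].copy()

    drugs = attach(_read_one(drug_path, "drug", cfg, sep), "drug", DRUG_COLUMNS)
    if "generic_name" not in drugs.columns:
        drugs["generic_name"] = None
    drugs["role"] = drugs["role"].str.strip().str.lower()
    drugs = drugs[drugs["role"].isin(ROLES)][DRUG_COLUMNS]
    reactions = attach(_read_one(reac_path, "reac", cfg, sep), "reac", PT_COLUMNS)
    reactions = reactions[PT_COLUMNS]
    indications = None
    if indi_path is not None:
        indications = attach(_read_one(indi_path, "indi", cfg, sep), "indi", PT_COLUMNS)
        indications = indications[PT_COLUMNS]

    prov["reports"] = len(demo)
    return ReportCollection(demo, drugs, reactions, indications, provenance=prov)


# --------------------------------------------------------------- cleaning ---

def _yq(year, quarter) -> int:
    return int(year) * 4 + int(quarter) - 1


def _fingerprint(
    collection: ReportCollection, resolver: Callable[[str], str] | None
) -> pd.Series:
    """Field-match key per report: demographics + sorted drug set (generic
    where resolvable) + sorted reaction PT set."""
    drugs = collection.drugs
    if resolver is None:
        names = drugs["verbatim_name"].astype(str).str.upper()
    else:
        uniq = {v: resolver(v) for v in drugs["verbatim_name"].astype(str).unique()}
        names = drugs["verbatim_name"].astype(str).map(uniq)
        names = names.where(names.notna() & (names != ""), drugs["verbatim_name"].astype(str).str.upper())
    dset = (
        pd.DataFrame({"report_id": drugs["report_id"], "n": names})
        .groupby("report_id")["n"]
        .apply(lambda s: "|".join(sorted(set(s))))
    )
    rset = (
        collection.reactions.groupby("report_id")["pt_code"]
        .apply(lambda s: "|".join(sorted(set(s))))
    )
    demo = collection.demo
    key = (
        demo["sex"].astype(str)
        + "\x1f" + demo["age_group"].astype(str)
        + "\x1f" + demo["country"].astype(str)
        + "\x1f" + demo["receipt_year"].astype(str)
        + "\x1f" + demo["receipt_quarter"].astype(str)
        + "\x1f" + demo["report_id"].map(dset).fillna("")
        + "\x1f" + demo["report_id"].map(rset).fillna("")
    )
    return key


def clean(
    collection: ReportCollection,
    window_start: tuple[int, int] = (2004, 1),
    window_end: tuple[int, int] = (2020, 1),
    dedup: bool = True,
    resolver: Callable[[str], str] | None = None,
) -> ReportCollection:
    """Apply missing-data removal, study-window restriction and deduplication.

    Removal rules, in order:

    1. reports with no drug mention or no reaction term (``removed_missing_data``);
    2. reports received outside ``[window_start, window_end]`` in
       (year, quarter) order (``removed_out_of_window``);
    3. older versions of a resubmitted ``report_id`` — the highest version
       wins (``removed_older_version``);
    4. exact field-match duplicates (see :func:`_fingerprint`) — the first in
       file order wins (``removed_field_duplicate``); disabled with
       ``dedup=False``.

    ``resolver`` optionally maps verbatim drug names to generic names for
    the duplicate fingerprint (pass ``DrugDictionary.resolve``).  The
    operation is idempotent and its provenance reconciles exactly.
    """
    if _yq(*window_start) > _yq(*window_end):
        raise ValueError("window_start must not be after window_end")
    demo = collection.demo
    n_in = len(demo)
    prov = dict(collection.provenance)
    prov["input_reports"] = n_in

    with_drug = demo["report_id"].isin(set(collection.drugs["report_id"]))
    with_reac = demo["report_id"].isin(set(collection.reactions["report_id"]))
    missing = ~(with_drug & with_reac)
    prov["removed_missing_data"] = int(missing.sum())
    demo = demo[~missing]

    yq = demo["receipt_year"] * 4 + demo["receipt_quarter"] - 1
    in_window = (yq >= _yq(*window_start)) & (yq <= _yq(*window_end))
    prov["removed_out_of_window"] = int((~in_window).sum())
    demo = demo[in_window]

    # keep the highest version per report_id; ties broken by file order
    max_v = demo.groupby("report_id")["version"].transform("max")
    first_at_max = ~demo[demo["version"] == max_v].duplicated("report_id", keep="first")
    keep_version = (demo["version"] == max_v) & first_at_max.reindex(demo.index, fill_value=False)
    prov["removed_older_version"] = int((~keep_version).sum())
    demo = demo[keep_version]

    removed_dup = 0
    if dedup and len(demo):
        sub = ReportCollection(
            demo, collection.drugs, collection.reactions, collection.indications
        )
        fp = _fingerprint(sub, resolver)
        dup = fp.duplicated(keep="first")
        removed_dup = int(dup.sum())
        demo = sub.demo[~dup.values]
    prov["removed_field_duplicate"] = removed_dup
    prov["output_reports"] = len(demo)

    removed = (
        prov["removed_missing_data"]
        + prov["removed_out_of_window"]
        + prov["removed_older_version"]
        + prov["removed_field_duplicate"]
    )
    assert prov["output_reports"] + removed == n_in, "provenance does not reconcile"
    if prov["output_reports"] == 0:
        logger.warning("cleaning removed every report")

    ids = set(demo["report_id"])
    out = ReportCollection(
        demo,
        collection.drugs[collection.drugs["report_id"].isin(ids)],
        collection.reactions[collection.reactions["report_id"].isin(ids)],
        collection.indications[collection.indications["report_id"].isin(ids)],
        provenance=prov,
    )
    return out
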