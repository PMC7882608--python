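"""Case and exposure definitions over a miniature MedDRA-style vocabulary.

A *case* is a report carrying at least one reaction Preferred Term (PT)
that falls under the target Higher Level Term (HLT) and is not on the
exclusion list — the mechanism used to restrict a broad HLT such as
"Lower respiratory tract neoplasms" to primary malignant disease by
excluding benign, metastatic and infiltrative PTs.  A report whose only
qualifying PTs are excluded is a non-case.

*Exposure* is defined at report level: a report is exposed to a drug class
(or a single generic) if any of its drug mentions resolves, after name
normalization, to a generic in that class, in any reporting role
(suspect, interacting or concomitant) unless a role subset is requested.
Each report counts once however many qualifying PTs or mentions it has.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import ConfigError, data_path
from .report_store import AEReport, ReportCollection, ROLES

logger = logging.getLogger(__name__)

#: Default composite event: primary malignant lung cancer.
TARGET_HLT = "lower_respiratory_tract_neoplasms"
DEFAULT_EXCLUDED_PTS = frozenset(
    {
        "carcinoid_tumour_pulmonary",
        "leukaemic_infiltration_pulmonary",
        "endobronchial_lipoma",
        "benign_respiratory_tract_neoplasm",
        "benign_lung_neoplasm",
        "metastases_to_lung",
    }
)

_warned_pts: set[str] = set()

# tokens stripped during drug-name normalization: anything containing a
# digit (doses, strengths) plus common form/route words
_FORM_WORDS = frozenset(
    """MG ML MCG G TABLET TABLETS TAB TABS CAPSULE CAPSULES CAP CAPS ORAL
    INJECTION SOLUTION SUSPENSION FILM COATED EXTENDED RELEASE ER XR SR
    UNKNOWN""".split()
)


def normalize_drug_name(verbatim: str) -> str:
    """Uppercase, drop punctuation and dose/route tokens, collapse spaces.

    ``"Lisinopril 10MG Tablet"`` -> ``"LISINOPRIL"``.  Deterministic, no
    fuzzy matching.
    """
    s = re.sub(r"[^A-Za-z0-9 ]+", " ", str(verbatim)).upper()
    tokens = [
        t for t in s.split()
        if t and not any(ch.isdigit() for ch in t) and t not in _FORM_WORDS
    ]
    return " ".join(tokens)


class TermHierarchy:
    """PT -> HLT map with display labels, loaded from a two-level TSV."""

    def __init__(self, pt_to_hlt: dict[str, str], labels: dict[str, str]):
        self.pt_to_hlt = dict(pt_to_hlt)
        self.labels = dict(labels)

    @classmethod
    def from_tsv(cls, path=None) -> "TermHierarchy":
        """Load from TSV (columns ``pt_code pt_name hlt_code hlt_name``);
        default is the packaged miniature vocabulary."""
        src = Path(path) if path is not None else data_path("meddra_mini.tsv")
        with src.open() as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        pt_to_hlt, labels = {}, {}
        for r in rows:
            pt_to_hlt[r["pt_code"]] = r["hlt_code"]
            labels[r["pt_code"]] = r["pt_name"]
            labels[r["hlt_code"]] = r["hlt_name"]
        return cls(pt_to_hlt, labels)

    def pts_under(self, hlt: str) -> frozenset[str]:
        return frozenset(pt for pt, h in self.pt_to_hlt.items() if h == hlt)

    def __contains__(self, pt: str) -> bool:
        return pt in self.pt_to_hlt


@lru_cache(maxsize=1)
def default_hierarchy() -> TermHierarchy:
    return TermHierarchy.from_tsv()


@dataclass(frozen=True)
class EventDefinition:
    """Composite adverse event: one HLT minus an excluded-PT set."""

    hlt: str = TARGET_HLT
    excluded_pts: frozenset[str] = DEFAULT_EXCLUDED_PTS
    label: str = "primary malignant lung cancer"

    def validate(self, hierarchy: TermHierarchy) -> None:
        under = hierarchy.pts_under(self.hlt)
        if not under:
            raise ConfigError(f"HLT {self.hlt!r} has no PTs in the vocabulary")
        stray = self.excluded_pts - under
        if stray:
            raise ConfigError(
                f"excluded PTs not under HLT {self.hlt!r}: {sorted(stray)}"
            )

    def with_extra_exclusions(self, pts) -> "EventDefinition":
        return EventDefinition(self.hlt, self.excluded_pts | frozenset(pts), self.label)

    @classmethod
    def from_yaml(cls, path) -> "EventDefinition":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            hlt=cfg["hlt"],
            excluded_pts=frozenset(cfg.get("excluded_pts", ())),
            label=cfg.get("label", cfg["hlt"]),
        )


class DrugDictionary:
    """Synonym -> generic -> class lookup with normalized, case-insensitive
    matching.  The packaged dictionary covers the ten FDA-approved ACE
    inhibitors, the ARB comparator irbesartan, thiazide diuretics (the
    adjusted-model reference class), antidiabetics and decoy classes."""

    def __init__(self, synonym_to_generic: dict[str, str], generic_to_class: dict[str, str]):
        self.synonym_to_generic = {
            normalize_drug_name(k): v for k, v in synonym_to_generic.items()
        }
        self.generic_to_class = dict(generic_to_class)

    @classmethod
    def from_tsv(cls, path=None) -> "DrugDictionary":
        src = Path(path) if path is not None else data_path("drug_dictionary.tsv")
        with src.open() as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        return cls(
            {r["synonym"]: r["generic"] for r in rows},
            {r["generic"]: r["class"] for r in rows},
        )

    def resolve(self, verbatim: str) -> str | None:
        """Generic name for a verbatim mention, or ``None`` if unresolvable."""
        return self.synonym_to_generic.get(normalize_drug_name(verbatim))

    def classes(self) -> frozenset[str]:
        return frozenset(self.generic_to_class.values())

    def generics_for(self, query: str) -> frozenset[str]:
        """Generic set for a class label or a single generic name.

        Raises :class:`ConfigError` when the query resolves to nothing.
        """
        if query in self.generic_to_class:
            return frozenset([query])
        hits = frozenset(
            g for g, c in self.generic_to_class.items() if c == query
        )
        if not hits:
            raise ConfigError(f"unknown drug class or generic: {query!r}")
        return hits


@lru_cache(maxsize=1)
def default_dictionary() -> DrugDictionary:
    return DrugDictionary.from_tsv()


def is_case(
    report: AEReport, event_def: EventDefinition, hierarchy: TermHierarchy
) -> bool:
    """True iff some reaction PT falls under the event HLT and is not
    excluded.  PTs absent from the vocabulary never qualify (logged once
    per code)."""
    for pt in report.reactions:
        hlt = hierarchy.pt_to_hlt.get(pt)
        if hlt is None:
            if pt not in _warned_pts:
                _warned_pts.add(pt)
                logger.warning("reaction PT %r not in vocabulary; ignored", pt)
            continue
        if hlt == event_def.hlt and pt not in event_def.excluded_pts:
            return True
    return False


def is_exposed(
    report: AEReport,
    query: str,
    dictionary: DrugDictionary,
    roles=ROLES,
) -> bool:
    """True iff any drug mention resolves to a generic in ``query`` (class
    label or generic name) with a role in ``roles`` (default: all three)."""
    targets = dictionary.generics_for(query)
    roles = frozenset(roles)
    for m in report.drugs:
        if m.role not in roles:
            continue
        generic = m.generic_name or dictionary.resolve(m.verbatim_name)
        if generic in targets:
            return True
    return False


@dataclass
class LabeledCollection:
    """A report collection with per-report (case, exposed) flags.

    ``labels`` has columns ``report_id, case, exposed`` aligned with
    ``collection.demo``.
    """

    collection: ReportCollection
    labels: pd.DataFrame
    event_def: EventDefinition
    exposure_query: str

    def counts(self) -> tuple[int, int, int, int]:
        """Cell counts (a, b, c, d) = (exposed case, exposed non-case,
        unexposed case, unexposed non-case)."""
        case = self.labels["case"].to_numpy()
        exp = self.labels["exposed"].to_numpy()
        a = int((case & exp).sum())
        b = int((~case & exp).sum())
        c = int((case & ~exp).sum())
        d = int((~case & ~exp).sum())
        return a, b, c, d


def exposed_report_ids(
    collection: ReportCollection,
    query: str,
    dictionary: DrugDictionary,
    roles=ROLES,
) -> set[str]:
    """Report ids exposed to ``query``, computed vectorized over the drug
    table (agrees with :func:`is_exposed` report by report)."""
    targets = dictionary.generics_for(query)
    drugs = collection.drugs
    if drugs.empty:
        return set()
    verb = drugs["verbatim_name"]
    if isinstance(verb.dtype, pd.CategoricalDtype):
        # resolve each distinct spelling once
        cats = np.asarray(
            [dictionary.resolve(v) for v in verb.cat.categories], dtype=object
        )
        fallback = pd.Series(cats[verb.cat.codes], index=verb.index)
    else:
        uniq = {v: dictionary.resolve(v) for v in verb.astype(str).unique()}
        fallback = verb.astype(str).map(uniq)
    resolved = drugs["generic_name"] if "generic_name" in drugs else None
    if resolved is None:
        generic = fallback
    else:
        generic = resolved.where(resolved.notna() & (resolved != ""), fallback)
    mask = generic.isin(targets) & drugs["role"].isin(frozenset(roles))
    return set(drugs.loc[mask, "report_id"])


def case_report_ids(
    collection: ReportCollection,
    event_def: EventDefinition,
    hierarchy: TermHierarchy,
) -> set[str]:
    """Report ids satisfying the event definition (vectorized)."""
    reac = collection.reactions
    if reac.empty:
        return set()
    hlt = reac["pt_code"].map(hierarchy.pt_to_hlt)
    unknown = sorted(set(reac.loc[hlt.isna(), "pt_code"]) - _warned_pts)
    for pt in unknown:
        _warned_pts.add(pt)
        logger.warning("reaction PT %r not in vocabulary; ignored", pt)
    qual = (hlt == event_def.hlt) & ~reac["pt_code"].isin(event_def.excluded_pts)
    return set(reac.loc[qual, "report_id"])


def classify(
    collection: ReportCollection,
    event_def: EventDefinition,
    exposure_query: str,
    dictionary: DrugDictionary | None = None,
    hierarchy: TermHierarchy | None = None,
    roles=ROLES,
) -> LabeledCollection:
    """Label every report with (case?, exposed?) flags.

    The four cell counts are available from :meth:`LabeledCollection.counts`
    and always partition the collection.
    """
    dictionary = dictionary or default_dictionary()
    hierarchy = hierarchy or default_hierarchy()
    event_def.validate(hierarchy)
    cases = case_report_ids(collection, event_def, hierarchy)
    exposed = exposed_report_ids(collection, exposure_query, dictionary, roles)
    rid = collection.demo["report_id"]
    labels = pd.DataFrame(
        {
            "report_id": rid,
            "case": rid.isin(cases).to_numpy(),
            "exposed": rid.isin(exposed).to_numpy(),
        }
    )
    return LabeledCollection(collection, labels, event_def, exposure_query)
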