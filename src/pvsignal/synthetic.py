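"""FAERS-like synthetic report generator with recorded ground truth.

Every pipeline stage is testable without any real data download: the
generator draws report demographics from configurable categorical
distributions (defaults loosely matching the population margins of a
large spontaneous-report database: ~46% male / 46% female / 8% unknown
sex, age mode 45–64, ~60% US), drug-class exposures and the target event
through logistic links with known odds ratios, then attaches reaction and
indication terms from the packaged miniature vocabulary, and finally
injects field-exact duplicate records and per-field missingness.

Ground truth (latent exposure and event labels, duplicate provenance) is
returned alongside the collection, so classification, cleaning and
estimation can each be checked against the generating mechanism.

Design properties worth knowing:

* One pseudo-random stream per run, seeded from the config: the same seed
  reproduces byte-identical tables.
* The latent event *is* the case definition's target (a primary malignant
  PT is attached iff the event fired).  Excluded PTs under the target HLT
  (benign/metastatic lookalikes) are attached independently of exposure at
  ``excluded_pt_rate``, exercising the exclusion logic without touching
  the true odds ratio.
* Injected duplicates are exact field copies under fresh report ids, and
  the generator perturbs receipt dates until original reports have unique
  demographic + drug-set + reaction-set fingerprints — so the field-match
  deduplication rule removes exactly the injected copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ConfigError
from .report_store import (
    DEMO_COLUMNS,
    DRUG_COLUMNS,
    PT_COLUMNS,
    ReportCollection,
    assign_region,
)

TARGET_PTS = (
    "lung_neoplasm_malignant",
    "lung_adenocarcinoma",
    "lung_squamous_cell_carcinoma",
    "small_cell_lung_cancer",
    "non_small_cell_lung_cancer",
    "bronchial_carcinoma",
    "bronchioloalveolar_carcinoma",
)
EXCLUDED_PTS = (
    "carcinoid_tumour_pulmonary",
    "leukaemic_infiltration_pulmonary",
    "endobronchial_lipoma",
    "benign_respiratory_tract_neoplasm",
    "benign_lung_neoplasm",
    "metastases_to_lung",
)
DECOY_PTS = (
    "headache", "migraine", "dizziness", "syncope", "nausea", "vomiting",
    "diarrhoea", "cough", "productive_cough", "dyspnoea", "rash", "fatigue",
    "oedema_peripheral", "hypotension", "cardiac_failure",
)

CLASS_GENERICS = {
    "ACEI": (
        "benazepril", "captopril", "enalapril", "fosinopril", "lisinopril",
        "moexipril", "perindopril", "quinapril", "ramipril", "trandolapril",
    ),
    "thiazide": ("hydrochlorothiazide", "chlorothiazide", "bendroflumethiazide"),
    "irbesartan": ("irbesartan",),
    "statin": ("atorvastatin", "simvastatin"),
    "ppi": ("omeprazole", "pantoprazole"),
}
ANTIDIABETIC_GENERICS = ("metformin", "glipizide", "insulin glargine")
FILLER_GENERICS = ("paracetamol", "ibuprofen")
ANTIHYPERTENSIVE_CLASSES = ("ACEI", "thiazide", "irbesartan")

_DOSE_SUFFIXES = ("", " 10MG", " 25MG TABLET", " 5MG ORAL")
_ROLE_LEVELS = ("suspect", "interacting", "concomitant")
_ROLE_PROBS = (0.6, 0.1, 0.3)

DEFAULT_SEX_DIST = {"male": 0.46, "female": 0.46, "unknown": 0.08}
DEFAULT_AGE_DIST = {
    "<18": 0.01, "18-44": 0.08, "45-64": 0.28, "65-74": 0.20,
    ">75": 0.17, "unknown": 0.26,
}
DEFAULT_COUNTRY_DIST = {
    "US": 0.60, "CA": 0.05, "GB": 0.08, "DE": 0.05, "FR": 0.03, "IT": 0.02,
    "JP": 0.02, "CN": 0.01, "AU": 0.02, "BR": 0.01, "ZA": 0.005, "IN": 0.005,
    "unknown": 0.10,
}
DEFAULT_OUTCOME_PROBS = {
    "hospitalization": 0.25, "disability": 0.03,
    "life-threatening": 0.05, "death": 0.08,
}


@dataclass(frozen=True)
class Confounder:
    """A demographic level that shifts both exposure and event odds,
    e.g. ``Confounder("sex", "female", {"ACEI": 3.0}, 3.0)``."""

    field: str
    level: str
    exposure_or: dict
    event_or: float = 1.0


@dataclass
class SynthConfig:
    """Generative parameters; defaults are the package's reference study
    conditions (see the methods note for rationale).

    ``true_or`` maps drug class to an odds multiplier, either a scalar or a
    per-sex dict (e.g. ``{"female": 1.36, "male": 1.0}``; missing levels
    default to 1.0).  ``baseline_event_odds`` is the target-event odds in
    an unexposed report.  Event and exposure rates are scaled up relative
    to a real spontaneous-report database so that desk-scale collections
    produce informative cell counts.
    """

    n_reports: int = 200_000
    p_exposure: dict = field(
        default_factory=lambda: {
            "ACEI": 0.05, "thiazide": 0.04, "irbesartan": 0.02,
            "statin": 0.08, "ppi": 0.06,
        }
    )
    baseline_event_odds: float = 0.01
    true_or: dict = field(default_factory=lambda: {"ACEI": 1.22})
    sex_dist: dict = field(default_factory=lambda: dict(DEFAULT_SEX_DIST))
    age_dist: dict = field(default_factory=lambda: dict(DEFAULT_AGE_DIST))
    country_dist: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRY_DIST))
    year_range: tuple = (2004, 2019)
    confounders: tuple = ()
    p_diabetes: float = 0.08
    p_hypertension_indication: float = 0.6
    dup_rate: float = 0.0
    missing_rates: dict = field(default_factory=dict)
    decoy_pt_rate: float = 0.3
    excluded_pt_rate: float = 0.03
    outcome_probs: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        for name, dist in [
            ("sex_dist", self.sex_dist), ("age_dist", self.age_dist),
            ("country_dist", self.country_dist),
        ]:
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ConfigError(f"{name} probabilities must be non-negative")
        for cls, p in self.p_exposure.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"p_exposure[{cls!r}] outside [0, 1]")
            if cls not in CLASS_GENERICS:
                raise ConfigError(f"unknown exposure class {cls!r}")
        for cls, v in self.true_or.items():
            if cls not in self.p_exposure:
                raise ConfigError(f"true_or refers to unexposed class {cls!r}")
            if isinstance(v, dict):
                bad = set(v) - set(self.sex_dist)
                if bad:
                    raise ConfigError(
                        f"per-stratum OR for absent sex level(s) {sorted(bad)}"
                    )
        for cf in self.confounders:
            dists = {"sex": self.sex_dist, "age_group": self.age_dist,
                     "country": self.country_dist}
            if cf.field not in dists:
                raise ConfigError(f"confounder field {cf.field!r} unsupported")
            if cf.level not in dists[cf.field]:
                raise ConfigError(
                    f"confounder level {cf.level!r} absent from {cf.field} distribution"
                )
        for rate_name in ("dup_rate", "decoy_pt_rate", "excluded_pt_rate",
                          "p_diabetes", "p_hypertension_indication"):
            r = getattr(self, rate_name)
            if not 0 <= r <= 1:
                raise ConfigError(f"{rate_name} outside [0, 1]")
        if self.baseline_event_odds <= 0:
            raise ConfigError("baseline_event_odds must be positive")


def _choice(rng, dist: dict, n: int) -> np.ndarray:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    return np.array(keys, dtype=object)[idx]


def _log_or(value, sex: np.ndarray) -> np.ndarray:
    """Per-report log odds multiplier for a scalar or per-sex OR."""
    if isinstance(value, dict):
        out = np.zeros(len(sex))
        for lev, orv in value.items():
            out[sex == lev] = math.log(orv)
        return out
    return np.full(len(sex), math.log(value))


def generate(config: SynthConfig) -> tuple[ReportCollection, pd.DataFrame]:
    """Draw a synthetic report collection and its ground-truth table.

    Returns ``(collection, ground_truth)``; ground truth has one row per
    emitted report (duplicates included) with columns ``report_id,
    source_id, is_duplicate, event, diabetes`` and one ``exposed_<class>``
    flag per configured class.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    classes = sorted(config.p_exposure)

    rid = np.char.add("R", np.char.zfill((np.arange(n) + 1).astype("U8"), 8)).astype(object)
    sex = _choice(rng, config.sex_dist, n)
    age = _choice(rng, config.age_dist, n)
    country = _choice(rng, config.country_dist, n)
    y0, y1 = config.year_range
    year = rng.integers(y0, y1 + 1, size=n)
    quarter = rng.integers(1, 5, size=n)

    covariate_values = {"sex": sex, "age_group": age, "country": country}

    # exposures: logistic link with confounder shifts
    exposed = {}
    for cls in classes:
        p = config.p_exposure[cls]
        logit = np.full(n, math.log(p / (1 - p)))
        for cf in config.confounders:
            if cls in cf.exposure_or:
                mask = covariate_values[cf.field] == cf.level
                logit[mask] += math.log(cf.exposure_or[cls])
        prob = 1.0 / (1.0 + np.exp(-logit))
        exposed[cls] = rng.random(n) < prob

    # event: baseline odds times per-class (possibly per-sex) odds ratios
    logit = np.full(n, math.log(config.baseline_event_odds))
    for cls in classes:
        orv = config.true_or.get(cls, 1.0)
        logit += exposed[cls] * _log_or(orv, sex)
    for cf in config.confounders:
        if cf.event_or != 1.0:
            mask = covariate_values[cf.field] == cf.level
            logit[mask] += math.log(cf.event_or)
    event = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    diabetic = rng.random(n) < config.p_diabetes

    # ---- drug table ------------------------------------------------------
    drug_ids, drug_names, drug_roles = [], [], []
    role_pool = np.array(_ROLE_LEVELS, dtype=object)

    def add_mentions(mask: np.ndarray, generics: tuple) -> None:
        k = int(mask.sum())
        if k == 0:
            return
        pool = np.array(
            [g.upper() + suf for g in generics for suf in _DOSE_SUFFIXES],
            dtype=object,
        )
        drug_ids.append(rid[mask])
        drug_names.append(pool[rng.integers(0, len(pool), size=k)])
        drug_roles.append(role_pool[rng.choice(3, size=k, p=_ROLE_PROBS)])

    for cls in classes:
        add_mentions(exposed[cls], CLASS_GENERICS[cls])
    on_antidiabetic = diabetic & (rng.random(n) < 0.7)
    add_mentions(on_antidiabetic, ANTIDIABETIC_GENERICS)
    any_drug = np.zeros(n, dtype=bool)
    for cls in classes:
        any_drug |= exposed[cls]
    any_drug |= on_antidiabetic
    add_mentions(~any_drug, FILLER_GENERICS)  # every report mentions a drug

    drugs = pd.DataFrame(
        {
            "report_id": np.concatenate(drug_ids),
            "verbatim_name": pd.Categorical(np.concatenate(drug_names)),
            "generic_name": np.full(sum(len(x) for x in drug_ids), None, dtype=object),
            "role": pd.Categorical(np.concatenate(drug_roles)),
        }
    )[DRUG_COLUMNS]

    # ---- reaction table --------------------------------------------------
    reac_ids, reac_pts = [], []
    # one primary complaint per report
    reac_ids.append(rid)
    reac_pts.append(
        np.array(DECOY_PTS, dtype=object)[rng.integers(0, len(DECOY_PTS), size=n)]
    )
    # the target event PT (never an excluded one) when the event fired
    k = int(event.sum())
    if k:
        reac_ids.append(rid[event])
        reac_pts.append(
            np.array(TARGET_PTS, dtype=object)[rng.integers(0, len(TARGET_PTS), size=k)]
        )
    # excluded lookalike PTs, independent of exposure
    excl_mask = rng.random(n) < config.excluded_pt_rate
    k = int(excl_mask.sum())
    if k:
        reac_ids.append(rid[excl_mask])
        reac_pts.append(
            np.array(EXCLUDED_PTS, dtype=object)[
                rng.integers(0, len(EXCLUDED_PTS), size=k)
            ]
        )
    # extra decoys
    extra = rng.random(n) < config.decoy_pt_rate
    k = int(extra.sum())
    if k:
        reac_ids.append(rid[extra])
        reac_pts.append(
            np.array(DECOY_PTS, dtype=object)[rng.integers(0, len(DECOY_PTS), size=k)]
        )
    reactions = pd.DataFrame(
        {
            "report_id": np.concatenate(reac_ids),
            "pt_code": pd.Categorical(np.concatenate(reac_pts)),
        }
    )

    # ---- indication table ------------------------------------------------
    indi_ids, indi_pts = [], []
    on_antihypertensive = np.zeros(n, dtype=bool)
    for cls in ANTIHYPERTENSIVE_CLASSES:
        if cls in exposed:
            on_antihypertensive |= exposed[cls]
    hyp = on_antihypertensive & (rng.random(n) < config.p_hypertension_indication)
    if hyp.any():
        indi_ids.append(rid[hyp])
        indi_pts.append(np.full(int(hyp.sum()), "hypertension", dtype=object))
    dia_indic = diabetic & (rng.random(n) < 0.8)
    if dia_indic.any():
        k = int(dia_indic.sum())
        indi_ids.append(rid[dia_indic])
        indi_pts.append(
            np.array(
                ["diabetes_mellitus", "type_2_diabetes_mellitus"], dtype=object
            )[rng.integers(0, 2, size=k)]
        )
    if indi_ids:
        indications = pd.DataFrame(
            {
                "report_id": np.concatenate(indi_ids),
                "pt_code": pd.Categorical(np.concatenate(indi_pts)),
            }
        )
    else:
        indications = pd.DataFrame(columns=PT_COLUMNS)

    # ---- outcomes (2^4 combination strings, drawn as codes) -------------
    outcome_names = sorted(config.outcome_probs)
    probs = np.array([config.outcome_probs[o] for o in outcome_names])
    bits = rng.random((n, len(outcome_names))) < probs
    weights = 1 << np.arange(len(outcome_names) - 1, -1, -1)
    codes = bits @ weights
    combos = np.array(
        [
            ";".join(o for o, b in zip(outcome_names, format(c, f"0{len(outcome_names)}b")) if b == "1")
            for c in range(1 << len(outcome_names))
        ],
        dtype=object,
    )
    outcomes = combos[codes]

    # ---- missingness (before duplication, so copies stay exact) ---------
    for fld, rate in config.missing_rates.items():
        if fld not in covariate_values:
            raise ConfigError(f"missing_rates refers to unknown field {fld!r}")
        mask = rng.random(n) < rate
        covariate_values[fld][mask] = "unknown"

    country_cat = pd.Categorical(country)
    cat_regions = np.array(
        [assign_region(c) for c in country_cat.categories], dtype=object
    )
    region_cat = pd.Categorical(cat_regions[country_cat.codes])
    demo = pd.DataFrame(
        {
            "report_id": rid,
            "version": 1,
            "sex": pd.Categorical(sex),
            "age_group": pd.Categorical(age),
            "country": country_cat,
            "region": region_cat,
            "receipt_year": year,
            "receipt_quarter": quarter,
            "outcomes": pd.Categorical(outcomes),
        }
    )[DEMO_COLUMNS]

    truth = pd.DataFrame(
        {
            "report_id": rid,
            "source_id": rid,
            "is_duplicate": False,
            "event": event,
            "diabetes": diabetic,
            **{f"exposed_{cls}": exposed[cls] for cls in classes},
        }
    )

    # ---- duplicate injection --------------------------------------------
    if config.dup_rate > 0:
        demo, drugs, reactions, indications, truth = _inject_duplicates(
            rng, config, demo, drugs, reactions, indications, truth
        )

    collection = ReportCollection(
        demo, drugs, reactions, indications,
        provenance={"generated": len(demo)},
    )
    return collection, truth


def _fingerprints(demo, drugs, reactions) -> pd.Series:
    """Demographic + drug-set + reaction-set key, identical to the
    cleaner's duplicate rule (generic-level drug sets, so two spellings of
    one generic collide here exactly as they do there)."""
    from .case_definition import default_dictionary

    resolve = default_dictionary().resolve
    verb = drugs["verbatim_name"]
    if isinstance(verb.dtype, pd.CategoricalDtype):
        cats = np.array(
            [(resolve(v) or str(v).upper()) for v in verb.cat.categories],
            dtype=object,
        )
        names = pd.Series(cats[verb.cat.codes], index=verb.index)
    else:
        uniq = {v: (resolve(v) or str(v).upper()) for v in verb.unique()}
        names = verb.map(uniq)
    dset = (
        pd.DataFrame({"report_id": drugs["report_id"], "n": names})
        .groupby("report_id")["n"]
        .apply(lambda s: "|".join(sorted(set(s))))
    )
    rset = reactions.groupby("report_id")["pt_code"].apply(
        lambda s: "|".join(sorted(set(s)))
    )
    return (
        demo["sex"].astype(str)
        + "\x1f" + demo["age_group"].astype(str)
        + "\x1f" + demo["country"].astype(str)
        + "\x1f" + demo["receipt_year"].astype(str)
        + "\x1f" + demo["receipt_quarter"].astype(str)
        + "\x1f" + demo["report_id"].map(dset).fillna("")
        + "\x1f" + demo["report_id"].map(rset).fillna("")
    )


def _inject_duplicates(rng, config, demo, drugs, reactions, indications, truth):
    n = len(demo)
    # make original fingerprints unique so dedup removes exactly the copies
    for _ in range(20):
        fp = _fingerprints(demo, drugs, reactions)
        dup = fp.duplicated(keep="first")
        if not dup.any():
            break
        k = int(dup.sum())
        demo.loc[dup, "receipt_year"] = rng.integers(
            config.year_range[0], config.year_range[1] + 1, size=k
        )
        demo.loc[dup, "receipt_quarter"] = rng.integers(1, 5, size=k)
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not make report fingerprints unique")

    n_dup = int(round(config.dup_rate * n))
    if n_dup == 0:
        return demo, drugs, reactions, indications, truth
    src_idx = rng.choice(n, size=n_dup, replace=False)
    src_ids = demo["report_id"].to_numpy(dtype=object)[src_idx]
    new_ids = np.array([f"D{i:08d}" for i in range(1, n_dup + 1)], dtype=object)
    remap = dict(zip(src_ids, new_ids))

    demo_dup = demo.iloc[src_idx].copy()
    demo_dup["report_id"] = new_ids

    def copy_rows(df):
        sub = df[df["report_id"].isin(remap)].copy()
        sub["report_id"] = sub["report_id"].map(remap)
        return sub

    demo = pd.concat([demo, demo_dup], ignore_index=True)
    drugs = pd.concat([drugs, copy_rows(drugs)], ignore_index=True)
    reactions = pd.concat([reactions, copy_rows(reactions)], ignore_index=True)
    indications = pd.concat([indications, copy_rows(indications)], ignore_index=True)

    truth_dup = truth.iloc[src_idx].copy()
    truth_dup["report_id"] = new_ids
    truth_dup["source_id"] = src_ids
    truth_dup["is_duplicate"] = True
    truth = pd.concat([truth, truth_dup], ignore_index=True)
    return demo, drugs, reactions, indications, truth


def write_tables(collection: ReportCollection, out_dir, sep: str = "\t") -> dict:
    """Serialize to the four-table format read by
    :func:`pvsignal.report_store.read_tables`; the round trip is exact and
    two runs from the same seed produce byte-identical files."""
    if len(collection) == 0:
        raise ValueError("refusing to write an empty collection")
    return collection.to_tables(out_dir, sep=sep)
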