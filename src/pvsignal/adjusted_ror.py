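"""Covariate-adjusted reporting odds ratio via logistic regression.

The crude ROR ignores that sex, age and reporting period shift both drug
use and event reporting.  The adjusted ROR (aROR) regresses case status on
exposure with those covariates, restricted to reports exposed to either
the drug class of interest or a named reference class (reports exposed to
the reference form the baseline); reports exposed to both classes are
excluded by default (configurable to count as exposed).  Reports with
unknown sex or age group are excluded, per the usual complete-case rule
for spontaneous-report covariates.

Fitting is maximum likelihood by iteratively reweighted least squares
(Newton scoring with step halving, so the log-likelihood never decreases),
with Wald intervals ``exp(beta ± z·se)``.  With no covariates the fit
reproduces the crude odds ratio of the collapsed 2×2 exactly — a useful
cross-check against :func:`pvsignal.disproportionality.compute_ror`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ConfigError, ValidationError
from .case_definition import (
    DrugDictionary,
    LabeledCollection,
    default_dictionary,
    exposed_report_ids,
)

logger = logging.getLogger(__name__)

SEX_BASELINE = "male"
AGE_BASELINE = "45-64"
SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class RegressionSpec:
    """What to adjust, and against which reference class.

    ``covariates`` is an ordered subset of {sex, age_group, receipt_year};
    ``year_coding`` chooses dummy-per-year (default) or a linear trend;
    ``both_exposed`` chooses whether reports exposed to both classes are
    dropped (default) or counted as exposed.
    """

    exposure: str = "ACEI"
    reference: str = "thiazide"
    covariates: tuple[str, ...] = ("sex", "age_group", "receipt_year")
    year_coding: str = "categorical"
    both_exposed: str = "exclude"

    def __post_init__(self) -> None:
        if self.exposure == self.reference:
            raise ConfigError("exposure and reference classes must differ")
        bad = set(self.covariates) - {"sex", "age_group", "receipt_year"}
        if bad:
            raise ConfigError(f"unsupported covariates: {sorted(bad)}")
        if self.year_coding not in ("categorical", "linear"):
            raise ConfigError(f"unknown year_coding {self.year_coding!r}")
        if self.both_exposed not in ("exclude", "exposed"):
            raise ConfigError(f"unknown both_exposed rule {self.both_exposed!r}")


@dataclass
class FitResult:
    """Coefficients, Wald intervals and convergence metadata of one fit."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    aror: float
    aror_ci: tuple[float, float]
    n_used: int
    converged: bool
    iterations: int
    loglik: float
    loglik_path: list[float]
    separation_warning: bool = False

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        z = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "OR": np.exp(self.beta),
                "ci_low": np.exp(self.beta - z * self.se),
                "ci_high": np.exp(self.beta + z * self.se),
            }
        )


def build_design(
    labeled: LabeledCollection,
    spec: RegressionSpec,
    dictionary: DrugDictionary | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and outcome vector for the adjusted-ROR fit.

    Rows: reports exposed to the exposure class or the reference class
    (overlap handled per ``spec.both_exposed``), with known sex and age
    group when those covariates are requested.  Dummy coding baselines:
    male sex, age 45–64, earliest observed year.  The returned frame
    includes the intercept column ``const``; the exposure indicator is
    ``exposed``.
    """
    dictionary = dictionary or default_dictionary()
    demo = labeled.collection.demo
    exp_ids = set(labeled.labels.loc[labeled.labels["exposed"], "report_id"])
    ref_ids = exposed_report_ids(labeled.collection, spec.reference, dictionary)

    rid = demo["report_id"]
    in_exp = rid.isin(exp_ids).to_numpy()
    in_ref = rid.isin(ref_ids).to_numpy()
    both = in_exp & in_ref
    if spec.both_exposed == "exclude":
        keep = (in_exp | in_ref) & ~both
    else:
        keep = in_exp | in_ref
    df = demo[keep].copy()
    df["exposed"] = in_exp[keep].astype(int)

    if "sex" in spec.covariates:
        df = df[df["sex"] != "unknown"]
    if "age_group" in spec.covariates:
        df = df[df["age_group"] != "unknown"]
    if df.empty:
        raise ValidationError("no reports left after exposure/covariate exclusions")
    if df["exposed"].nunique() == 1:
        raise ValidationError(
            "exposure column is constant: every retained report is "
            f"{'exposed' if df['exposed'].iloc[0] else 'reference'}-class only"
        )

    case_map = labeled.labels.set_index("report_id")["case"]
    y = case_map.reindex(df["report_id"]).to_numpy(dtype=float)

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["exposed"] = df["exposed"].astype(float)
    for cov in spec.covariates:
        if cov == "sex":
            levels = [l for l in sorted(df["sex"].unique()) if l != SEX_BASELINE]
            for lev in levels:
                X[f"sex[{lev}]"] = (df["sex"] == lev).astype(float)
        elif cov == "age_group":
            levels = [l for l in sorted(df["age_group"].unique()) if l != AGE_BASELINE]
            for lev in levels:
                X[f"age_group[{lev}]"] = (df["age_group"] == lev).astype(float)
        elif cov == "receipt_year":
            years = sorted(df["receipt_year"].unique())
            if spec.year_coding == "linear":
                X["receipt_year"] = (df["receipt_year"] - years[0]).astype(float)
            else:
                for yv in years[1:]:  # earliest year is the baseline
                    X[f"receipt_year[{yv}]"] = (df["receipt_year"] == yv).astype(float)
    # drop dummy columns that are constant in the retained rows
    keep_cols = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    X = X[keep_cols]
    return X.reset_index(drop=True), y


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    exposure_term: str = "exposed",
) -> FitResult:
    """Maximum-likelihood logistic fit by IRLS with step halving.

    Convergence when the largest score component falls below ``tol`` or the
    relative log-likelihood change does.  Step halving guarantees the
    log-likelihood trajectory (``loglik_path``) is non-decreasing.  A
    coefficient beyond ±15 sets ``separation_warning`` (quasi-separation:
    the MLE is drifting to infinity).
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        terms = [f"x{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n != y.shape[0]:
        raise ValidationError("design and outcome lengths differ")

    def loglik(beta: np.ndarray) -> float:
        eta = Xm @ beta
        # log(1+e^eta) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    beta = np.zeros(p)
    ll = loglik(beta)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = Xm.T @ (y - mu)
        info = (Xm * w[:, None]).T @ Xm
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        new_ll = loglik(beta + step)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            halvings += 1
            new_ll = loglik(beta + step)
        beta = beta + step
        path.append(new_ll)
        rel = abs(new_ll - ll) / (abs(ll) + 1.0)
        ll = new_ll
        if np.max(np.abs(score)) < tol or rel < tol:
            converged = True
            break
    if not converged:
        logger.warning("IRLS did not converge in %d iterations", max_iter)

    eta = Xm @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (Xm * w[:, None]).T @ Xm
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.diag(cov))
    sep = bool(np.any(np.abs(beta) > SEPARATION_BETA))
    if sep:
        logger.warning("possible quasi-separation: |beta| exceeds %.0f", SEPARATION_BETA)

    z = stats.norm.ppf(0.975)
    if exposure_term in terms:
        i = terms.index(exposure_term)
        with np.errstate(over="ignore"):
            aror = float(np.exp(beta[i]))
            ci = (float(np.exp(beta[i] - z * se[i])), float(np.exp(beta[i] + z * se[i])))
    else:
        aror, ci = math.nan, (math.nan, math.nan)
    return FitResult(
        terms=terms, beta=beta, se=se, aror=aror, aror_ci=ci,
        n_used=n, converged=converged, iterations=it,
        loglik=ll, loglik_path=path, separation_warning=sep,
    )


def adjusted_ror(
    labeled: LabeledCollection,
    spec: RegressionSpec = RegressionSpec(),
    dictionary: DrugDictionary | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FitResult:
    """Convenience wrapper: build the design and fit in one call."""
    X, y = build_design(labeled, spec, dictionary)
    return fit_logistic(X, y, max_iter=max_iter, tol=tol)
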