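"""Disproportionality statistics on the drug × event 2×2 report table.

For a drug (class) and an event, the cleaned database collapses to

====================  =========  =============
                      event      all other
====================  =========  =============
drug of interest      a          b
all other reports     c          d
====================  =========  =============

*Reporting odds ratio* (ROR): ``(a/b)/(c/d)``, with the Woolf log-scale
95% interval ``exp(ln ROR ± z·sqrt(1/a+1/b+1/c+1/d))``.  Any zero cell
triggers the Haldane–Anscombe correction (+0.5 to every cell), flagged on
the result.

*Information component* (IC): a shrinkage log2 observed-to-expected ratio,
``IC = log2((a + 1/2) / (E + 1/2))`` with ``E = n_drug · n_event / n_total``.
The half-count shrinkage pulls small-count signals toward zero (BCPNN
style).  The default interval is the normal approximation
``IC ± z / (ln 2 · sqrt(a))``; the Norén credibility-interval approximation
is available as ``method="noren"``.

A *signal* fires when either index meets its criterion: ROR lower bound
above 1 with at least 3 exposed cases, or IC lower bound above 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from ._util import ValidationError, round_half_away
from .case_definition import LabeledCollection


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: a = exposed cases, b = exposed non-cases, c = unexposed
    cases, d = unexposed non-cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n_total == 0:
            raise ValidationError("empty database: all four cells are zero")

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = n_drug · n_event / n_total, the count expected under
        independence of drug and event."""
        return self.n_drug * self.n_event / self.n_total

    @classmethod
    def from_margins(cls, a: int, n_drug: int, n_event: int, n_total: int) -> "ContingencyTable":
        """Build from the counts a study typically prints: exposed cases and
        the three marginals."""
        b = n_drug - a
        c = n_event - a
        d = n_total - n_drug - c
        if min(b, c, d) < 0:
            raise ValidationError(
                f"margins imply a negative cell: a={a}, n_drug={n_drug}, "
                f"n_event={n_event}, n_total={n_total}"
            )
        return cls(a, b, c, d)

    @classmethod
    def from_labeled(cls, labeled: LabeledCollection) -> "ContingencyTable":
        return cls(*labeled.counts())


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a two-sided interval; ``defined=False`` marks an
    undefined result (e.g. a zero cell with correction disabled)."""

    value: float
    low: float
    high: float
    corrected: bool = False
    defined: bool = True

    def round(self, ndigits: int = 2) -> tuple[float, float, float]:
        return tuple(round_half_away(v, ndigits) for v in (self.value, self.low, self.high))


UNDEFINED = Estimate(math.nan, math.nan, math.nan, corrected=False, defined=False)


def compute_ror(table: ContingencyTable, alpha: float = 0.05, correction: bool = True) -> Estimate:
    """Crude reporting odds ratio with its Woolf log-scale interval.

    A zero cell yields the Haldane–Anscombe corrected estimate (all cells
    +0.5, ``corrected=True``) or, with ``correction=False``, an undefined
    marker.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if min(a, b, c, d) == 0:
        if not correction:
            return UNDEFINED
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        corrected = True
    z = stats.norm.ppf(1 - alpha / 2)
    ror = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return Estimate(
        ror,
        math.exp(math.log(ror) - z * se),
        math.exp(math.log(ror) + z * se),
        corrected=corrected,
    )


def compute_ic(table: ContingencyTable, alpha: float = 0.05, method: str = "normal") -> Estimate:
    """Information component in bits with a 95% interval.

    ``method="normal"``: symmetric interval ``IC ± z/(ln2·sqrt(a))``
    (undefined for a = 0, where the point estimate is still returned).
    ``method="noren"``: Norén's credibility-interval approximation on the
    shrunk count ``a* = a + 1/2``:
    ``IC025 ≈ IC − 3.3·a*^(−1/2) − 2·a*^(−3/2)``,
    ``IC975 ≈ IC + 2.4·a*^(−1/2) − 0.5·a*^(−3/2)``.
    """
    if table.n_drug == 0 or table.n_event == 0:
        return UNDEFINED
    a = table.a
    e = table.expected
    ic = math.log2((a + 0.5) / (e + 0.5))
    if method == "normal":
        if a == 0:
            return Estimate(ic, math.nan, math.nan, defined=False)
        z = stats.norm.ppf(1 - alpha / 2)
        w = z / (math.log(2) * math.sqrt(a))
        return Estimate(ic, ic - w, ic + w)
    if method == "noren":
        s = a + 0.5
        low = ic - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
        high = ic + 2.4 * s ** -0.5 - 0.5 * s ** -1.5
        return Estimate(ic, low, high)
    raise ValueError(f"unknown IC interval method {method!r}")


@dataclass(frozen=True)
class CriteriaConfig:
    """Dual signal criteria; a drug–event pair signals when either fires."""

    ror_low_gt: float = 1.0
    min_cases: int = 3
    ic_low_gt: float = 0.0


DEFAULT_CRITERIA = CriteriaConfig()


@dataclass(frozen=True)
class SignalResult:
    """ROR, IC, expected count and the dual-criterion signal call for one
    drug/event pair in one stratum."""

    label: str
    table: ContingencyTable
    ror: Estimate
    ic: Estimate
    expected: float
    signal: bool
    criteria_detail: str

    @property
    def a(self) -> int:
        return self.table.a


def detect_signal(
    ror: Estimate,
    ic: Estimate,
    a: int,
    criteria: CriteriaConfig = DEFAULT_CRITERIA,
) -> tuple[bool, str]:
    """Apply the dual criteria; undefined intervals fail their criterion.

    Returns the flag and a detail string naming which criterion fired
    (``"ror"``, ``"ic"``, ``"ror+ic"`` or ``"none"``).
    """
    ror_fires = (
        ror.defined
        and not math.isnan(ror.low)
        and ror.low > criteria.ror_low_gt
        and a >= criteria.min_cases
    )
    ic_fires = ic.defined and not math.isnan(ic.low) and ic.low > criteria.ic_low_gt
    fired = [name for name, f in (("ror", ror_fires), ("ic", ic_fires)) if f]
    return bool(fired), "+".join(fired) if fired else "none"


def compute_signal(
    table: ContingencyTable,
    label: str = "",
    alpha: float = 0.05,
    criteria: CriteriaConfig = DEFAULT_CRITERIA,
    ic_method: str = "normal",
    correction: bool = True,
) -> SignalResult:
    """One-stop computation of ROR, IC and the signal flag for a table."""
    ror = compute_ror(table, alpha=alpha, correction=correction)
    ic = compute_ic(table, alpha=alpha, method=ic_method)
    signal, detail = detect_signal(ror, ic, table.a, criteria)
    return SignalResult(label, table, ror, ic, table.expected, signal, detail)


RESULT_COLUMNS = [
    "label", "stratum", "a", "b", "c", "d", "expected",
    "ROR", "ROR_low", "ROR_high", "IC", "IC_low", "IC_high",
    "signal", "criteria_detail", "corrected",
]


def results_frame(results, stratum: str | None = None, ndigits: int = 2) -> pd.DataFrame:
    """Tabulate :class:`SignalResult` rows for TSV export.

    Statistics are display-rounded (half away from zero) to ``ndigits``;
    counts and the expected count keep full precision (expected at 1 extra
    digit).
    """
    rows = []
    for r in results:
        ror = r.ror.round(ndigits)
        ic = r.ic.round(ndigits)
        rows.append(
            {
                "label": r.label,
                "stratum": stratum if stratum is not None else "",
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "expected": round_half_away(r.expected, ndigits + 1),
                "ROR": ror[0], "ROR_low": ror[1], "ROR_high": ror[2],
                "IC": ic[0], "IC_low": ic[1], "IC_high": ic[2],
                "signal": bool(r.signal),
                "criteria_detail": r.criteria_detail,
                "corrected": bool(r.ror.corrected),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
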