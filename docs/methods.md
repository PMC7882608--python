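# Methods

## The case/non-case design

Spontaneous reporting systems (SRS) such as FAERS collect voluntary
reports of suspected adverse drug events. They have no denominator of
exposed patients, so incidence cannot be estimated; what can be measured
is *disproportionality* — whether a given event is reported more often
with a given drug than with everything else in the same database. Within
the cleaned database, *cases* are reports of the event of interest and
*non-cases* all remaining reports. For a drug (or drug class) the data
collapse to the 2×2 table

|                    | event (case) | all other reports |
|--------------------|:------------:|:-----------------:|
| drug of interest   | a            | b                 |
| all other reports  | c            | d                 |

with marginals n_drug = a+b, n_event = a+c, N = a+b+c+d. A signal of
disproportionate reporting is evidence of an association in reporting,
never of causation.

## Statistics

**Reporting odds ratio.** ROR = (a/b)/(c/d) with the Woolf log-scale
interval exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96 at the 95% level.
Any zero cell triggers the Haldane–Anscombe correction (all cells +0.5);
the result carries a `corrected` flag. With correction disabled a zero
cell yields an explicit undefined marker instead of a number.

**Information component.** IC = log2((a+½)/(E+½)) with E = n_drug·n_event/N.
The half-count shrinkage (BCPNN style) pulls small-count estimates toward
zero; it vanishes identically when a = E. The default interval is the
normal approximation IC ± z/(ln 2·√a), undefined for a = 0. The Norén
credibility-interval approximation (IC025 ≈ IC − 3.3·a*^−½ − 2·a*^−3/2,
IC975 ≈ IC + 2.4·a*^−½ − 0.5·a*^−3/2 on the shrunk count a* = a+½) is
available behind `method="noren"`. The normal approximation is the
default because, applied to the published class-level counts of the
reference analysis (a = 622, n_drug = 197,320, n_event = 20,403,
N = 7,861,515), it reproduces the printed interval exactly at 2 decimals;
the package's acceptance checks pin this.

**Signal criteria.** A drug–event pair signals when *either* criterion
fires: ROR lower 95% bound > 1 with a ≥ 3, or IC lower 95% bound > 0.
Both thresholds are configurable (`CriteriaConfig`). These defaults are
common pharmacovigilance practice and reproduce the qualitative calls of
the reference analysis (class-level and female-stratum signal, no
male-stratum signal).

**Adjusted ROR.** Case status is regressed on exposure with sex, age
group and reporting year as covariates, restricted to reports exposed to
the drug class of interest or to a named reference class (thiazide
diuretics by default), the reference forming the baseline. Reports with
unknown sex or age group are excluded (complete-case rule); reports
exposed to both classes are excluded by default (`both_exposed="exposed"`
counts them as exposed instead — the overlap rule is genuinely open and
therefore a switch). Year is dummy-coded per calendar year by default
(`year_coding="linear"` fits a trend instead). Dummy baselines: male sex,
age 45–64, earliest observed year. Fitting is maximum likelihood by
iteratively reweighted least squares with step halving, so the
log-likelihood trajectory is provably non-decreasing; the fit records the
trajectory, iteration count and convergence flag. Convergence requires
max|score| < 1e-8 or a relative log-likelihood change below the same
tolerance. Intervals are Wald, exp(β ± 1.96·se): standard for adjusted
ROR reporting, cheap and deterministic. |β| > 15 on any term sets a
quasi-separation warning. The IRLS implementation is cross-checked
against statsmodels' `Logit` in the test suite to ≤1e-6 on coefficients
and standard errors; with no covariates it equals the crude 2×2 odds
ratio to at least 6 significant digits.

## Cleaning and deduplication

Reports are removed only when uninterpretable for the design: no drug
mention, no reaction term, or receipt outside the study window
(2004 Q1 – 2020 Q1 by default). Unknown sex, age or country is *kept* and
reported as its own stratum. Deduplication is two-stage: (1) case
versioning — among rows sharing a `report_id`, only the highest version
survives; (2) field matching — reports agreeing exactly on sex, age
group, country, receipt year and quarter, the sorted set of resolved
generic drug names, and the sorted set of reaction PTs are treated as one
case, the first in file order surviving. Field-match deduplication is
deliberately conservative (exact agreement only, no fuzzy matching) and
can be disabled. The provenance log reconciles exactly:
output + Σ removed = input, asserted on every run.

## Event and exposure definitions

Events are defined as one Higher Level Term minus an excluded-PT set, on
a packaged miniature two-level vocabulary (13 PTs under the target HLT
"Lower respiratory tract neoplasms" — including the six benign,
metastatic or infiltrative exclusions — plus decoy HLTs). A report whose
only qualifying PTs are excluded is a non-case. Exposure is report-level:
a report counts once per drug class however many mentions or qualifying
PTs it carries, in any of the three reporting roles (suspect,
interacting, concomitant) unless a role subset is requested. Drug names
are normalized by uppercasing, stripping punctuation and dose/route
tokens, then exact dictionary lookup — deterministic and testable; real
FAERS verbatim fuzziness is out of scope.

Age, when supplied raw, is binned with left-closed edges [18, 45, 65, 75]:
an age exactly on an edge goes to the older group (75 → ">75"). Published
tables in this field rarely state their boundary convention; the edges
are a constructor argument.

## Subset and sensitivity reruns

A stratum is a pure declarative filter (AND of field/op/value clauses)
with optional extra case exclusions. Conventions chosen where the
published description is ambiguous:

* *Region removal* drops only reports positively in the named region;
  unknown-region reports stay, so the comparator is not silently shrunk.
* *Histology exclusion* (e.g. non-small cell carcinoma) by default
  reclassifies carriers as non-cases via the exclusion mechanism;
  `extra_excluded_mode="drop"` removes them from the stratum entirely.
  Both behaviours exist because the source description does not say which
  was used.
* *Diabetic subgroup*: SRS data have no diagnosis table, so the standard
  proxy is used — a diabetes indication PT or an antidiabetic
  co-medication in any role.
* Gender-stratum statistics use gender-restricted comparators (the 2×2 is
  rebuilt inside the stratum).

`run_panel` output row order is deterministic (strata in configured
order; within a stratum the class row first, then drugs alphabetically)
and byte-identical across reruns.

## The synthetic-report generator

The generator emulates the *structure* of an SRS database: categorical
demographics (defaults loosely matching the reference population margins:
46% male / 46% female / 8% unknown; age mode 45–64; ~60% US; years
2004–2019), per-class drug exposure and a target event drawn through
logistic links with configurable odds ratios (scalar or per-sex),
optional confounders that shift both exposure and event odds, reaction
and indication terms from the packaged vocabulary, exact-copy duplicate
records under fresh report ids, and per-field missingness. Every latent
label is returned as ground truth.

Two scale choices matter. First, exposure prevalence (5% for the class of
interest) and baseline event odds (0.01) are roughly 2–4× their values in
the real database, so that collections of 10⁴–10⁵ reports — the sizes the
test suite can afford — yield informative cell counts; the generator
makes no claim to reproduce the reference database's absolute rates.
Second, the generator perturbs receipt dates until all original reports
have unique dedup fingerprints before injecting duplicates, which makes
cleaning ground truth exact: the field-match rule removes precisely the
injected copies.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: reporting-behaviour phenomena (Weber
effect, signal masking by competing drugs, notoriety bias), verbatim
drug-name noise beyond dose/route suffixes, partially duplicated records,
within-report correlation of multiple drugs and events, and secular
trends in reporting volume.

## Problem sizes and numerical choices

The interval-coverage experiment uses 200 replicates of 200,000 reports
per true odds ratio in {0.5, 1, 1.5, 2}, accepting a coverage deviation
of at most 3 Monte-Carlo standard errors from 95%; the confounding
experiment uses one database of 150,000 reports with a 4-fold
exposure/event confounder and a true conditional OR of 1.5. These sizes
give each experiment comfortable power while keeping the full suite
runnable on a laptop. Display rounding is half-away-from-zero at 2
decimals for statistics and 1 decimal for percentages (a truncation
switch exists because published tables are not always consistent);
internal computation is full double precision throughout. Ties in
deduplication are broken by file order; permuting input rows changes no
reported number beyond 1e-10 (asserted).

## Known limitations

* The miniature vocabulary and drug dictionary cover only the drug
  classes and terms the analyses need; they are not a MedDRA or RxNorm
  substitute.
* No Firth correction for separated logistic fits — separation is
  flagged, not repaired.
* Crude and adjusted ROR use different comparators by construction (all
  other reports vs reference-class reports), so their point estimates are
  not directly comparable.
* Per-drug analyses count a report once per generic; a multi-ACEI report
  contributes to each mentioned drug's row and once to the class row.
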