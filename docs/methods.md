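# Methods

This note records the statistical conventions, design choices and known
limitations of `pvsignal`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external runs.

## Data model and cleaning

A FAERS-style dataset is five relational tables keyed by `primaryid` (one
report *version*) with `caseid` grouping versions of the same case. The
reader accepts the modern (2012Q4+) dollar-delimited layout only; rows with
the wrong field count are skipped and counted, and child-table rows whose
`primaryid` is absent from DEMO are excluded as orphans, so that
`rows read = kept + skipped + orphans` per table. The writer strips the
`$` delimiter from field values (the dialect has no quoting); apart from
that, write∘read is the identity, which is property-tested on generated
datasets.

Dates are total-function parsed: 8 digits → day precision, 6 → month,
4 → year, anything else (including calendar-invalid strings such as
`20230230`) → missing with a logged warning. Ages are decoded to years with
the conventional unit factors (DEC×10, MON/12, WK/52.14, DY/365.25,
HR/8766); a present age without a unit code is assumed to be years.

**Deduplication.** Per `caseid`, keep the version with the latest FDA
receipt date; on ties, the numerically higher `primaryid`. A version with a
missing receipt date sorts before any dated version — preferring the more
complete record — and ties among undated versions again go to the higher
`primaryid`. The implementation is a vectorised sort/group-tail; tests
check it against an independent brute-force per-case scan on random
fixtures up to 10⁴ rows, and idempotence.

**Cohort.** Filters apply in a fixed order, each recorded in a flow table:
(1) suspect-role drug rows (primary suspect `PS` by default); (2) exact
drug-name match against a per-drug synonym list (case- and
whitespace-insensitive; substring matching available but off by default,
because verbatim FAERS names are noisy and exact matching is the
reproducible rule); (3) sex (`M` by default; missing sex is excluded);
(4) indication — the indication must be attached to the matched suspect
drug's `drug_seq`, not merely present on the report, with default term list
exactly `{PROSTATE CANCER}` ("product used for unknown indication" and
"malignant neoplasm" are deliberately not accepted, which is
test-asserted); (5) event preferred terms. Deduplication runs before the
filters (the order is configurable in principle but this is the documented
default). A *case* is a distinct `caseid` with ≥ 1 matched event term; a
*report* is one (case, matched PT) pair, so reports ≥ cases always.

The SCARs term set ships as a plain YAML list (Stevens-Johnson syndrome,
toxic epidermal necrolysis, DRESS, AGEP, drug-induced hypersensitivity
syndrome) — it is a configurable stand-in, not a licensed MedDRA SMQ
export, and analyses that need broad-SMQ coverage should supply their own
list.

## Disproportionality statistics

The counting unit of the 2×2 table is the distinct (report, suspect drug,
PT) pair over the deduplicated dataset. The default comparator ("full"
background scope) is every suspect-drug pair in the loaded data; a
"cohort" scope restricted to the filtered cohort's reports is selectable,
since published case series are often ambiguous about which comparator
they used.

With cells a, b, c, d and N = a+b+c+d:

* ROR = ad/(bc); 95% CI = exp(ln ROR ± 1.96·s), s = √(1/a+1/b+1/c+1/d).
* PRR = a(c+d)/(c(a+b)); companion statistic: Pearson χ² without Yates
  correction, N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)). A Yates-corrected variant
  is available. The log-form χ² expression that circulates in the
  signal-detection literature is not internally consistent as printed, so
  the standard Pearson statistic — the only reduction compatible with the
  conventional "χ² ≥ 4" criterion — is the implemented default; it is
  cross-checked against `scipy.stats.chi2_contingency` in tests.
* IC = log₂(aN/((a+b)(a+c))); IC025 = E(IC) − 2√V(IC). The default V(IC)
  is the delta-method variance on the log₂ scale,
  (1/a+1/b+1/c+1/d)/ln(2)², mirroring the Wald structure used for the
  other intervals; it is explicit and reproducible. The closed-form
  posterior moments of the BCPNN (Bate et al. 1998, standard priors
  α₁=β₁=γ₁₁=1, α=β=2, γ chosen so the prior IC expectation is zero) are
  available via `ic_variance="bate"`; published IC025 values computed with
  unstated variance estimators generally cannot be reproduced exactly, so
  the choice is a documented configuration, not an inference.
* EBGM here denotes the *unshrunk* observed/expected relative reporting
  ratio aN/((a+b)(a+c)) with lower bound exp(ln EBGM − 1.96·s). No
  gamma-Poisson mixture is fitted: full MGPS shrinkage across all
  drug–event pairs is out of scope, and the naming follows the common
  case-series usage of "EBGM" for this ratio. Consequently
  IC = log₂(EBGM) holds as an exact identity, which tests assert to
  machine precision.

Signal criteria: ROR positive iff a ≥ 3 and CI lower limit > 1; PRR
positive iff a ≥ 3, PRR ≥ 2 and χ² ≥ 4; BCPNN positive iff IC025 > 0; MGPS
positive iff EBGM05 > 2.

**Zero cells.** No continuity correction by default. Ratios with zero
denominators are *undefined-marked* (NaN): they propagate to report output
as empty cells, never as sentinel numbers, and an undefined quantity never
raises a positive flag. (a = 0 with b, c > 0 yields a defined point ROR of
0 with an undefined CI.) Haldane's +0.5 on all cells is available via
`continuity="haldane"`; the a ≥ 3 gate always uses the uncorrected count.

All four estimators are verified against an independent arbitrary-precision
(sympy, 25+ significant digits) evaluation of the defining formulas on
1,000 random tables at relative error < 10⁻¹².

**Cell reconstruction diagnostic.** `reconstruct_cells` solves the ROR/PRR/
EBGM ratio equations continuously for (b, c, d) given a, then scans the
integer neighbourhood for combinations reproducing every printed value
under 2-decimal rounding. It demonstrates joint consistency of a published
signal row; solutions are not unique and it is not an inversion.

## Descriptives

One row per (case, drug). Age bands `<18`, `18–64`, `65–85`, `>85`,
`Missing` in completed years, with 85 assigned to the closed `65–85` band
so the bands partition. Reporter classes: MD/PH/RN/HP → health
professionals, CN/LW → non-health professionals, empty → missing. Countries
render as the two-letter code when it appears in the bundled code table,
otherwise "COUNTRY NOT SPECIFIED". Percentages are half-up rounded to one
decimal (matching how printed tables round .05 up); each block's counts sum
to the case total and its percents to 100 ± 0.3.

## Time to onset

Onset = event date − earliest *full-precision* therapy start date of the
matched suspect drug, in days; same-day start and event counts as 0 and is
included. Reports with a missing or partial date on either side, or a
negative difference, are excluded and tallied by reason. Median and
quartiles default to Tukey hinges (even-n median = midpoint of the central
order statistics; each half includes the middle value when n is odd);
linear interpolation is a switch. The binned distribution uses [0, 37],
[38, 74], … — a first bin of about five weeks is the conventional early
window in onset analyses — with configurable width.

## Synthetic data generator

The generator emulates, at desk scale, the reporting landscape the pipeline
targets: a drug catalogue mixing three AR antagonists with common
background drugs, elderly-male-heavy demographics, Japan/US-heavy reporter
countries, prostate-cancer indications for the target drugs, log-normal
onset latencies, partial/missing dates, and case duplication.

The drug–event mechanism is deliberately simple so estimands are exact:
each report carries one suspect drug (categorical by prescribing weight)
and a SCAR indicator drawn from a Bernoulli whose odds are
`baseline_odds × OR(drug)`. Because all non-SCAR reports carry exactly one
background PT and SCAR reports carry one SCAR PT (two distinct ones with
probability 0.05, uniformly across drugs, so that cases < reports), the
population (report, PT)-pair reporting odds ratio for each injected pair
equals the configured OR exactly. Infeasible configurations (non-positive
odds, probabilities outside [0, 1]) are rejected before sampling. Duplicate
cases are true versions — identical content, higher `primaryid`,
later-or-equal receipt date (equal with probability 0.3, exercising the
tie-break) — so the deduplicated dataset is exactly the case population and
the expected removed count is `round(duplicate_rate × n)`.

Default conditions: 20,000 cases, background SCAR probability 0.003,
injected odds ratios 33 (apalutamide), 0.36 (enzalutamide) and 0.43
(darolutamide) — the strong-positive / null-negative pattern the analysis
is designed to resolve — onset medians 28.5 and 30 days with log-scale
sigmas 1.1 and 0.7 (chosen so the log-normal quartiles fall near 11–60 and
22–48 days), 10% duplicated cases, 12–15% missing and ~8% partial dates.
At this scale the enzalutamide/darolutamide expected SCAR counts are of
order one, as in the real sparse-count setting.

The recovery experiment (`recovery_config`) uses one exposed drug carrying
2% of a 20,000-report database with background SCAR probability 0.0072, so
the expected exposed SCAR count is ≈ 75 at the default injected OR of 30
while the comparator cells stay well populated, as they are in a real
spontaneous-reporting system. Over 200 seeded replicates the mean estimated
ROR recovers the injected value to within a few percent (the Wald CI
covers at close to the nominal 95%), and under the matching null
configuration the BCPNN flag rate does not exceed the ROR flag rate — the
Bayesian bound is the more conservative of the two at small counts, which
is the classical motivation for combining frequentist and Bayesian
criteria.

What the generator does **not** emulate: correlated drug co-reporting and
polypharmacy structure, masking/competition bias, secular reporting trends,
duplicated cases with *different* caseids, free-text drug-name noise beyond
case/synonym variation, and real MedDRA coding practice. Passing recovery
tests therefore validate the pipeline's arithmetic and its behaviour under
the stated sampling model — not robustness to those real-data pathologies.

## Problem sizes and runtime

Defaults are sized for a laptop-class single CPU: 20,000-case datasets,
200-replicate recovery experiments, 1,000-table oracle comparisons and
10⁴-row deduplication fixtures. These are the package's chosen study
conditions; all scale linearly via their configuration fields.

## Known limitations

* Only the `primaryid`-era FAERS ASCII layout is supported (no legacy ISR
  files, no XML/E2B, no OUTC/RPSR tables).
* No probabilistic duplicate detection across different caseids.
* No MedDRA hierarchy traversal; event sets are flat PT lists.
* No multiple-testing control across drug–event pairs.
* The "EBGM" is the unshrunk relative reporting ratio (see above); sparse
  cells are handled by undefined-marks and the a ≥ 3 gates rather than by
  empirical-Bayes shrinkage.
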