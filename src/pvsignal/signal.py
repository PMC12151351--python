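"""Disproportionality statistics on the 2x2 spontaneous-reporting table.

For one drug and one adverse-event term set, reports (counted as
(report, preferred-term) pairs among suspect drugs) are cross-classified as

=============  ==============  ===============
               target events   other events
=============  ==============  ===============
target drug    a               b
other drugs    c               d
=============  ==============  ===============

with N = a+b+c+d.  Four estimators are computed, each with the conventional
signal criterion of the pharmacovigilance literature:

* **ROR** (reporting odds ratio) ``ad/(bc)`` with the Wald 95% CI
  ``exp(ln ROR +- 1.96*sqrt(1/a+1/b+1/c+1/d))``; signal when the lower limit
  exceeds 1 and a >= 3.
* **PRR** (proportional reporting ratio) ``a(c+d)/(c(a+b))`` with a Pearson
  chi-squared companion; signal when PRR >= 2, chi2 >= 4 and a >= 3.
* **BCPNN information component** ``IC = log2(aN/((a+b)(a+c)))`` with
  credibility bound ``IC025 = E(IC) - 2*sqrt(V(IC))``; signal when IC025 > 0.
  The default V(IC) is the delta-method variance on the log2 scale,
  ``(1/a+1/b+1/c+1/d)/ln(2)^2``; the Bayesian closed-form moments of the
  BCPNN posterior (Bate et al. 1998 priors) are available via
  ``ic_variance="bate"``.
* **EBGM** here denotes the observed/expected relative reporting ratio
  ``aN/((a+b)(a+c))`` with lower bound
  ``exp(ln EBGM - 1.96*sqrt(1/a+1/b+1/c+1/d))``; signal when EBGM05 > 2.
  (No gamma-Poisson shrinkage is applied: this is the unshrunk ratio, and
  ``IC = log2(EBGM)`` holds as an exact identity.)

Quantities whose defining ratio has a zero denominator are *undefined-marked*
as NaN and can never raise a positive flag.  No continuity correction is
applied by default; Haldane's +0.5 can be requested.

The module-level functions operate on a single :class:`ContingencyTable`;
:class:`DisproportionalityModel` wraps a family of tables (one per drug
against a common comparator) and ``fit()`` returns a
:class:`DisproportionalityResults` with the estimate table and a
``summary()`` rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

NAN = float("nan")
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d counts of one drug-event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty contingency table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def haldane(self) -> "ContingencyTableF":
        return ContingencyTableF(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class ContingencyTableF:
    """Continuity-corrected (non-integer) cells; same interface as above."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


class RorResult(NamedTuple):
    ror: float
    lo95: float
    hi95: float


class PrrResult(NamedTuple):
    prr: float
    chi2: float


class IcResult(NamedTuple):
    ic: float
    ic025: float
    e_ic: float
    v_ic: float


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float


def _wald_halfwidth(t) -> float:
    """1.96 * sqrt(1/a + 1/b + 1/c + 1/d); NaN when any cell is zero."""
    if min(t.a, t.b, t.c, t.d) <= 0:
        return NAN
    return 1.96 * math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def ror(t: ContingencyTable | ContingencyTableF) -> RorResult:
    """Reporting odds ratio with Wald 95% CI.

    a=0 or d=0 give a point estimate of 0; b=0 or c=0 leave it undefined; any
    zero cell leaves the CI undefined.
    """
    if t.b <= 0 or t.c <= 0:
        return RorResult(NAN, NAN, NAN)
    point = (t.a * t.d) / (t.b * t.c)
    half = _wald_halfwidth(t)
    if math.isnan(half) or point <= 0:
        return RorResult(point, NAN, NAN)
    log_point = math.log(point)
    return RorResult(point, math.exp(log_point - half), math.exp(log_point + half))


def pearson_chi2(t: ContingencyTable | ContingencyTableF, yates: bool = False) -> float:
    """Pearson chi-squared for the 2x2 table (optionally Yates-corrected)."""
    n = t.n
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    if min(r1, r2, c1, c2) <= 0:
        return NAN
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / (r1 * r2 * c1 * c2)


def prr(t: ContingencyTable | ContingencyTableF, yates: bool = False) -> PrrResult:
    """Proportional reporting ratio and its chi-squared companion."""
    if t.c <= 0 or (t.a + t.b) <= 0:
        return PrrResult(NAN, pearson_chi2(t, yates=yates))
    point = (t.a * (t.c + t.d)) / (t.c * (t.a + t.b))
    return PrrResult(point, pearson_chi2(t, yates=yates))


def _relative_reporting_ratio(t) -> float:
    if t.a <= 0 or (t.a + t.b) <= 0 or (t.a + t.c) <= 0:
        return NAN
    return (t.a * t.n) / ((t.a + t.c) * (t.a + t.b))


def bcpnn_ic(t: ContingencyTable | ContingencyTableF, variance: str = "delta") -> IcResult:
    """Information component and its lower credibility bound E(IC) - 2*sqrt(V(IC)).

    ``variance="delta"`` (default): E(IC) is the observed IC and V(IC) the
    delta-method variance (1/a+1/b+1/c+1/d)/ln(2)^2 — undefined if any cell
    is zero.  ``variance="bate"``: closed-form posterior moments of the BCPNN
    with the standard Bate-1998 priors, defined for any table with a >= 0.
    """
    rrr = _relative_reporting_ratio(t)
    if math.isnan(rrr):
        return IcResult(NAN, NAN, NAN, NAN)
    ic = math.log2(rrr)
    if variance == "delta":
        if min(t.a, t.b, t.c, t.d) <= 0:
            return IcResult(ic, NAN, ic, NAN)
        v = (1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d) / (_LN2 * _LN2)
        return IcResult(ic, ic - 2.0 * math.sqrt(v), ic, v)
    if variance == "bate":
        e, v = _bate_moments(t)
        return IcResult(ic, e - 2.0 * math.sqrt(v), e, v)
    raise ValueError(f"unknown IC variance estimator {variance!r}")


def _bate_moments(t) -> tuple[float, float]:
    """Posterior mean and variance of the IC (Bate et al. 1998 closed forms).

    Priors: alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1 and gamma tuned
    so the prior IC expectation is 0.
    """
    a, n = t.a, t.n
    r1 = t.a + t.b  # drug margin
    c1 = t.a + t.c  # event margin
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((r1 + alpha1) * (c1 + beta1))
    e = math.log2(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (r1 + alpha1) * (c1 + beta1))
    )
    v = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - r1 + alpha - alpha1) / ((r1 + alpha1) * (1 + n + alpha))
        + (n - c1 + beta - beta1) / ((c1 + beta1) * (1 + n + beta))
    ) / (_LN2 * _LN2)
    return e, v


def ebgm(t: ContingencyTable | ContingencyTableF) -> EbgmResult:
    """Relative reporting ratio ('EBGM') and its lower 95% bound."""
    point = _relative_reporting_ratio(t)
    if math.isnan(point):
        return EbgmResult(NAN, NAN)
    half = _wald_halfwidth(t)
    if math.isnan(half):
        return EbgmResult(point, NAN)
    return EbgmResult(point, math.exp(math.log(point) - half))


@dataclass(frozen=True)
class SignalResult:
    """All four estimators, intervals and positivity flags for one table."""

    table: ContingencyTable
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ic_expectation: float
    ic_variance: float
    ebgm: float
    ebgm05: float
    ror_positive: bool
    prr_positive: bool
    bcpnn_positive: bool
    mgps_positive: bool

    @property
    def flags(self) -> dict[str, bool]:
        return {
            "ror_positive": self.ror_positive,
            "prr_positive": self.prr_positive,
            "bcpnn_positive": self.bcpnn_positive,
            "mgps_positive": self.mgps_positive,
        }

    @property
    def n_positive(self) -> int:
        return sum(self.flags.values())


def evaluate_signal(
    t: ContingencyTable,
    ic_variance: str = "delta",
    yates: bool = False,
    continuity: str | None = None,
) -> SignalResult:
    """Compute all four estimators and apply the signal criteria.

    Undefined-marked quantities (NaN) never satisfy a criterion.  The a >= 3
    gate uses the *uncorrected* count even when ``continuity="haldane"``.
    """
    if continuity not in (None, "haldane"):
        raise ValueError(f"unknown continuity correction {continuity!r}")
    work = t.haldane() if continuity == "haldane" else t
    r = ror(work)
    p = prr(work, yates=yates)
    i = bcpnn_ic(work, variance=ic_variance)
    e = ebgm(work)
    a_gate = t.a >= 3
    return SignalResult(
        table=t,
        ror=r.ror, ror_lo95=r.lo95, ror_hi95=r.hi95,
        prr=p.prr, chi2=p.chi2,
        ic=i.ic, ic025=i.ic025, ic_expectation=i.e_ic, ic_variance=i.v_ic,
        ebgm=e.ebgm, ebgm05=e.ebgm05,
        ror_positive=bool(a_gate and r.lo95 > 1.0),
        prr_positive=bool(a_gate and p.prr >= 2.0 and p.chi2 >= 4.0),
        bcpnn_positive=bool(i.ic025 > 0.0),
        mgps_positive=bool(e.ebgm05 > 2.0),
    )


# ---------------------------------------------------------------------------
# pair counting


def suspect_pairs(
    dataset,
    kept_primaryids: Iterable[str] | None = None,
    role_codes: Iterable[str] = ("PS",),
) -> pd.DataFrame:
    """Distinct (report, drug name, preferred term) pairs among suspect drugs.

    This is the counting universe of the 2x2 table: every suspect-role drug
    of every (deduplicated) report, crossed with every reaction term on that
    report.  Drug names and terms are whitespace/case-normalised.
    """
    from .curation import normalize_term  # local import to avoid cycle

    drug = dataset.drug
    reac = dataset.reac
    if kept_primaryids is not None:
        kept = set(kept_primaryids)
        drug = drug[drug["primaryid"].isin(kept)]
        reac = reac[reac["primaryid"].isin(kept)]
    roles = {str(r).strip().upper() for r in role_codes}
    drug = drug[drug["role_cod"].map(lambda s: str(s).strip().upper()).isin(roles)]
    left = drug[["primaryid", "drugname"]].copy()
    left["drugname"] = left["drugname"].map(normalize_term)
    left = left.drop_duplicates()
    right = reac[["primaryid", "pt"]].copy()
    right["pt"] = right["pt"].map(normalize_term)
    right = right.drop_duplicates()
    pairs = left.merge(right, on="primaryid", how="inner")
    return pairs.reset_index(drop=True)


def contingency(
    pairs: pd.DataFrame,
    target_drug_names: Iterable[str],
    event_terms: Iterable[str],
) -> ContingencyTable:
    """Cross-classify (report, drug, PT) pairs for one target drug and event set."""
    from .curation import normalize_term

    if pairs.empty:
        raise ValueError("no (report, drug, PT) pairs in scope (N = 0)")
    targets = {normalize_term(t) for t in target_drug_names}
    events = {normalize_term(t) for t in event_terms}
    is_target = pairs["drugname"].isin(targets).to_numpy()
    is_event = pairs["pt"].isin(events).to_numpy()
    a = int(np.sum(is_target & is_event))
    b = int(np.sum(is_target & ~is_event))
    c = int(np.sum(~is_target & is_event))
    d = int(np.sum(~is_target & ~is_event))
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# model / results


class DisproportionalityModel:
    """A family of drug-event 2x2 tables sharing one comparator universe.

    Construct from explicit tables, from raw counts, or from a (report,
    drug, PT) pair frame via :meth:`from_pairs`; ``fit()`` evaluates all four
    estimators per drug.
    """

    def __init__(self, tables: Mapping[str, ContingencyTable]):
        if not tables:
            raise ValueError("no contingency tables supplied")
        self.tables = dict(tables)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "DisproportionalityModel":
        """Build from a DataFrame with columns a, b, c, d indexed by drug."""
        tables = {
            str(idx): ContingencyTable(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))
            for idx, row in counts.iterrows()
        }
        return cls(tables)

    @classmethod
    def from_pairs(
        cls,
        pairs: pd.DataFrame,
        drug_synonyms: Mapping[str, Iterable[str]],
        event_terms: Iterable[str],
    ) -> "DisproportionalityModel":
        """One table per configured drug against the full pair universe."""
        event_terms = list(event_terms)
        tables = {}
        for canonical, names in drug_synonyms.items():
            tables[canonical] = contingency(pairs, list(names) + [canonical], event_terms)
        return cls(tables)

    def fit(
        self,
        ic_variance: str = "delta",
        yates: bool = False,
        continuity: str | None = None,
    ) -> "DisproportionalityResults":
        results = {
            drug: evaluate_signal(t, ic_variance=ic_variance, yates=yates, continuity=continuity)
            for drug, t in self.tables.items()
        }
        return DisproportionalityResults(self, results, ic_variance=ic_variance, yates=yates, continuity=continuity)


_NUMERIC_COLUMNS = [
    "a", "b", "c", "d", "ror", "ror_lo95", "ror_hi95", "prr", "chi2",
    "ic", "ic025", "ebgm", "ebgm05",
]


class DisproportionalityResults:
    """Fitted estimates, intervals and flags; one row per drug."""

    def __init__(self, model, results: Mapping[str, SignalResult], **options):
        self.model = model
        self.results = dict(results)
        self.options = options

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for drug, r in self.results.items():
            t = r.table
            rows.append({
                "drug": drug, "reports": t.a,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "ror": r.ror, "ror_lo95": r.ror_lo95, "ror_hi95": r.ror_hi95,
                "prr": r.prr, "chi2": r.chi2,
                "ic": r.ic, "ic025": r.ic025,
                "ebgm": r.ebgm, "ebgm05": r.ebgm05,
                "ror_positive": r.ror_positive, "prr_positive": r.prr_positive,
                "bcpnn_positive": r.bcpnn_positive, "mgps_positive": r.mgps_positive,
            })
        return pd.DataFrame(rows).set_index("drug")

    def rounded_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Report rendering: values at ``decimals`` places, plus a companion
        1-decimal column for statistics whose magnitude is below 10 (report
        tables conventionally mix the two renderings for small values)."""
        frame = self.frame.copy()
        out = frame.copy()
        for col in _NUMERIC_COLUMNS:
            if col in ("a", "b", "c", "d"):
                continue
            out[col] = frame[col].round(decimals)
            small = frame[col].abs() < 10
            out[col + "_1dp"] = frame[col].where(small).round(1)
        return out

    def summary(self) -> str:
        """Signal-strength table, one line per drug."""
        def fmt(v: float, nd: int = 2) -> str:
            return "NA" if v != v else f"{v:.{nd}f}"

        lines = [
            "Disproportionality analysis (suspect-drug (report, PT) pairs)",
            f"IC variance: {self.options.get('ic_variance', 'delta')}; "
            f"continuity: {self.options.get('continuity') or 'none'}; "
            f"Yates: {self.options.get('yates', False)}",
            "",
            f"{'drug':<16}{'reports':>8}  {'ROR (95% CI)':<24}{'PRR (chi2)':<20}"
            f"{'IC (IC025)':<18}{'EBGM (EBGM05)':<18}{'signals':<8}",
        ]
        for drug, r in self.results.items():
            ror_cell = f"{fmt(r.ror)} ({fmt(r.ror_lo95)}-{fmt(r.ror_hi95)})"
            lines.append(
                f"{drug:<16}{r.table.a:>8}  "
                + ror_cell.ljust(24)
                + f"{fmt(r.prr)} ({fmt(r.chi2)})".ljust(20)
                + f"{fmt(r.ic)} ({fmt(r.ic025)})".ljust(18)
                + f"{fmt(r.ebgm)} ({fmt(r.ebgm05)})".ljust(18)
                + f"{r.n_positive}/4"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """Full-precision CSV; undefined-marked cells are written empty."""
        self.frame.to_csv(path)


# ---------------------------------------------------------------------------
# diagnostics


def reconstruct_cells(
    a: int,
    ror_printed: float,
    prr_printed: float,
    ebgm_printed: float,
    chi2_printed: float | None = None,
    search_radius: int = 25,
) -> list[ContingencyTable]:
    """Search integer (b, c, d) jointly consistent with printed statistics.

    Published signal tables print a and rounded ROR/PRR/EBGM (and chi2) but
    not the underlying b, c, d.  This solves the three ratio equations
    continuously, then scans the integer neighbourhood for cell combinations
    that reproduce every printed value under 2-decimal rounding — a
    consistency diagnostic, not an inversion (solutions are not unique).
    """
    from scipy.optimize import fsolve

    def equations(x):
        b, c, d = np.exp(x)
        n = a + b + c + d
        return [
            a * d / (b * c) - ror_printed,
            a * (c + d) / (c * (a + b)) - prr_printed,
            a * n / ((a + c) * (a + b)) - ebgm_printed,
        ]

    x0 = np.log([max(a * 10.0, 100.0), max(a * 2.0, 50.0), max(a * 1000.0, 1e5)])
    sol = fsolve(equations, x0, full_output=False)
    b0, c0, d0 = (int(round(v)) for v in np.exp(sol))

    def consistent(t: ContingencyTable) -> bool:
        r = ror(t)
        p = prr(t)
        e = ebgm(t)
        checks = [
            round(r.ror, 2) == round(ror_printed, 2),
            round(p.prr, 2) == round(prr_printed, 2),
            round(e.ebgm, 2) == round(ebgm_printed, 2),
        ]
        if chi2_printed is not None:
            checks.append(round(p.chi2, 2) == round(chi2_printed, 2))
        return all(checks)

    found = []
    for b in range(max(1, b0 - search_radius), b0 + search_radius + 1):
        for c in range(max(1, c0 - search_radius), c0 + search_radius + 1):
            d_star = ror_printed * b * c / a
            # d values whose ROR still rounds to the printed one
            span = max(1, int(math.ceil(0.005 * b * c / a)))
            for dd in range(max(1, int(d_star) - span), int(d_star) + span + 1):
                t = ContingencyTable(a, b, c, dd)
                if consistent(t):
                    found.append(t)
    return found
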