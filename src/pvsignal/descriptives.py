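"""Per-drug descriptive summary of cohort cases (age bands, reporter, country).

Cases (distinct patients) are tabulated into the conventional demographic
blocks of pharmacovigilance case series:

* age bands ``<18``, ``18-64``, ``65-85``, ``>85``, ``Missing`` — completed
  years; 85 falls in the closed ``65-85`` band so the bands partition;
* reporter class: MD/PH/RN/HP occupation codes are Health Professionals,
  CN/LW Non-Health Professionals, empty Missing;
* reporter country, rendered as the two-letter code; codes missing from the
  bundled code table (or empty) render as ``COUNTRY NOT SPECIFIED``.

Percentages use half-up rounding to one decimal, matching how such tables
are conventionally printed.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

AGE_BANDS = ("<18", "18-64", "65-85", ">85", "Missing")
REPORTER_CLASSES = ("Health Professionals", "Non-Health Professionals", "Missing")

HEALTH_PROFESSIONAL_CODES = {"MD", "PH", "RN", "HP"}
NON_HEALTH_PROFESSIONAL_CODES = {"CN", "LW"}

UNSPECIFIED_COUNTRY = "COUNTRY NOT SPECIFIED"


def percent(count: int, total: int) -> float:
    """100*count/total, half-up rounded to 1 decimal (0.0 for empty blocks)."""
    if total <= 0:
        return 0.0
    return math.floor(1000.0 * count / total + 0.5) / 10.0


def assign_age_band(age_years: float) -> str:
    """Partition assignment of an age in completed years."""
    if age_years is None or age_years != age_years:
        return "Missing"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64"
    if age_years <= 85:
        return "65-85"
    return ">85"


def assign_reporter_class(occp_cod: object) -> str:
    code = str(occp_cod).strip().upper()
    if code in HEALTH_PROFESSIONAL_CODES:
        return "Health Professionals"
    if code in NON_HEALTH_PROFESSIONAL_CODES:
        return "Non-Health Professionals"
    return "Missing"


def country_table() -> dict[str, str]:
    ref = importlib.resources.files("pvsignal.data") / "country_codes.yaml"
    payload = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return dict(payload["country_codes"])


def render_country(code: object, known: dict[str, str] | None = None) -> str:
    known = country_table() if known is None else known
    c = str(code).strip().upper()
    if c in known:
        return c
    return UNSPECIFIED_COUNTRY


@dataclass
class DescriptiveSummary:
    """Counts and percents per block for one drug's cases."""

    drug: str
    total_cases: int
    age: dict[str, tuple[int, float]] = field(default_factory=dict)
    reporter: dict[str, tuple[int, float]] = field(default_factory=dict)
    country: dict[str, tuple[int, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block, mapping in (("age", self.age), ("reporter", self.reporter), ("country", self.country)):
            for level, (count, pct) in mapping.items():
                rows.append({
                    "drug": self.drug, "block": block, "level": level,
                    "count": count, "percent": pct,
                })
        return pd.DataFrame(rows, columns=["drug", "block", "level", "count", "percent"])


def summarize(cases: pd.DataFrame, drugs: list[str] | None = None) -> list[DescriptiveSummary]:
    """Summarise a one-row-per-(case, drug) frame with ``age_years``,
    ``occp_cod`` and ``country`` columns into per-drug blocks."""
    known = country_table()
    if drugs is None:
        drugs = sorted(cases["drug"].unique()) if len(cases) else []
    summaries = []
    for drug in drugs:
        sub = cases[cases["drug"] == drug] if len(cases) else cases
        total = len(sub)
        summary = DescriptiveSummary(drug=drug, total_cases=total)
        bands = sub["age_years"].map(assign_age_band) if total else pd.Series(dtype=str)
        for band in AGE_BANDS:
            count = int((bands == band).sum()) if total else 0
            summary.age[band] = (count, percent(count, total))
        classes = sub["occp_cod"].map(assign_reporter_class) if total else pd.Series(dtype=str)
        for cls in REPORTER_CLASSES:
            count = int((classes == cls).sum()) if total else 0
            summary.reporter[cls] = (count, percent(count, total))
        rendered = sub["country"].map(lambda c: render_country(c, known)) if total else pd.Series(dtype=str)
        if total:
            counts = rendered.value_counts()
            # highest first, unspecified last
            levels = sorted(
                counts.index,
                key=lambda lv: (lv == UNSPECIFIED_COUNTRY, -counts[lv], lv),
            )
            for level in levels:
                summary.country[level] = (int(counts[level]), percent(int(counts[level]), total))
        summaries.append(summary)
    return summaries


def summaries_frame(summaries: list[DescriptiveSummary]) -> pd.DataFrame:
    if not summaries:
        return pd.DataFrame(columns=["drug", "block", "level", "count", "percent"])
    return pd.concat([s.to_frame() for s in summaries], ignore_index=True)
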