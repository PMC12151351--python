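"""Report-version deduplication and analysis-cohort construction.

FAERS cases are submitted repeatedly: each revision of a case (shared
``caseid``) arrives as a new report version (new ``primaryid``).  The cleaning
rule keeps, per case, the version with the latest FDA receipt date, breaking
ties by the numerically higher ``primaryid``.  A version with no receipt date
never beats a dated one.

Cohort construction then applies, in order: suspect-role filter (primary
suspect by default), drug-name matching against a synonym list, sex filter,
drug-linked indication filter, and finally the adverse-event preferred-term
filter.  The surviving counts at each stage form the selection flow table.
Counting vocabulary: a *case* is a distinct ``caseid`` with at least one
matched event term; a *report* is one (case, matched preferred term) pair, so
reports >= cases.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

from .faers import QuarterDataset, age_to_years, date_sort_key

FLOW_STAGES = ("input", "suspect_drug", "sex", "indication", "event")

#: generic + brand names for the three second-generation AR antagonists.
SGARA_SYNONYMS: dict[str, list[str]] = {
    "enzalutamide": ["ENZALUTAMIDE", "XTANDI"],
    "apalutamide": ["APALUTAMIDE", "ERLEADA"],
    "darolutamide": ["DAROLUTAMIDE", "NUBEQA"],
}


def normalize_term(value: object) -> str:
    """Trim, collapse internal whitespace and upper-case a name or term."""
    return " ".join(str(value).split()).upper()


def default_event_terms() -> list[str]:
    """The packaged SCARs preferred-term list."""
    ref = importlib.resources.files("pvsignal.data") / "scars_terms.yaml"
    payload = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return list(payload["scars_terms"])


@dataclass
class CohortConfig:
    """Everything that defines cohort membership.

    Matching of drug names, indication terms and event terms is
    case-insensitive after whitespace normalisation.  ``substring_match``
    additionally accepts drug names that merely contain a synonym (off by
    default: verbatim FAERS drug names are noisy, and exact matching is the
    reproducible rule).
    """

    drug_synonyms: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in SGARA_SYNONYMS.items()})
    role_codes: tuple[str, ...] = ("PS",)
    sex_filter: str | None = "M"
    indication_terms: tuple[str, ...] = ("PROSTATE CANCER",)
    event_terms: list[str] = field(default_factory=default_event_terms)
    substring_match: bool = False
    indication_drug_linked: bool = True

    def __post_init__(self) -> None:
        if not self.drug_synonyms or any(not v for v in self.drug_synonyms.values()):
            raise ValueError("drug_synonyms must map each drug to a non-empty name list")
        if not self.role_codes:
            raise ValueError("role_codes must be non-empty")
        if not self.indication_terms:
            raise ValueError("indication_terms must be non-empty")
        if not self.event_terms:
            raise ValueError("event_terms must be non-empty")

    def synonym_lookup(self) -> dict[str, str]:
        """Normalised synonym -> canonical drug name."""
        lookup: dict[str, str] = {}
        for canonical, names in self.drug_synonyms.items():
            for name in list(names) + [canonical]:
                lookup[normalize_term(name)] = canonical
        return lookup

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("drug_synonyms", "event_terms", "substring_match", "indication_drug_linked", "sex_filter"):
            if key in payload:
                kwargs[key] = payload[key]
        for key in ("role_codes", "indication_terms"):
            if key in payload:
                kwargs[key] = tuple(payload[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        payload = {
            "drug_synonyms": {k: list(v) for k, v in self.drug_synonyms.items()},
            "role_codes": list(self.role_codes),
            "sex_filter": self.sex_filter,
            "indication_terms": list(self.indication_terms),
            "event_terms": list(self.event_terms),
            "substring_match": self.substring_match,
            "indication_drug_linked": self.indication_drug_linked,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# deduplication


@dataclass(frozen=True)
class DedupResult:
    kept_primaryids: frozenset[str]
    removed_count: int
    input_count: int

    def __post_init__(self) -> None:
        assert len(self.kept_primaryids) + self.removed_count == self.input_count


def deduplicate(demo: pd.DataFrame) -> DedupResult:
    """Keep one report version per case: latest FDA date, then higher primaryid.

    Missing receipt dates sort earliest, so a dated version always beats an
    undated one; among undated versions the higher primaryid wins.
    """
    if demo.empty:
        return DedupResult(frozenset(), 0, 0)
    work = demo[["primaryid", "caseid", "fda_dt"]].copy()
    work["_date_key"] = work["fda_dt"].map(date_sort_key)
    work["_pid_num"] = pd.to_numeric(work["primaryid"], errors="coerce")
    # non-numeric primaryids (not expected in the modern layout) sort lowest
    work["_pid_num"] = work["_pid_num"].fillna(float("-inf"))
    work = work.sort_values(["caseid", "_date_key", "_pid_num"], kind="mergesort")
    kept = work.groupby("caseid", sort=False).tail(1)["primaryid"]
    return DedupResult(
        kept_primaryids=frozenset(kept),
        removed_count=len(work) - len(kept),
        input_count=len(work),
    )


def match_drug(drugname: object, config: CohortConfig) -> str | None:
    """Map a verbatim drug name to its canonical name, or ``None``.

    Exact match after normalisation; with ``substring_match`` a name that
    contains a synonym as a substring also matches.
    """
    name = normalize_term(drugname)
    lookup = config.synonym_lookup()
    if name in lookup:
        return lookup[name]
    if config.substring_match:
        for syn, canonical in lookup.items():
            if syn in name:
                return canonical
    return None


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortResult:
    """Output of :func:`build_cohort`.

    ``drug_reports``: one row per (report, canonical drug) surviving every
    filter except the event-term filter.  ``event_reports``: one row per
    (report, canonical drug, matched event PT) — the *reports* of the
    analysis; demographics and dates attached.  ``flow``: long-format staged
    counts per drug (the selection flow diagram).
    """

    drug_reports: pd.DataFrame
    event_reports: pd.DataFrame
    flow: pd.DataFrame
    dedup: DedupResult

    def cases_by_drug(self) -> pd.Series:
        if self.event_reports.empty:
            return pd.Series(dtype=int)
        return self.event_reports.groupby("drug")["caseid"].nunique()

    def reports_by_drug(self) -> pd.Series:
        if self.event_reports.empty:
            return pd.Series(dtype=int)
        return self.event_reports.groupby("drug").size()

    def case_table(self) -> pd.DataFrame:
        """One row per (case, drug) with demographics — the descriptives input."""
        if self.event_reports.empty:
            return self.event_reports.copy()
        return (
            self.event_reports.sort_values(["drug", "caseid", "primaryid"])
            .drop_duplicates(["drug", "caseid"])
            .reset_index(drop=True)
        )


def _match_names_vector(names: pd.Series, config: CohortConfig) -> pd.Series:
    lookup = config.synonym_lookup()
    normalized = names.map(normalize_term)
    matched = normalized.map(lookup)
    if config.substring_match:
        missing = matched.isna()
        if missing.any():
            def sub(name: str) -> str | None:
                for syn, canonical in lookup.items():
                    if syn in name:
                        return canonical
                return None
            matched.loc[missing] = normalized[missing].map(sub)
    return matched


def build_cohort(
    dataset: QuarterDataset,
    config: CohortConfig | None = None,
    dedup: DedupResult | None = None,
) -> CohortResult:
    """Apply deduplication (unless supplied) and the staged cohort filters."""
    config = config or CohortConfig()
    if dedup is None:
        dedup = deduplicate(dataset.demo)
    kept = dedup.kept_primaryids

    demo = dataset.demo[dataset.demo["primaryid"].isin(kept)].copy()
    demo["age_years"] = [age_to_years(a, c) for a, c in zip(demo["age"], demo["age_cod"])]
    demo["sex_norm"] = demo["sex"].map(lambda s: str(s).strip().upper())

    # stage 1: suspect-role rows whose name matches a configured drug
    drug = dataset.drug[dataset.drug["primaryid"].isin(kept)].copy()
    drug["role_norm"] = drug["role_cod"].map(lambda s: str(s).strip().upper())
    drug = drug[drug["role_norm"].isin({r.upper() for r in config.role_codes})]
    drug["drug"] = _match_names_vector(drug["drugname"], config)
    matched = drug.dropna(subset=["drug"])
    # one row per (report, canonical drug); remember the matched drug_seq values
    matched_pairs = (
        matched.groupby(["primaryid", "drug"], sort=False)["drug_seq"]
        .agg(lambda s: tuple(sorted(set(s))))
        .reset_index()
        .rename(columns={"drug_seq": "drug_seqs"})
    )
    matched_pairs = matched_pairs.merge(
        demo[
            ["primaryid", "caseid", "fda_dt", "event_dt", "age_years", "sex_norm",
             "occp_cod", "reporter_country"]
        ],
        on="primaryid",
        how="inner",
    )

    drugs = list(config.drug_synonyms)
    flow_rows: list[dict] = []
    for d in drugs:
        flow_rows.append({"drug": d, "stage": "input", "count": len(demo)})
    stage1 = matched_pairs

    def record(stage: str, frame: pd.DataFrame) -> None:
        counts = frame.groupby("drug")["primaryid"].nunique() if len(frame) else pd.Series(dtype=int)
        for d in drugs:
            flow_rows.append({"drug": d, "stage": stage, "count": int(counts.get(d, 0))})

    record("suspect_drug", stage1)

    # stage 2: sex
    if config.sex_filter is not None:
        stage2 = stage1[stage1["sex_norm"] == config.sex_filter.upper()]
    else:
        stage2 = stage1
    record("sex", stage2)

    # stage 3: indication, linked to the matched drug's drug_seq by default
    indi = dataset.indi[dataset.indi["primaryid"].isin(kept)].copy()
    indi["indi_norm"] = indi["indi_pt"].map(normalize_term)
    wanted = {normalize_term(t) for t in config.indication_terms}
    indi = indi[indi["indi_norm"].isin(wanted)]
    if config.indication_drug_linked:
        indi_keys = set(zip(indi["primaryid"], indi["indi_drug_seq"]))
        has_indi = [
            any((pid, seq) in indi_keys for seq in seqs)
            for pid, seqs in zip(stage2["primaryid"], stage2["drug_seqs"])
        ]
    else:
        with_indi = set(indi["primaryid"])
        has_indi = stage2["primaryid"].isin(with_indi).tolist()
    stage3 = stage2[pd.Series(has_indi, index=stage2.index, dtype=bool)] if len(stage2) else stage2
    record("indication", stage3)

    # stage 4: event preferred terms
    reac = dataset.reac[dataset.reac["primaryid"].isin(kept)].copy()
    reac["pt_norm"] = reac["pt"].map(normalize_term)
    events = {normalize_term(t) for t in config.event_terms}
    reac = reac[reac["pt_norm"].isin(events)].drop_duplicates(["primaryid", "pt_norm"])
    event_reports = stage3.merge(
        reac[["primaryid", "pt_norm"]].rename(columns={"pt_norm": "pt"}),
        on="primaryid",
        how="inner",
    )
    record("event", event_reports)

    # therapy start for the matched suspect drug: earliest full-precision date
    ther = dataset.ther[dataset.ther["primaryid"].isin(kept)]
    ther_keys: dict[tuple[str, str], list[str]] = {}
    for pid, seq, start in zip(ther["primaryid"], ther["dsg_drug_seq"], ther["start_dt"]):
        ther_keys.setdefault((pid, seq), []).append(str(start).strip())

    def therapy_start(pid: str, seqs: tuple[str, ...]) -> tuple[str, str]:
        starts: list[str] = []
        for seq in seqs:
            starts.extend(ther_keys.get((pid, seq), []))
        full = sorted(s for s in starts if len(s) == 8 and s.isdigit())
        if full:
            return full[0], "full"
        if any(s for s in starts):
            return "", "partial"
        return "", "missing"

    for frame in (event_reports,):
        if len(frame):
            values = [therapy_start(p, s) for p, s in zip(frame["primaryid"], frame["drug_seqs"])]
            frame["ther_start_dt"] = [v[0] for v in values]
            frame["ther_start_status"] = [v[1] for v in values]
        else:
            frame["ther_start_dt"] = pd.Series(dtype=str)
            frame["ther_start_status"] = pd.Series(dtype=str)

    flow = pd.DataFrame(flow_rows, columns=["drug", "stage", "count"])
    event_reports = event_reports.rename(columns={"sex_norm": "sex", "reporter_country": "country"})
    keep_cols = [
        "primaryid", "caseid", "drug", "pt", "age_years", "sex", "occp_cod",
        "country", "fda_dt", "event_dt", "ther_start_dt", "ther_start_status",
    ]
    event_reports = event_reports[keep_cols].reset_index(drop=True)
    drug_reports = stage3.rename(columns={"sex_norm": "sex", "reporter_country": "country"}).reset_index(drop=True)
    return CohortResult(drug_reports=drug_reports, event_reports=event_reports, flow=flow, dedup=dedup)


def with_event_terms(config: CohortConfig, terms: list[str]) -> CohortConfig:
    return replace(config, event_terms=list(terms))
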