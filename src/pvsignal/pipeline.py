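"""End-to-end orchestration: load or simulate data, clean, analyse, write artifacts.

Every run writes CSV artifacts (selection flow, signal table, descriptives,
onset records/bins) plus a ``run.json`` sidecar carrying the seed and a
configuration digest, so identical configurations reproduce identical
output bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import curation, descriptives, onset as onset_mod
from .curation import CohortConfig, build_cohort, deduplicate
from .faers import QuarterDataset, concat_quarters, read_quarter
from .signal import DisproportionalityModel, suspect_pairs
from .simulate import GeneratorConfig, generate

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run."""

    quarters: list[str] = field(default_factory=list)
    generator: GeneratorConfig | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ic_variance: str = "delta"
    yates: bool = False
    continuity: str | None = None
    background_scope: str = "full"  # or "cohort"
    tto_bin_width: int = 37
    tto_quantile_method: str = "tukey"

    def __post_init__(self) -> None:
        if self.ic_variance not in ("delta", "bate"):
            raise ValueError(f"invalid ic_variance {self.ic_variance!r}")
        if self.background_scope not in ("full", "cohort"):
            raise ValueError(f"invalid background_scope {self.background_scope!r}")
        if self.continuity not in (None, "haldane"):
            raise ValueError(f"invalid continuity {self.continuity!r}")
        if self.tto_bin_width <= 0:
            raise ValueError("tto_bin_width must be positive")
        if self.tto_quantile_method not in ("tukey", "linear"):
            raise ValueError(f"invalid tto_quantile_method {self.tto_quantile_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        kwargs = dict(payload)
        if "generator" in kwargs and kwargs["generator"] is not None:
            gen = kwargs["generator"]
            if "drugs" in gen:
                from .simulate import DrugSpec
                gen["drugs"] = [DrugSpec(**d) for d in gen["drugs"]]
            if "age_mixture" in gen:
                gen["age_mixture"] = [tuple(c) for c in gen["age_mixture"]]
            if "window" in gen:
                gen["window"] = tuple(gen["window"])
            kwargs["generator"] = GeneratorConfig(**gen)
        if "cohort" in kwargs and kwargs["cohort"] is not None:
            c = dict(kwargs["cohort"])
            for key in ("role_codes", "indication_terms"):
                if key in c:
                    c[key] = tuple(c[key])
            kwargs["cohort"] = CohortConfig(**c)
        return cls(**kwargs)

    def digest(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        canon = json.dumps(self, default=default, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class PipelineArtifacts:
    dataset: QuarterDataset
    cohort: "curation.CohortResult"
    signals: "pd.DataFrame"
    summary_text: str
    descriptives: pd.DataFrame
    onset_records: pd.DataFrame
    onset_exclusions: pd.DataFrame
    onset_bins: pd.DataFrame


def load_dataset(config: PipelineConfig, seed: int | None = None) -> QuarterDataset:
    if config.quarters:
        return concat_quarters([read_quarter(q) for q in config.quarters])
    if config.generator is None:
        raise ValueError("config names neither quarter directories nor a generator")
    gen = config.generator
    if seed is not None:
        from dataclasses import replace
        gen = replace(gen, seed=seed)
    dataset, _ = generate(gen)
    return dataset


def run_pipeline(config: PipelineConfig, dataset: QuarterDataset) -> PipelineArtifacts:
    """Dedup -> cohort -> signals -> descriptives -> onset, in memory."""
    dedup = deduplicate(dataset.demo)
    log.info("dedup input=%d kept=%d removed=%d", dedup.input_count,
             len(dedup.kept_primaryids), dedup.removed_count)
    cohort = build_cohort(dataset, config.cohort, dedup=dedup)

    if config.background_scope == "cohort":
        scope_ids = set(cohort.drug_reports["primaryid"]) if len(cohort.drug_reports) else set()
    else:
        scope_ids = dedup.kept_primaryids
    pairs = suspect_pairs(dataset, scope_ids, role_codes=config.cohort.role_codes)
    if pairs.empty:
        signals = pd.DataFrame()
        summary_text = "no suspect (report, PT) pairs in scope"
    else:
        model = DisproportionalityModel.from_pairs(
            pairs, config.cohort.drug_synonyms, config.cohort.event_terms
        )
        results = model.fit(ic_variance=config.ic_variance, yates=config.yates,
                            continuity=config.continuity)
        signals = results.frame
        summary_text = results.summary()

    cases = cohort.case_table()
    desc = descriptives.summaries_frame(
        descriptives.summarize(cases, drugs=list(config.cohort.drug_synonyms))
        if len(cases) else []
    )

    records, exclusions = onset_mod.compute_onset(cohort.event_reports)
    per_drug = onset_mod.summarize_onset_by_drug(
        records, bin_width=config.tto_bin_width, method=config.tto_quantile_method
    )
    bin_rows = []
    for drug, s in per_drug.items():
        for lo, hi, count, pct in s.bins:
            bin_rows.append({
                "drug": drug, "lo": lo, "hi": hi, "count": count, "percent": pct,
                "n": s.n, "median_days": s.median_days, "q1": s.q1, "q3": s.q3,
            })
    onset_bins = pd.DataFrame(
        bin_rows, columns=["drug", "lo", "hi", "count", "percent", "n", "median_days", "q1", "q3"]
    )

    return PipelineArtifacts(
        dataset=dataset, cohort=cohort, signals=signals, summary_text=summary_text,
        descriptives=desc, onset_records=records, onset_exclusions=exclusions,
        onset_bins=onset_bins,
    )


def write_artifacts(artifacts: PipelineArtifacts, config: PipelineConfig,
                    out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    header = f"# config_sha256={digest} seed={seed}\n"

    def write_csv(frame: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            frame.to_csv(fh, index=index, lineterminator="\n")
        return path

    paths = {
        "flow": write_csv(artifacts.cohort.flow, "flow_counts.csv"),
        "signals": write_csv(
            artifacts.signals, "signals.csv",
            index=not artifacts.signals.empty,
        ),
        "descriptives": write_csv(artifacts.descriptives, "descriptives.csv"),
        "onset_records": write_csv(artifacts.onset_records, "onset_records.csv"),
        "onset_exclusions": write_csv(artifacts.onset_exclusions, "onset_exclusions.csv"),
        "onset_bins": write_csv(artifacts.onset_bins, "onset_bins.csv"),
    }
    (out / "signals_summary.txt").write_text(header + artifacts.summary_text + "\n", encoding="utf-8")
    paths["summary"] = out / "signals_summary.txt"
    run_info = {
        "config_sha256": digest,
        "seed": seed,
        "n_reports_loaded": artifacts.dataset.n_reports,
        "dedup_removed": artifacts.cohort.dedup.removed_count,
        "cases_by_drug": {k: int(v) for k, v in artifacts.cohort.cases_by_drug().items()},
        "reports_by_drug": {k: int(v) for k, v in artifacts.cohort.reports_by_drug().items()},
    }
    (out / "run.json").write_text(json.dumps(run_info, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["run"] = out / "run.json"
    return paths
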