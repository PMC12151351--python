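"""Synthetic FAERS-style spontaneous-report generator with known ground truth.

Emulates the quarterly DEMO/DRUG/REAC/INDI/THER tables so the whole
disproportionality pipeline runs — and can be validated — without any
download.  One *case* is one patient; a configurable fraction of cases is
emitted as two report versions (same ``caseid``, distinct ``primaryid``,
later-or-equal FDA receipt date) to exercise deduplication.

The generative model, chosen so every estimand has a closed form:

* each report carries one suspect (PS) drug drawn by prescribing weight;
* a severe-cutaneous-reaction (SCAR) indicator is Bernoulli with odds
  ``baseline_odds * OR_drug`` where ``OR_drug`` is the injected association
  for that drug (1 for background drugs) — the population reporting odds
  ratio for every injected drug-event pair is therefore exactly the
  configured value;
* SCAR reports carry one SCARs preferred term (two distinct ones with a
  small configured probability, so cases < reports), other reports one
  background term;
* therapy start is back-dated from the event date by a per-drug log-normal
  onset, so the configured onset median is the true one;
* demographics (age mixture concentrated in 65-85, sex, reporter
  occupation, country), indication (prostate cancer with per-drug
  probability), date partiality/missingness and a concomitant drug row are
  layered on top without touching the drug-event estimand.

Fixed seed implies byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curation import SGARA_SYNONYMS, default_event_terms
from .faers import QuarterDataset, TABLE_COLUMNS, write_quarter

FILLER_TERMS_DEFAULT = [
    "NAUSEA", "FATIGUE", "DIARRHOEA", "RASH", "DIZZINESS", "HEADACHE",
    "ARTHRALGIA", "FALL", "HOT FLUSH", "WEIGHT DECREASED", "ANAEMIA",
    "HYPERTENSION", "BACK PAIN", "DECREASED APPETITE", "SEIZURE",
]

OTHER_INDICATIONS = [
    "PRODUCT USED FOR UNKNOWN INDICATION", "MALIGNANT NEOPLASM",
    "HYPERTENSION", "DIABETES MELLITUS", "GASTROOESOPHAGEAL REFLUX DISEASE",
    "PAIN",
]

BACKGROUND_DRUGS = [
    ("ABIRATERONE", 0.06, 0.5), ("DOCETAXEL", 0.05, 0.5),
    ("BICALUTAMIDE", 0.04, 0.5), ("PEMBROLIZUMAB", 0.07, 0.05),
    ("ATORVASTATIN", 0.12, 0.01), ("METFORMIN", 0.12, 0.01),
    ("ASPIRIN", 0.10, 0.01), ("LISINOPRIL", 0.08, 0.01),
    ("OMEPRAZOLE", 0.08, 0.01), ("IBUPROFEN", 0.09, 0.01),
    ("AMOXICILLIN", 0.09, 0.01),
]


@dataclass
class DrugSpec:
    """One drug in the simulated catalogue."""

    name: str
    synonyms: list[str] = field(default_factory=list)
    weight: float = 0.05
    prostate_indication_prob: float = 0.05
    onset_median_days: float = 30.0
    onset_sigma: float = 1.0

    def all_names(self) -> list[str]:
        return [self.name.upper()] + [s.upper() for s in self.synonyms]


@dataclass
class GeneratorConfig:
    """Full parameterisation of the simulator; defaults mirror a scaled-down
    prostate-cancer reporting landscape (three AR antagonists among a
    background catalogue, elderly male-heavy demographics, Japan/US-heavy
    reporting)."""

    seed: int = 0
    n_reports: int = 20000
    drugs: list[DrugSpec] = field(default_factory=list)
    injected_associations: dict[str, float] = field(default_factory=dict)
    scars_terms: list[str] = field(default_factory=default_event_terms)
    filler_terms: list[str] = field(default_factory=lambda: list(FILLER_TERMS_DEFAULT))
    background_scar_prob: float = 0.003
    multi_scar_rate: float = 0.05
    sex_dist: dict[str, float] = field(default_factory=lambda: {"M": 0.80, "F": 0.16, "UNK": 0.02, "": 0.02})
    occupation_dist: dict[str, float] = field(
        default_factory=lambda: {"MD": 0.38, "PH": 0.16, "RN": 0.09, "HP": 0.10, "CN": 0.17, "LW": 0.02, "": 0.08}
    )
    country_dist: dict[str, float] = field(
        default_factory=lambda: {
            "JP": 0.30, "US": 0.22, "FR": 0.08, "CN": 0.06, "DE": 0.05,
            "GB": 0.04, "KR": 0.03, "TW": 0.02, "IT": 0.03, "BR": 0.02,
            "CA": 0.03, "ES": 0.03, "IE": 0.01, "FI": 0.01, "CH": 0.01,
            "BE": 0.01, "NL": 0.01, "RO": 0.01, "": 0.03,
        }
    )
    age_missing_prob: float = 0.15
    age_mixture: list[tuple] = field(
        default_factory=lambda: [(0.70, "normal", 75.0, 6.0), (0.25, "normal", 56.0, 9.0), (0.05, "uniform", 5.0, 17.0)]
    )
    duplicate_rate: float = 0.10
    duplicate_tie_rate: float = 0.30
    event_dt_missing: float = 0.12
    event_dt_partial: float = 0.08
    start_dt_missing: float = 0.08
    start_dt_partial: float = 0.08
    concomitant_rate: float = 0.20
    window: tuple[str, str] = ("20180101", "20240630")

    def __post_init__(self) -> None:
        if not self.drugs:
            self.drugs = default_drug_catalog()
            if not self.injected_associations:
                self.injected_associations = {"apalutamide": 33.0, "enzalutamide": 0.36, "darolutamide": 0.43}
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not self.scars_terms or not self.filler_terms:
            raise ValueError("term catalogues must be non-empty")
        if not 0.0 < self.background_scar_prob < 1.0:
            raise ValueError("background_scar_prob must lie in (0, 1)")
        for name, orr in self.injected_associations.items():
            if orr <= 0:
                raise ValueError(f"injected odds ratio for {name} must be positive")
            if self._scar_prob(orr) >= 1.0:
                raise ValueError(f"infeasible odds configuration for {name}: implied probability >= 1")
        for spec in self.drugs:
            if spec.weight <= 0:
                raise ValueError(f"drug weight for {spec.name} must be positive")
            if not 0.0 <= spec.prostate_indication_prob <= 1.0:
                raise ValueError("prostate_indication_prob must lie in [0, 1]")
            if spec.onset_median_days <= 0 or spec.onset_sigma <= 0:
                raise ValueError("onset model parameters must be positive")
        for prob in (
            self.multi_scar_rate, self.age_missing_prob, self.duplicate_rate,
            self.duplicate_tie_rate, self.event_dt_missing, self.event_dt_partial,
            self.start_dt_missing, self.start_dt_partial, self.concomitant_rate,
        ):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for dist in (self.sex_dist, self.occupation_dist, self.country_dist):
            if any(v < 0 for v in dist.values()) or sum(dist.values()) <= 0:
                raise ValueError("distribution weights must be non-negative and sum > 0")
        for w, kind, *_ in self.age_mixture:
            if w < 0 or kind not in ("normal", "uniform"):
                raise ValueError("invalid age mixture component")

    # -- derived quantities ----------------------------------------------
    def _scar_prob(self, odds_ratio: float) -> float:
        p0 = self.background_scar_prob
        odds = p0 / (1.0 - p0) * odds_ratio
        return odds / (1.0 + odds)

    def scar_prob_by_drug(self) -> dict[str, float]:
        return {
            spec.name: self._scar_prob(self.injected_associations.get(spec.name, 1.0))
            for spec in self.drugs
        }

    def drug_weights(self) -> np.ndarray:
        w = np.array([s.weight for s in self.drugs], dtype=float)
        return w / w.sum()

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["age_mixture"] = [list(c) for c in self.age_mixture]
        payload["window"] = list(self.window)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if "drugs" in payload:
            payload["drugs"] = [DrugSpec(**d) for d in payload["drugs"]]
        if "age_mixture" in payload:
            payload["age_mixture"] = [tuple(c) for c in payload["age_mixture"]]
        if "window" in payload:
            payload["window"] = tuple(payload["window"])
        return cls(**payload)


def default_drug_catalog() -> list[DrugSpec]:
    catalog = [
        DrugSpec("enzalutamide", SGARA_SYNONYMS["enzalutamide"], 0.05, 0.90, 28.5, 1.1),
        DrugSpec("apalutamide", SGARA_SYNONYMS["apalutamide"], 0.04, 0.90, 30.0, 0.7),
        DrugSpec("darolutamide", SGARA_SYNONYMS["darolutamide"], 0.01, 0.90, 30.0, 1.0),
    ]
    for name, weight, p_ind in BACKGROUND_DRUGS:
        catalog.append(DrugSpec(name, [], weight, p_ind, 30.0, 1.0))
    return catalog


@dataclass
class GroundTruth:
    """Closed-form expectations implied by a GeneratorConfig (no sampling)."""

    expected_pairs: dict[str, dict[str, float]]
    onset_median_days: dict[str, float]
    duplicate_extra_versions: int
    expected_flow: dict[str, dict[str, float]]
    injected_associations: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def ground_truth(config: GeneratorConfig) -> GroundTruth:
    n = config.n_reports
    w = config.drug_weights()
    p_scar = config.scar_prob_by_drug()
    multi = config.multi_scar_rate
    p_male = config.sex_dist.get("M", 0.0) / sum(config.sex_dist.values())
    exp_scar_pairs = {
        s.name: n * w[i] * p_scar[s.name] * (1.0 + multi) for i, s in enumerate(config.drugs)
    }
    exp_other_pairs = {
        s.name: n * w[i] * (1.0 - p_scar[s.name]) for i, s in enumerate(config.drugs)
    }
    total_scar = sum(exp_scar_pairs.values())
    total_other = sum(exp_other_pairs.values())
    expected_pairs = {}
    expected_flow = {}
    for i, s in enumerate(config.drugs):
        expected_pairs[s.name] = {
            "a": exp_scar_pairs[s.name],
            "b": exp_other_pairs[s.name],
            "c": total_scar - exp_scar_pairs[s.name],
            "d": total_other - exp_other_pairs[s.name],
        }
        n_drug = n * w[i]
        expected_flow[s.name] = {
            "input": float(n),
            "suspect_drug": n_drug,
            "sex": n_drug * p_male,
            "indication": n_drug * p_male * s.prostate_indication_prob,
            "event": n_drug * p_male * s.prostate_indication_prob * p_scar[s.name],
        }
    return GroundTruth(
        expected_pairs=expected_pairs,
        onset_median_days={s.name: s.onset_median_days for s in config.drugs},
        duplicate_extra_versions=int(round(config.duplicate_rate * n)),
        expected_flow=expected_flow,
        injected_associations=dict(config.injected_associations),
    )


# ---------------------------------------------------------------------------
# generation


def _categorical(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    keys = list(dist)
    p = np.array([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=n, p=p)]


def _dates_to_str(days: np.ndarray, base: np.datetime64) -> pd.Series:
    stamps = pd.to_datetime(base) + pd.to_timedelta(days, unit="D")
    return pd.Series(pd.DatetimeIndex(stamps).strftime("%Y%m%d"))


def _truncate_dates(dates: pd.Series, partial_mask: np.ndarray, month_mask: np.ndarray) -> pd.Series:
    out = dates.copy()
    to_month = partial_mask & month_mask
    to_year = partial_mask & ~month_mask
    out[to_month] = out[to_month].str[:6]
    out[to_year] = out[to_year].str[:4]
    return out


def generate(config: GeneratorConfig) -> tuple[QuarterDataset, GroundTruth]:
    """Sample one multi-quarter dataset and its closed-form ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = config.drugs
    k = len(drugs)

    drug_idx = rng.choice(k, size=n, p=config.drug_weights())
    p_scar = np.array([config.scar_prob_by_drug()[s.name] for s in drugs])
    scar = rng.random(n) < p_scar[drug_idx]
    multi = scar & (rng.random(n) < config.multi_scar_rate)

    n_scars = len(config.scars_terms)
    scar_pt1 = rng.integers(0, n_scars, size=n)
    scar_pt2 = (scar_pt1 + 1 + rng.integers(0, max(n_scars - 1, 1), size=n)) % n_scars
    filler_pt = rng.integers(0, len(config.filler_terms), size=n)

    # calendar scaffold
    base = np.datetime64(f"{config.window[0][:4]}-{config.window[0][4:6]}-{config.window[0][6:]}")
    end = np.datetime64(f"{config.window[1][:4]}-{config.window[1][4:6]}-{config.window[1][6:]}")
    span = int((end - base) / np.timedelta64(1, "D"))
    event_days = rng.integers(0, span + 1, size=n)
    med = np.array([s.onset_median_days for s in drugs])
    sig = np.array([s.onset_sigma for s in drugs])
    onset = np.rint(rng.lognormal(np.log(med[drug_idx]), sig[drug_idx])).astype(int)
    lag = np.rint(rng.lognormal(math.log(21.0), 0.7, size=n)).astype(int)
    event_str_full = _dates_to_str(event_days, base)
    start_str_full = _dates_to_str(event_days - onset, base)
    fda_str = _dates_to_str(event_days + lag, base)

    event_missing = rng.random(n) < config.event_dt_missing
    event_partial = ~event_missing & (rng.random(n) < config.event_dt_partial)
    event_month = rng.random(n) < 0.5
    start_missing = rng.random(n) < config.start_dt_missing
    start_partial = ~start_missing & (rng.random(n) < config.start_dt_partial)
    start_month = rng.random(n) < 0.5
    event_str = _truncate_dates(event_str_full, event_partial, event_month)
    event_str[event_missing] = ""
    start_str = _truncate_dates(start_str_full, start_partial, start_month)

    # demographics
    sex = _categorical(rng, config.sex_dist, n)
    occp = _categorical(rng, config.occupation_dist, n)
    country = _categorical(rng, config.country_dist, n)
    mix_w = np.array([c[0] for c in config.age_mixture], dtype=float)
    comp = rng.choice(len(config.age_mixture), size=n, p=mix_w / mix_w.sum())
    age_years = np.zeros(n)
    for i, (_, kind, p1, p2) in enumerate(config.age_mixture):
        mask = comp == i
        m = int(mask.sum())
        if kind == "normal":
            age_years[mask] = rng.normal(p1, p2, size=m)
        else:
            age_years[mask] = rng.uniform(p1, p2, size=m)
    age_years = np.clip(np.rint(age_years), 0, 105)
    age_missing = rng.random(n) < config.age_missing_prob
    age_dec = rng.random(n) < 0.05  # a slice reported in decades
    age_vals = np.where(age_dec, age_years / 10.0, age_years)
    age_cod = np.where(age_dec, "DEC", "YR")

    # indication & drug-name rendering
    prost = rng.random(n) < np.array([s.prostate_indication_prob for s in drugs])[drug_idx]
    other_ind = rng.integers(0, len(OTHER_INDICATIONS), size=n)
    syn_pick = rng.random(n)
    title_case = rng.random(n) < 0.3
    names = np.empty(n, dtype=object)
    for i, spec in enumerate(drugs):
        mask = drug_idx == i
        options = spec.all_names()
        choice = (syn_pick[mask] * len(options)).astype(int)
        names[mask] = np.array(options, dtype=object)[choice]
    names = np.where(title_case, [str(x).title() for x in names], names)

    conc = rng.random(n) < config.concomitant_rate
    conc_idx = rng.integers(0, k, size=n)
    conc_names = np.array([drugs[i].name.upper() for i in conc_idx], dtype=object)
    conc_prost = rng.random(n) < 0.10
    conc_other = rng.integers(0, len(OTHER_INDICATIONS), size=n)

    # duplicates: chosen cases get a second, later-or-equal version
    n_dup = int(round(config.duplicate_rate * n))
    dup_rows = np.sort(rng.choice(n, size=n_dup, replace=False))
    tie = rng.random(n_dup) < config.duplicate_tie_rate
    extra_lag = np.where(tie, 0, 1 + rng.integers(0, 90, size=n_dup))
    fda2_str = _dates_to_str(event_days[dup_rows] + lag[dup_rows] + extra_lag, base)

    caseid = (10_000_000 + np.arange(n)).astype(str)
    pid1 = ((10_000_000 + np.arange(n)) * 100 + 1).astype(str)
    pid2 = ((10_000_000 + dup_rows) * 100 + 2).astype(str)

    age_str = np.where(age_missing, "", np.where(age_dec, [f"{v:.1f}" for v in age_vals], [f"{int(v)}" for v in age_vals]))
    age_cod_str = np.where(age_missing, "", age_cod)

    demo_v1 = pd.DataFrame({
        "primaryid": pid1, "caseid": caseid, "fda_dt": fda_str.to_numpy(dtype=object),
        "event_dt": event_str.to_numpy(dtype=object), "age": age_str, "age_cod": age_cod_str,
        "sex": sex, "occp_cod": occp, "reporter_country": country,
    })
    demo_v2 = demo_v1.iloc[dup_rows].copy()
    demo_v2["primaryid"] = pid2
    demo_v2["fda_dt"] = fda2_str.to_numpy(dtype=object)
    demo = pd.concat([demo_v1, demo_v2], ignore_index=True).astype(str)

    # DRUG: suspect (seq 1, PS) + concomitant (seq 2, C)
    def drug_frame(pids, sel):
        idx = np.arange(n)[sel]
        p = np.asarray(pids, dtype=object)
        sus = pd.DataFrame({
            "primaryid": p, "drug_seq": "1", "role_cod": "PS", "drugname": names[idx],
        })
        cmask = conc[idx]
        con = pd.DataFrame({
            "primaryid": p[cmask], "drug_seq": "2", "role_cod": "C",
            "drugname": conc_names[idx][cmask],
        })
        return pd.concat([sus, con], ignore_index=True)

    drug_tab = pd.concat([drug_frame(pid1, slice(None)), drug_frame(pid2, dup_rows)], ignore_index=True).astype(str)

    # REAC: one SCAR PT (two when multi) or one filler PT
    scars_arr = np.array(config.scars_terms, dtype=object)
    filler_arr = np.array(config.filler_terms, dtype=object)

    def reac_frame(pids, sel):
        idx = np.arange(n)[sel]
        p = np.asarray(pids, dtype=object)
        smask = scar[idx]
        mmask = multi[idx]
        parts = [
            pd.DataFrame({"primaryid": p[smask], "pt": scars_arr[scar_pt1[idx][smask]]}),
            pd.DataFrame({"primaryid": p[mmask], "pt": scars_arr[scar_pt2[idx][mmask]]}),
            pd.DataFrame({"primaryid": p[~smask], "pt": filler_arr[filler_pt[idx][~smask]]}),
        ]
        return pd.concat(parts, ignore_index=True)

    reac_tab = pd.concat([reac_frame(pid1, slice(None)), reac_frame(pid2, dup_rows)], ignore_index=True).astype(str)

    # INDI: indication for the suspect drug; concomitant gets its own row
    other_arr = np.array(OTHER_INDICATIONS, dtype=object)

    def indi_frame(pids, sel):
        idx = np.arange(n)[sel]
        p = np.asarray(pids, dtype=object)
        ind1 = np.where(prost[idx], "PROSTATE CANCER", other_arr[other_ind[idx]])
        parts = [pd.DataFrame({"primaryid": p, "indi_drug_seq": "1", "indi_pt": ind1})]
        cmask = conc[idx]
        ind2 = np.where(conc_prost[idx][cmask], "PROSTATE CANCER", other_arr[conc_other[idx][cmask]])
        parts.append(pd.DataFrame({"primaryid": p[cmask], "indi_drug_seq": "2", "indi_pt": ind2}))
        return pd.concat(parts, ignore_index=True)

    indi_tab = pd.concat([indi_frame(pid1, slice(None)), indi_frame(pid2, dup_rows)], ignore_index=True).astype(str)

    # THER: start date for the suspect drug, unless missing
    def ther_frame(pids, sel):
        idx = np.arange(n)[sel]
        p = np.asarray(pids, dtype=object)
        present = ~start_missing[idx]
        starts = start_str.to_numpy(dtype=object)[idx][present]
        return pd.DataFrame({"primaryid": p[present], "dsg_drug_seq": "1", "start_dt": starts})

    ther_tab = pd.concat([ther_frame(pid1, slice(None)), ther_frame(pid2, dup_rows)], ignore_index=True).astype(str)

    for name_, tab in (("demo", demo), ("drug", drug_tab), ("reac", reac_tab), ("indi", indi_tab), ("ther", ther_tab)):
        tab.reset_index(drop=True, inplace=True)
        missing_cols = [c for c in TABLE_COLUMNS[name_] if c not in tab.columns]
        for c in missing_cols:
            tab[c] = ""

    dataset = QuarterDataset(
        demo=demo, drug=drug_tab, reac=reac_tab, indi=indi_tab, ther=ther_tab,
        provenance={t: [f"synthetic(seed={config.seed})"] for t in TABLE_COLUMNS},
    )
    return dataset, ground_truth(config)


def generate_files(config: GeneratorConfig, out_dir: str | Path) -> tuple[dict, GroundTruth]:
    """Generate and write the five tables plus a ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    dataset, truth = generate(config)
    paths = write_quarter(dataset, out_dir)
    truth.to_json(out_dir / "ground_truth.json")
    return paths, truth


# ---------------------------------------------------------------------------
# recovery experiments


def recovery_config(odds_ratio: float = 30.0, seed: int = 0) -> GeneratorConfig:
    """Injected-signal recovery setting.

    One exposed drug carries 2% of a 20,000-report database — the comparator
    cells are well populated, as in a real spontaneous-reporting system —
    and the background SCAR probability is set so the expected target-drug
    SCAR pair count is ~75 at the default injected odds ratio of 30.
    """
    drugs = [
        DrugSpec("apalutamide", SGARA_SYNONYMS["apalutamide"], 0.02, 0.90, 30.0, 0.7),
        DrugSpec("ATORVASTATIN", [], 0.33, 0.01),
        DrugSpec("METFORMIN", [], 0.33, 0.01),
        DrugSpec("OMEPRAZOLE", [], 0.32, 0.01),
    ]
    return GeneratorConfig(
        seed=seed,
        n_reports=20000,
        drugs=drugs,
        injected_associations={"apalutamide": odds_ratio},
        background_scar_prob=0.0072,
    )


def null_config(seed: int = 0) -> GeneratorConfig:
    """The same setting with no association (odds ratio 1 everywhere)."""
    return recovery_config(odds_ratio=1.0, seed=seed)


def recovery_experiment(
    config: GeneratorConfig,
    replicates: int,
    target_drug: str | None = None,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo validation of the estimators against the injected truth.

    Per replicate: generate, deduplicate, count suspect (report, PT) pairs,
    evaluate all four estimators for the target drug.  Returns one row per
    estimator with the mean point estimate, mean bias against the injected
    odds ratio, the coverage of the ROR 95% CI, and the positive-flag rate.
    """
    from .curation import deduplicate
    from .signal import contingency, evaluate_signal, suspect_pairs

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if target_drug is None:
        target_drug = next(iter(config.injected_associations))
    truth_or = config.injected_associations.get(target_drug, 1.0)
    spec = next(s for s in config.drugs if s.name == target_drug)
    names = spec.all_names()

    estimates: dict[str, list[float]] = {"ror": [], "prr": [], "ic": [], "ebgm": []}
    flags: dict[str, list[bool]] = {"ror": [], "prr": [], "ic": [], "ebgm": []}
    covered: list[bool] = []
    start = config.seed if base_seed is None else base_seed
    for i in range(replicates):
        cfg = replace(config, seed=start + i)
        dataset, _ = generate(cfg)
        dedup = deduplicate(dataset.demo)
        pairs = suspect_pairs(dataset, dedup.kept_primaryids)
        table = contingency(pairs, names, cfg.scars_terms)
        res = evaluate_signal(table)
        estimates["ror"].append(res.ror)
        estimates["prr"].append(res.prr)
        estimates["ic"].append(res.ic)
        estimates["ebgm"].append(res.ebgm)
        flags["ror"].append(res.ror_positive)
        flags["prr"].append(res.prr_positive)
        flags["ic"].append(res.bcpnn_positive)
        flags["ebgm"].append(res.mgps_positive)
        if res.ror_lo95 == res.ror_lo95 and res.ror_hi95 == res.ror_hi95:
            covered.append(res.ror_lo95 <= truth_or <= res.ror_hi95)
        else:
            covered.append(False)

    rows = []
    truth_values = {
        "ror": truth_or, "prr": float("nan"),
        "ic": math.log2(truth_or), "ebgm": float("nan"),
    }
    for est in ("ror", "prr", "ic", "ebgm"):
        vals = np.array(estimates[est], dtype=float)
        finite = vals[np.isfinite(vals)]
        mean = float(finite.mean()) if len(finite) else float("nan")
        truth = truth_values[est]
        rows.append({
            "estimator": est,
            "mean_estimate": mean,
            "injected_value": truth,
            "mean_bias": mean - truth if truth == truth else float("nan"),
            "ci_coverage": float(np.mean(covered)) if est == "ror" else float("nan"),
            "flag_rate": float(np.mean(flags[est])),
        })
    return pd.DataFrame(rows)
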