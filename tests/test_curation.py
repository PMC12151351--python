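"""Deduplication rule, drug-name matching, and staged cohort construction."""

import numpy as np
import pandas as pd
import pytest

from pvsignal.curation import (
    CohortConfig,
    build_cohort,
    deduplicate,
    match_drug,
    normalize_term,
)
from pvsignal.faers import date_sort_key

from conftest import demo_row, make_dataset


def demo_frame(rows):
    return make_dataset(demo=rows).demo


class TestDeduplicate:
    def test_later_fda_date_wins(self):
        demo = demo_frame([
            demo_row("1001", caseid="100", fda="20230101"),
            demo_row("1000", caseid="100", fda="20230301"),
        ])
        assert deduplicate(demo).kept_primaryids == {"1000"}

    def test_tied_date_higher_primaryid_wins(self):
        demo = demo_frame([
            demo_row("1001", caseid="100", fda="20230101"),
            demo_row("1002", caseid="100", fda="20230101"),
        ])
        assert deduplicate(demo).kept_primaryids == {"1002"}

    def test_dated_version_beats_undated(self):
        demo = demo_frame([
            demo_row("9999", caseid="100", fda=""),
            demo_row("1000", caseid="100", fda="20200101"),
        ])
        assert deduplicate(demo).kept_primaryids == {"1000"}

    def test_matches_bruteforce_on_random_versions(self):
        # 1,000 versions over 100 caseids, random dates incl. missing/partial
        rng = np.random.default_rng(42)
        n = 1000
        caseids = rng.integers(0, 100, n).astype(str)
        dates = np.where(
            rng.random(n) < 0.1, "",
            (20180000 + rng.integers(101, 1231, n)).astype(str),
        )
        pids = rng.permutation(n) + 10
        demo = demo_frame([
            demo_row(str(p), caseid=c, fda=d) for p, c, d in zip(pids, caseids, dates)
        ])
        result = deduplicate(demo)

        # independent brute-force per-caseid scan
        best: dict[str, tuple] = {}
        for p, c, d in zip(pids, caseids, dates):
            key = (date_sort_key(d), int(p))
            if c not in best or key > best[c][0]:
                best[c] = (key, str(p))
        expected = {v[1] for v in best.values()}
        assert result.kept_primaryids == expected
        assert result.removed_count == n - len(expected)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        demo = demo_frame([
            demo_row(str(1000 + i), caseid=str(rng.integers(0, 30)),
                     fda=str(20200000 + rng.integers(101, 1231)))
            for i in range(200)
        ])
        once = deduplicate(demo)
        again = deduplicate(demo[demo["primaryid"].isin(once.kept_primaryids)])
        assert again.kept_primaryids == once.kept_primaryids
        assert again.removed_count == 0

    def test_empty(self):
        res = deduplicate(demo_frame([]))
        assert res.input_count == 0 and not res.kept_primaryids


class TestMatchDrug:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("XTANDI", "enzalutamide"),
            ("xtandi", "enzalutamide"),
            ("  Apalutamide ", "apalutamide"),
            ("ERLEADA", "apalutamide"),
            ("NUBEQA", "darolutamide"),
            ("DAROLUTAMIDE", "darolutamide"),
            ("ENZALUTAMIDE.", None),  # exact rule: trailing punctuation fails
            ("XTANDI 40MG", None),
            ("ENZA", None),
            ("ASPIRIN", None),
        ],
    )
    def test_exact_matching_enumeration(self, name, expected):
        assert match_drug(name, CohortConfig()) == expected

    def test_substring_mode(self):
        cfg = CohortConfig(substring_match=True)
        assert match_drug("XTANDI 40MG TABLET", cfg) == "enzalutamide"
        assert match_drug("ASPIRIN", cfg) is None

    def test_whitespace_collapse(self):
        assert normalize_term("  stevens-johnson   syndrome ") == "STEVENS-JOHNSON SYNDROME"


class TestBuildCohort:
    def test_staged_flow_counts(self, staged_dataset):
        res = build_cohort(staged_dataset)
        flow = res.flow.set_index(["drug", "stage"])["count"]
        assert flow[("apalutamide", "input")] == 6
        assert flow[("apalutamide", "suspect_drug")] == 3
        assert flow[("apalutamide", "sex")] == 2
        assert flow[("apalutamide", "indication")] == 2
        assert flow[("apalutamide", "event")] == 1
        assert res.cases_by_drug()["apalutamide"] == 1
        assert res.reports_by_drug()["apalutamide"] == 1

    def test_flow_monotone(self, staged_dataset):
        res = build_cohort(staged_dataset)
        for drug, grp in res.flow.groupby("drug"):
            ordered = grp.set_index("stage").loc[list(["input", "suspect_drug", "sex", "indication", "event"])]
            counts = ordered["count"].to_list()
            assert all(x >= y for x, y in zip(counts, counts[1:]))

    def test_two_event_terms_one_case_two_reports(self):
        ds = make_dataset(
            demo=[demo_row("1", sex="M")],
            drug=[{"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "APALUTAMIDE"}],
            indi=[{"primaryid": "1", "indi_drug_seq": "1", "indi_pt": "PROSTATE CANCER"}],
            reac=[
                {"primaryid": "1", "pt": "STEVENS-JOHNSON SYNDROME"},
                {"primaryid": "1", "pt": "TOXIC EPIDERMAL NECROLYSIS"},
            ],
        )
        res = build_cohort(ds)
        assert res.cases_by_drug()["apalutamide"] == 1
        assert res.reports_by_drug()["apalutamide"] == 2

    def test_excluded_indications_not_in_default_list(self):
        # 'product used for unknown indication' and 'malignant neoplasm'
        # are deliberately NOT accepted as prostate-cancer indications
        for indi_pt in ("PRODUCT USED FOR UNKNOWN INDICATION", "MALIGNANT NEOPLASM"):
            ds = make_dataset(
                demo=[demo_row("1", sex="M")],
                drug=[{"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "APALUTAMIDE"}],
                indi=[{"primaryid": "1", "indi_drug_seq": "1", "indi_pt": indi_pt}],
                reac=[{"primaryid": "1", "pt": "STEVENS-JOHNSON SYNDROME"}],
            )
            res = build_cohort(ds)
            assert len(res.event_reports) == 0

    def test_indication_must_be_linked_to_suspect_drug(self):
        ds = make_dataset(
            demo=[demo_row("1", sex="M")],
            drug=[
                {"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "APALUTAMIDE"},
                {"primaryid": "1", "drug_seq": "2", "role_cod": "C", "drugname": "ASPIRIN"},
            ],
            indi=[{"primaryid": "1", "indi_drug_seq": "2", "indi_pt": "PROSTATE CANCER"}],
            reac=[{"primaryid": "1", "pt": "STEVENS-JOHNSON SYNDROME"}],
        )
        assert len(build_cohort(ds).event_reports) == 0
        relaxed = CohortConfig(indication_drug_linked=False)
        assert len(build_cohort(ds, relaxed).event_reports) == 1

    def test_missing_sex_excluded(self):
        ds = make_dataset(
            demo=[demo_row("1", sex="")],
            drug=[{"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "APALUTAMIDE"}],
            indi=[{"primaryid": "1", "indi_drug_seq": "1", "indi_pt": "PROSTATE CANCER"}],
            reac=[{"primaryid": "1", "pt": "STEVENS-JOHNSON SYNDROME"}],
        )
        assert len(build_cohort(ds).event_reports) == 0

    def test_no_matching_drug_is_empty_not_error(self):
        ds = make_dataset(
            demo=[demo_row("1")],
            drug=[{"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "ASPIRIN"}],
            reac=[{"primaryid": "1", "pt": "NAUSEA"}],
        )
        res = build_cohort(ds)
        assert len(res.event_reports) == 0
        assert res.flow["count"].iloc[-1] == 0

    def test_empty_term_list_is_hard_error(self):
        with pytest.raises(ValueError):
            CohortConfig(event_terms=[])
        with pytest.raises(ValueError):
            CohortConfig(indication_terms=())

    def test_therapy_start_attached_from_matched_drug_seq(self, staged_dataset):
        res = build_cohort(staged_dataset)
        row = res.event_reports.iloc[0]
        assert row["ther_start_dt"] == "20230101"
        assert row["ther_start_status"] == "full"

    def test_cases_never_exceed_reports_on_synthetic_data(self):
        from pvsignal.simulate import GeneratorConfig, generate

        ds, _ = generate(GeneratorConfig(seed=3, n_reports=4000))
        res = build_cohort(ds)
        cases, reports = res.cases_by_drug(), res.reports_by_drug()
        for drug in cases.index:
            assert cases[drug] <= reports[drug]


def test_cohort_config_yaml_roundtrip(tmp_path):
    cfg = CohortConfig(substring_match=True)
    path = tmp_path / "cohort.yaml"
    cfg.to_yaml(path)
    back = CohortConfig.from_yaml(path)
    assert back.drug_synonyms == cfg.drug_synonyms
    assert back.event_terms == cfg.event_terms
    assert back.substring_match is True
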