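import pandas as pd
import pytest

from pvsignal.faers import QuarterDataset, TABLE_COLUMNS


def frame(name: str, rows: list[dict]) -> pd.DataFrame:
    cols = TABLE_COLUMNS[name]
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=str) for c in cols})
    out = pd.DataFrame(rows).astype(str)
    for c in cols:
        if c not in out.columns:
            out[c] = ""
    return out[cols]


def make_dataset(demo=(), drug=(), reac=(), indi=(), ther=()) -> QuarterDataset:
    return QuarterDataset(
        demo=frame("demo", list(demo)),
        drug=frame("drug", list(drug)),
        reac=frame("reac", list(reac)),
        indi=frame("indi", list(indi)),
        ther=frame("ther", list(ther)),
    )


def demo_row(pid, caseid=None, fda="20230101", sex="M", **kw):
    row = {
        "primaryid": pid,
        "caseid": caseid if caseid is not None else pid,
        "fda_dt": fda,
        "event_dt": kw.pop("event_dt", ""),
        "age": kw.pop("age", "70"),
        "age_cod": kw.pop("age_cod", "YR"),
        "sex": sex,
        "occp_cod": kw.pop("occp_cod", "MD"),
        "reporter_country": kw.pop("country", "US"),
    }
    row.update(kw)
    return row


@pytest.fixture
def staged_dataset():
    """Six deduplicated reports exercising each cohort filter in turn.

    Reports 1-3 carry the target drug as primary suspect; 1-2 are male;
    both 1 and 2 have a drug-linked prostate-cancer indication; only report
    1 has a SCARs preferred term.
    """
    demo = [
        demo_row("1", sex="M", event_dt="20230215"),
        demo_row("2", sex="M"),
        demo_row("3", sex="F"),
        demo_row("4", sex="M"),
        demo_row("5", sex="M"),
        demo_row("6", sex="UNK"),
    ]
    drug = [
        {"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "APALUTAMIDE"},
        {"primaryid": "2", "drug_seq": "1", "role_cod": "PS", "drugname": "Erleada"},
        {"primaryid": "3", "drug_seq": "1", "role_cod": "PS", "drugname": "APALUTAMIDE"},
        {"primaryid": "4", "drug_seq": "1", "role_cod": "C", "drugname": "APALUTAMIDE"},
        {"primaryid": "5", "drug_seq": "1", "role_cod": "PS", "drugname": "METFORMIN"},
        {"primaryid": "6", "drug_seq": "1", "role_cod": "PS", "drugname": "METFORMIN"},
    ]
    indi = [
        {"primaryid": "1", "indi_drug_seq": "1", "indi_pt": "Prostate cancer"},
        {"primaryid": "2", "indi_drug_seq": "1", "indi_pt": "PROSTATE CANCER"},
        {"primaryid": "3", "indi_drug_seq": "1", "indi_pt": "PROSTATE CANCER"},
        {"primaryid": "5", "indi_drug_seq": "1", "indi_pt": "DIABETES MELLITUS"},
    ]
    reac = [
        {"primaryid": "1", "pt": "STEVENS-JOHNSON SYNDROME"},
        {"primaryid": "2", "pt": "NAUSEA"},
        {"primaryid": "3", "pt": "TOXIC EPIDERMAL NECROLYSIS"},
        {"primaryid": "4", "pt": "RASH"},
        {"primaryid": "5", "pt": "NAUSEA"},
        {"primaryid": "6", "pt": "STEVENS-JOHNSON SYNDROME"},
    ]
    ther = [
        {"primaryid": "1", "dsg_drug_seq": "1", "start_dt": "20230101"},
    ]
    return make_dataset(demo, drug, reac, indi, ther)
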