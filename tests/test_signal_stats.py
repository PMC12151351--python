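"""The four disproportionality estimators, their intervals, criteria and identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency, hypergeom

from pvsignal.signal import (
    ContingencyTable,
    DisproportionalityModel,
    bcpnn_ic,
    contingency,
    ebgm,
    evaluate_signal,
    pearson_chi2,
    prr,
    reconstruct_cells,
    ror,
)

# frozen values from an independent arbitrary-precision evaluation (sympy,
# 30 significant digits) of the defining formulas on (a,b,c,d)=(10,90,100,9900)
REF = {
    "ror": 11.0,
    "ror_lo": 5.55951492889462578907510652656,
    "ror_hi": 21.7644887274469293588686141785,
    "prr": 10.0,
    "chi2": 74.4471744471744471744471744472,
    "ic": 3.19877986411449748097229606676,
    "ic025": 2.19421598020705589272946977625,
    "ebgm": 9.18181818181818181818181818182,
    "ebgm05": 4.64058684147402648509575007589,
}

T = ContingencyTable(10, 90, 100, 9900)
BALANCED = ContingencyTable(25, 25, 25, 25)

tables = st.builds(
    ContingencyTable,
    a=st.integers(1, 500),
    b=st.integers(1, 5000),
    c=st.integers(1, 5000),
    d=st.integers(1, 100000),
)


class TestPointEstimates:
    def test_reference_table(self):
        r = ror(T)
        assert r.ror == pytest.approx(REF["ror"], rel=1e-12)
        assert r.lo95 == pytest.approx(REF["ror_lo"], rel=1e-12)
        assert r.hi95 == pytest.approx(REF["ror_hi"], rel=1e-12)
        p = prr(T)
        assert p.prr == pytest.approx(REF["prr"], rel=1e-12)
        assert p.chi2 == pytest.approx(REF["chi2"], rel=1e-12)
        i = bcpnn_ic(T)
        assert i.ic == pytest.approx(REF["ic"], rel=1e-12)
        assert i.ic025 == pytest.approx(REF["ic025"], rel=1e-12)
        e = ebgm(T)
        assert e.ebgm == pytest.approx(REF["ebgm"], rel=1e-12)
        assert e.ebgm05 == pytest.approx(REF["ebgm05"], rel=1e-12)

    def test_balanced_table_is_null(self):
        assert ror(BALANCED).ror == 1.0
        assert prr(BALANCED) == (1.0, 0.0)
        assert bcpnn_ic(BALANCED).ic == 0.0
        assert ebgm(BALANCED).ebgm == 1.0
        assert evaluate_signal(BALANCED).n_positive == 0

    def test_zero_a_gives_zero_ror_undefined_ci(self):
        r = ror(ContingencyTable(0, 5, 5, 5))
        assert r.ror == 0.0
        assert math.isnan(r.lo95) and math.isnan(r.hi95)

    def test_prr_with_zero_b_and_d(self):
        p = prr(ContingencyTable(3, 0, 1, 0))
        assert p.prr == pytest.approx(1.0)

    def test_undefined_marks_on_degenerate_tables(self):
        only_target = ContingencyTable(3, 7, 0, 0)  # dataset with only the target drug
        res = evaluate_signal(only_target)
        assert math.isnan(res.ror) and math.isnan(res.prr)
        assert res.n_positive == 0
        assert math.isnan(res.ic025)

    def test_haldane_correction_defines_everything(self):
        res = evaluate_signal(ContingencyTable(3, 0, 0, 10), continuity="haldane")
        assert np.isfinite([res.ror, res.prr, res.ic, res.ebgm]).all()


class TestChiSquared:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_pearson(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            t = ContingencyTable(*(int(v) for v in rng.integers(1, 400, 4)))
            expected = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=False)[0]
            assert pearson_chi2(t) == pytest.approx(expected, rel=1e-10)
            yates = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=True)[0]
            assert pearson_chi2(t, yates=True) == pytest.approx(yates, rel=1e-10)


class TestIdentitiesAndProperties:
    @given(tables)
    @settings(max_examples=300, derandomize=True)
    def test_ic_equals_log2_ebgm(self, t):
        i = bcpnn_ic(t)
        e = ebgm(t)
        assert i.ic == pytest.approx(math.log2(e.ebgm), rel=1e-12)
        assert e.ebgm == pytest.approx(2.0 ** i.ic, rel=1e-12)

    @given(tables)
    @settings(max_examples=300, derandomize=True)
    def test_interval_ordering(self, t):
        res = evaluate_signal(t)
        assert res.ror_lo95 <= res.ror <= res.ror_hi95
        assert res.ic025 <= res.ic
        assert res.ebgm05 <= res.ebgm

    def test_estimates_strictly_increase_in_a(self):
        b, c, d = 50, 80, 4000
        prev = None
        for a in range(1, 40):
            t = ContingencyTable(a, b, c, d)
            cur = (ror(t).ror, prr(t).prr, bcpnn_ic(t).ic, ebgm(t).ebgm)
            if prev is not None:
                assert all(x > y for x, y in zip(cur, prev))
            prev = cur

    @given(
        st.integers(1, 50), st.integers(1, 50),
        st.integers(100, 1000), st.integers(100, 1000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_ror_approaches_prr_for_rare_events(self, a, c, bf, df):
        # with b >= 100a and d >= 100c the odds ratio and the proportional
        # reporting ratio coincide to a few percent
        t = ContingencyTable(a, 100 * a * bf // 100, c, 100 * c * df // 100)
        if t.b < 100 * a or t.d < 100 * c:
            return
        r, p = ror(t).ror, prr(t).prr
        assert abs(r - p) / p < 0.025

    def test_bcpnn_flags_no_more_than_ror_under_independence(self):
        # margins fixed, a hypergeometric: the Bayesian bound flags less
        # often than the frequentist interval at small expected a
        rng = np.random.default_rng(2024)
        N, row1, col1 = 5000, 120, 60
        draws = hypergeom(N, col1, row1).rvs(size=3000, random_state=rng)
        flags_ror = flags_ic = 0
        for a in draws:
            a = int(a)
            t = ContingencyTable(a, row1 - a, col1 - a, N - row1 - col1 + a)
            res = evaluate_signal(t)
            flags_ror += res.ror_positive
            flags_ic += res.bcpnn_positive
        assert flags_ic <= flags_ror


class TestCriteria:
    def test_reference_table_flags(self):
        res = evaluate_signal(T)
        assert res.ror_positive and res.prr_positive and res.mgps_positive
        assert res.bcpnn_positive  # ic025 = 2.19 > 0

    def test_a_below_three_gates_frequentist_flags(self):
        t = ContingencyTable(2, 2, 2, 10000)  # enormous ratio, tiny count
        res = evaluate_signal(t)
        assert not res.ror_positive and not res.prr_positive
        assert res.ror > 100  # the gate, not the estimate, suppressed it

    def test_flags_derivable_from_numeric_fields(self):
        for cells in [(10, 90, 100, 9900), (25, 25, 25, 25), (3, 1, 1, 3), (5, 500, 500, 50000)]:
            res = evaluate_signal(ContingencyTable(*cells))
            a = res.table.a
            assert res.ror_positive == (a >= 3 and res.ror_lo95 > 1)
            assert res.prr_positive == (a >= 3 and res.prr >= 2 and res.chi2 >= 4)
            assert res.bcpnn_positive == (res.ic025 > 0)
            assert res.mgps_positive == (res.ebgm05 > 2)


class TestBateVariance:
    def test_bayesian_bound_is_finite_and_below_ic(self):
        i = bcpnn_ic(T, variance="bate")
        assert np.isfinite(i.ic025)
        assert i.ic025 < i.ic
        # posterior mean shrinks toward 0 relative to the observed IC
        assert abs(i.e_ic) < abs(i.ic)

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValueError):
            bcpnn_ic(T, variance="bogus")


class TestContingencyConstruction:
    def test_hand_enumerated_pairs(self):
        # target drug: 3 pairs, 1 of them an event; others: 7 pairs, 2 events
        pairs = pd.DataFrame({
            "primaryid": [str(i) for i in range(10)],
            "drugname": ["APALUTAMIDE"] * 3 + ["OTHER"] * 7,
            "pt": (
                ["STEVENS-JOHNSON SYNDROME", "NAUSEA", "RASH"]
                + ["TOXIC EPIDERMAL NECROLYSIS", "STEVENS-JOHNSON SYNDROME"]
                + ["NAUSEA"] * 5
            ),
        })
        t = contingency(pairs, ["APALUTAMIDE"], ["STEVENS-JOHNSON SYNDROME", "TOXIC EPIDERMAL NECROLYSIS"])
        assert (t.a, t.b, t.c, t.d) == (1, 2, 2, 5)
        assert t.n == 10

    def test_empty_scope_is_hard_error(self):
        with pytest.raises(ValueError):
            contingency(pd.DataFrame(columns=["primaryid", "drugname", "pt"]), ["X"], ["Y"])

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestModelResults:
    def test_from_counts_summary_and_frame(self):
        counts = pd.DataFrame(
            {"a": [10, 25], "b": [90, 25], "c": [100, 25], "d": [9900, 25]},
            index=["drugx", "drugy"],
        )
        res = DisproportionalityModel.from_counts(counts).fit()
        frame = res.frame
        assert frame.loc["drugx", "ror"] == pytest.approx(11.0)
        assert frame.loc["drugy", "ic"] == 0.0
        assert "drugx" in res.summary()
        rounded = res.rounded_frame()
        assert rounded.loc["drugx", "ror"] == 11.0
        # small-magnitude statistics get a companion 1-decimal rendering
        assert rounded.loc["drugx", "ic_1dp"] == 3.2
        assert np.isnan(rounded.loc["drugx", "ror_1dp"])  # |ROR| >= 10

    def test_undefined_cells_written_empty(self, tmp_path):
        counts = pd.DataFrame({"a": [0], "b": [0], "c": [5], "d": [5]}, index=["ghost"])
        res = DisproportionalityModel.from_counts(counts).fit()
        path = tmp_path / "signals.csv"
        res.to_csv(path)
        row = path.read_text().splitlines()[1]
        assert ",,"  in row  # NaNs render as empty cells, not sentinels


def test_reconstruct_cells_recovers_consistent_table():
    truth = ContingencyTable(77, 2100, 310, 98000)
    r, p, e = ror(truth), prr(truth), ebgm(truth)
    found = reconstruct_cells(
        77, round(r.ror, 2), round(p.prr, 2), round(e.ebgm, 2),
        chi2_printed=round(p.chi2, 2),
    )
    assert found, "no integer cells consistent with the rounded statistics"
    for t in found:
        assert round(ror(t).ror, 2) == round(r.ror, 2)
        assert round(prr(t).chi2, 2) == round(p.chi2, 2)
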