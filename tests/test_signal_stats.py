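"""Disproportionality statistics: values, invariants, criteria, ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faers_signals.signal_stats import (
    ContingencyTable,
    FOREST_COLUMNS,
    build_tables,
    classify_signal,
    compute_signals,
    ebgm_stat,
    export_forest,
    ic_stat,
    prr_stat,
    rank_results,
    ror_stat,
)
from oracle_stats import oracle_ebgm, oracle_ic, oracle_prr, oracle_ror

T_REF = ContingencyTable(5, 95, 50, 9850)
T_SYM = ContingencyTable(10, 10, 10, 10)

cells = st.integers(min_value=1, max_value=5000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


def frame_of(pts_sets):
    return pd.DataFrame({"pts": [frozenset(s) for s in pts_sets]})


class TestBuildTables:
    def test_report_level_enumeration(self):
        cohort = frame_of([{"X", "Y"}, {"X"}])
        background = frame_of([{"Y"}])
        tabs = dict(build_tables(cohort, background))
        assert tabs["X"] == ContingencyTable(2, 0, 0, 1)
        assert tabs["Y"] == ContingencyTable(1, 1, 1, 0)

    def test_background_only_pt_emits_no_table(self):
        tabs = dict(build_tables(frame_of([{"X"}]), frame_of([{"Z"}])))
        assert "Z" not in tabs

    def test_empty_background_degenerate(self):
        tabs = dict(build_tables(frame_of([{"X"}]), frame_of([])))
        assert tabs["X"] == ContingencyTable(1, 0, 0, 0)
        assert np.isnan(ror_stat(tabs["X"])[0])


class TestPointValues:
    def test_symmetric_table_all_unity(self):
        assert ror_stat(T_SYM)[0] == pytest.approx(1.0)
        prr, _, _, chi2 = prr_stat(T_SYM)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)
        assert ic_stat(T_SYM)[0] == pytest.approx(0.0)
        assert ebgm_stat(T_SYM)[0] == pytest.approx(1.0)

    def test_reference_table_ror(self):
        ror, lo, hi = ror_stat(T_REF)
        assert ror == pytest.approx(10.37, abs=0.01)
        assert lo == pytest.approx(4.04, abs=0.01)
        assert hi == pytest.approx(26.58, abs=0.01)

    def test_reference_table_prr_chi2(self):
        prr, _, _, chi2 = prr_stat(T_REF)
        assert prr == pytest.approx(9.90, abs=0.01)
        assert chi2 == pytest.approx(36.57, abs=0.01)

    def test_reference_table_ic(self):
        ic, _ = ic_stat(T_REF)
        assert ic == pytest.approx(3.18, abs=0.01)

    def test_reference_table_ebgm_and_lower_bound(self):
        ebgm, ebgm05, _ = ebgm_stat(T_REF)
        assert ebgm == pytest.approx(9.09, abs=0.01)
        assert ebgm05 == pytest.approx(3.55, abs=0.01)

    def test_zero_cell_undefined_without_correction(self):
        assert all(np.isnan(v) for v in ror_stat(ContingencyTable(3, 0, 5, 100)))
        assert all(np.isnan(v) for v in prr_stat(ContingencyTable(5, 95, 0, 9900)))


class TestInvariants:
    @settings(max_examples=300, derandomize=True)
    @given(tables)
    def test_oracle_equivalence(self, t):
        assert ror_stat(t) == pytest.approx(oracle_ror(*t), rel=1e-9)
        assert prr_stat(t) == pytest.approx(oracle_prr(*t), rel=1e-9)
        assert ic_stat(t) == pytest.approx(oracle_ic(*t), rel=1e-9)
        assert ebgm_stat(t) == pytest.approx(oracle_ebgm(*t), rel=1e-9)

    @settings(max_examples=300, derandomize=True)
    @given(tables)
    def test_sign_consistency(self, t):
        a, b, c, d = t
        ror = ror_stat(t)[0]
        prr = prr_stat(t)[0]
        ic = ic_stat(t)[0]
        ebgm = ebgm_stat(t)[0]
        if a * d > b * c:
            assert ror > 1 and prr > 1 and ebgm > 1 and ic > 0
        elif a * d < b * c:
            assert ror < 1 and prr < 1 and ebgm < 1 and ic < 0

    @settings(max_examples=300, derandomize=True)
    @given(tables)
    def test_ordering_when_disproportionate(self, t):
        a, b, c, d = t
        if a * d > b * c:
            assert ror_stat(t)[0] > prr_stat(t)[0] > ebgm_stat(t)[0] > 1

    @settings(max_examples=200, derandomize=True)
    @given(tables)
    def test_ic_is_log2_of_ebgm(self, t):
        assert ic_stat(t)[0] == pytest.approx(math.log2(ebgm_stat(t)[0]), rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(tables, st.integers(min_value=1, max_value=50))
    def test_more_cases_strictly_increase_ror_and_prr(self, t, bump):
        t2 = ContingencyTable(t.a + bump, t.b, t.c, t.d)
        assert ror_stat(t2)[0] > ror_stat(t)[0]
        assert prr_stat(t2)[0] > prr_stat(t)[0]

    def test_relative_reporting_ratio_not_monotone_in_a(self):
        # EBGM = a(a+b+c+d)/((a+b)(a+c)) tends to 1 as a grows, so unlike
        # ROR/PRR it is not monotone in a: same value at a=1 and a=5 here.
        assert ebgm_stat(ContingencyTable(1, 1, 1, 2))[0] == pytest.approx(1.25)
        assert ebgm_stat(ContingencyTable(5, 1, 1, 2))[0] == pytest.approx(1.25)
        assert ebgm_stat(ContingencyTable(50, 1, 1, 2))[0] < 1.25

    def test_bcpnn_dialect_lower_bound_below_point_estimate(self):
        ic, ic025 = ic_stat(T_REF, dialect="bcpnn-approx")
        assert ic025 < ic
        # strong signal at this sample size stays positive under both dialects
        assert ic025 > 0
        assert ic_stat(T_REF, dialect="log2-transform")[1] > 0

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ValueError, match="dialect"):
            ic_stat(T_REF, dialect="bogus")


class TestClassification:
    @staticmethod
    def result_row(t, dialect="log2-transform"):
        ror, ror_lo, ror_hi = ror_stat(t)
        prr, prr_lo, prr_hi, chi2 = prr_stat(t)
        ic, ic025 = ic_stat(t, dialect)
        ebgm, ebgm05, _ = ebgm_stat(t)
        return {"n": t.a, "ror": ror, "ror_lo": ror_lo, "prr": prr,
                "prr_lo": prr_lo, "chi2": chi2, "ic": ic, "ic025": ic025,
                "ebgm": ebgm, "ebgm05": ebgm05}

    def test_reference_table_flags_all_positive(self):
        flags = classify_signal(self.result_row(T_REF))
        assert flags == {"ror_pos": True, "prr_pos": True,
                         "bcpnn_pos": True, "mgps_pos": True}

    def test_symmetric_table_flags_all_negative(self):
        assert not any(classify_signal(self.result_row(T_SYM)).values())

    def test_fewer_than_three_cases_never_signals_ror(self):
        t = ContingencyTable(2, 5, 1, 5000)  # huge ror, tiny a
        row = self.result_row(t)
        assert row["ror"] > 100
        assert not classify_signal(row)["ror_pos"]

    def test_undefined_statistics_flag_false(self):
        # b = 0 leaves the odds ratio undefined (PRR is still defined there)
        assert not classify_signal(self.result_row(ContingencyTable(5, 0, 3, 100)))["ror_pos"]
        # c = 0 leaves both ratios against the background undefined
        flags = classify_signal(self.result_row(ContingencyTable(5, 95, 0, 9900)))
        assert not flags["ror_pos"] and not flags["prr_pos"]


class TestRanking:
    @staticmethod
    def results(rows):
        df = pd.DataFrame(rows)
        for col in FOREST_COLUMNS:
            if col not in df.columns:
                df[col] = 1.0 if col not in ("pt", "soc") else "x"
        return df

    def test_frequency_mode_sorts_by_count(self):
        df = self.results([
            {"pt": "B", "n": 135, "ror": 2.17, "ror_pos": True},
            {"pt": "A", "n": 300, "ror": 9.55, "ror_pos": True},
            {"pt": "C", "n": 69, "ror": 2.03, "ror_pos": True},
        ])
        assert rank_results(df, "frequency", 30)["pt"].tolist() == ["A", "B", "C"]

    def test_strength_mode_sorts_by_ror(self):
        df = self.results([
            {"pt": "A", "n": 300, "ror": 9.55, "ror_pos": True},
            {"pt": "B", "n": 12, "ror": 45.52, "ror_pos": True},
            {"pt": "C", "n": 26, "ror": 24.69, "ror_pos": True},
        ])
        assert rank_results(df, "strength", 30)["pt"].tolist() == ["B", "C", "A"]

    def test_only_ror_positive_pts_ranked(self):
        df = self.results([
            {"pt": "A", "n": 500, "ror": 0.9, "ror_pos": False},
            {"pt": "B", "n": 5, "ror": 3.0, "ror_pos": True},
        ])
        assert rank_results(df, "frequency", 30)["pt"].tolist() == ["B"]

    def test_k_larger_than_list_returns_all(self):
        df = self.results([{"pt": "A", "n": 5, "ror": 2.0, "ror_pos": True}])
        assert len(rank_results(df, "frequency", 30)) == 1

    def test_equal_n_and_ror_tie_breaks_alphabetically(self):
        rows = [{"pt": p, "n": 10, "ror": 2.0, "ror_pos": True} for p in "ZQM"]
        for perm in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
            df = self.results([rows[i] for i in perm])
            assert rank_results(df, "frequency", 3)["pt"].tolist() == ["M", "Q", "Z"]


class TestExport:
    def test_forest_file_columns_and_round_trip(self, tmp_path):
        cohort = frame_of([{"X"}] * 8 + [set()] * 92)
        background = frame_of([{"X"}] * 10 + [set()] * 990)
        # pts must be non-empty in real cohorts; pad with a second PT
        cohort["pts"] = cohort["pts"].apply(lambda s: s | {"pad"})
        background["pts"] = background["pts"].apply(lambda s: s | {"pad"})
        results = compute_signals(cohort, background)
        path = export_forest(results, tmp_path / "forest.tsv")
        back = pd.read_csv(path, sep="\t")
        assert back.columns.tolist() == FOREST_COLUMNS
        x = back.set_index("pt").loc["X"]
        want = results.set_index("pt").loc["X"]
        assert x["ror"] == pytest.approx(want["ror"], abs=5e-5)

    def test_empty_export_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_forest(pd.DataFrame(), tmp_path / "x.tsv")
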