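"""Cohort filters, PT→SOC mapping, and demographic summaries."""

import numpy as np
import pandas as pd
import pytest

from faers_signals.cohort_builder import (
    CohortConfig,
    EmptyCohortError,
    SocMap,
    build_cohort,
    map_pt_to_soc,
    primary_outcome,
    is_serious,
    reporter_label,
    summarize_demographics,
    summarize_provenance,
)
from conftest import make_corpus

CFG = CohortConfig(date_window=("2021Q1", "2021Q4"))


def target_report(**kw):
    base = dict(
        fda_dt="2021-03-15",
        drugs=[{"name": "KEYTRUDA (pembrolizumab)", "role": "PS",
                "indi": "Endometrial cancer"}],
        pts=["Nausea"],
    )
    base.update(kw)
    return base


def other_report(**kw):
    base = dict(fda_dt="2021-03-15",
                drugs=[{"name": "METFORMIN", "role": "PS", "indi": "Diabetes"}],
                pts=["Fatigue"])
    base.update(kw)
    return base


class TestBuildCohort:
    def test_brand_name_primary_suspect_with_whitelisted_indication_included(self):
        corpus = make_corpus([target_report(primaryid=1), other_report(primaryid=2)])
        cohort, background, _ = build_cohort(corpus, CFG)
        assert cohort["primaryid"].tolist() == [1]
        assert background["primaryid"].tolist() == [2]

    def test_secondary_suspect_only_excluded_by_default_role(self):
        corpus = make_corpus([
            target_report(primaryid=1,
                          drugs=[{"name": "PEMBROLIZUMAB", "role": "SS",
                                  "indi": "Endometrial cancer"}]),
            target_report(primaryid=2),
        ])
        cohort, _, _ = build_cohort(corpus, CFG)
        assert cohort["primaryid"].tolist() == [2]

    def test_ambiguous_indication_excluded(self):
        corpus = make_corpus([
            target_report(primaryid=1,
                          drugs=[{"name": "PEMBROLIZUMAB", "role": "PS",
                                  "indi": "Malignant neoplasm"}]),
            target_report(primaryid=2),
        ])
        cohort, background, diag = build_cohort(corpus, CFG)
        assert cohort["primaryid"].tolist() == [2]
        assert 1 in background["primaryid"].tolist()
        assert diag["indication_missing_or_ambiguous"] >= 1

    def test_indication_must_belong_to_matched_drug_row(self):
        # whitelisted indication attached to a different drug's sequence
        corpus = make_corpus([{
            "primaryid": 1, "fda_dt": "2021-03-15",
            "drugs": [{"seq": 1, "name": "PEMBROLIZUMAB", "role": "PS",
                       "indi": "Melanoma"},
                      {"seq": 2, "name": "CARBOPLATIN", "role": "C",
                       "indi": "Endometrial cancer"}],
            "pts": ["Nausea"],
        }, target_report(primaryid=2)])
        cohort, _, _ = build_cohort(corpus, CFG)
        assert cohort["primaryid"].tolist() == [2]

    def test_out_of_window_report_not_in_cohort_or_background(self):
        corpus = make_corpus([target_report(primaryid=1),
                              target_report(primaryid=2, fda_dt="2015-06-01")])
        cohort, background, _ = build_cohort(corpus, CFG)
        assert set(cohort["primaryid"]) | set(background["primaryid"]) == {1}

    def test_cohort_background_partition_of_window(self):
        reports = [target_report(primaryid=i) for i in range(5)]
        reports += [other_report(primaryid=10 + i) for i in range(7)]
        corpus = make_corpus(reports)
        cohort, background, _ = build_cohort(corpus, CFG)
        in_window = set(corpus["demo"]["primaryid"])
        assert set(cohort["primaryid"]) & set(background["primaryid"]) == set()
        assert set(cohort["primaryid"]) | set(background["primaryid"]) == in_window

    def test_whitelist_growth_never_shrinks_cohort(self):
        corpus = make_corpus([
            target_report(primaryid=1),
            target_report(primaryid=2,
                          drugs=[{"name": "PEMBROLIZUMAB", "role": "PS",
                                  "indi": "Uterine cancer"}]),
        ])
        small = CohortConfig(indication_whitelist=("Endometrial cancer",),
                             date_window=("2021Q1", "2021Q4"))
        big = CohortConfig(
            indication_whitelist=("Endometrial cancer", "Uterine cancer"),
            date_window=("2021Q1", "2021Q4"))
        n_small = len(build_cohort(corpus, small)[0])
        n_big = len(build_cohort(corpus, big)[0])
        assert n_big >= n_small

    def test_background_scope_restricted_to_whitelist_indications(self):
        corpus = make_corpus([
            target_report(primaryid=1),
            other_report(primaryid=2),
            other_report(primaryid=3,
                         drugs=[{"name": "NIVOLUMAB", "role": "PS",
                                 "indi": "Endometrial cancer"}]),
        ])
        cfg = CohortConfig(date_window=("2021Q1", "2021Q4"),
                           background_scope="whitelist_indication")
        _, background, _ = build_cohort(corpus, cfg)
        assert background["primaryid"].tolist() == [3]

    def test_empty_cohort_fatal_with_diagnostics(self):
        corpus = make_corpus([other_report(primaryid=1)])
        with pytest.raises(EmptyCohortError) as exc:
            build_cohort(corpus, CFG)
        assert exc.value.diagnostics["drug_role_match"] == 0

    def test_earliest_therapy_start_of_matched_drug(self):
        corpus = make_corpus([target_report(
            primaryid=1,
            ther=[(1, "2021-02-01"), (1, "2021-01-01")])])
        cohort, _, _ = build_cohort(corpus, CFG)
        assert cohort["therapy_start_dt"].iloc[0] == pd.Timestamp("2021-01-01")


class TestDemographics:
    def test_age_bins_quarter_each(self):
        reports = [target_report(primaryid=i, age=a)
                   for i, a in enumerate([17, 30, 70])]
        reports.append(target_report(primaryid=3))  # age missing
        cohort, _, _ = build_cohort(make_corpus(reports), CFG)
        demo = summarize_demographics(cohort)
        age = demo[demo["characteristic"] == "Age (years)"].set_index("classification")
        for label in ("<18 years", "18~64.9", "65~85", "Missing"):
            assert age.loc[label, "n"] == 1
            assert age.loc[label, "pct"] == pytest.approx(25.0)

    def test_age_bin_edges(self):
        # 65 and 85 belong to the 65~85 bin; 85.5 is >85; 64.95 is 18~64.9
        reports = [target_report(primaryid=i, age=a)
                   for i, a in enumerate([65, 85, 85.5, 64.95])]
        cohort, _, _ = build_cohort(make_corpus(reports), CFG)
        demo = summarize_demographics(cohort)
        age = demo[demo["characteristic"] == "Age (years)"].set_index("classification")
        assert age.loc["65~85", "n"] == 2
        assert age.loc[">85", "n"] == 1
        assert age.loc["18~64.9", "n"] == 1

    def test_multi_outcome_report_counted_once_as_death(self):
        assert primary_outcome(frozenset({"HO", "DE"})) == "Death"

    def test_other_only_outcome_is_non_serious(self):
        assert not is_serious(frozenset({"OT"}))
        assert not is_serious(frozenset())
        assert is_serious(frozenset({"HO"}))

    def test_percentages_sum_to_100_per_characteristic(self):
        reports = [target_report(primaryid=i, age=float(20 + i),
                                 outcomes=["HO"] if i % 2 else ["OT"])
                   for i in range(7)]
        cohort, _, _ = build_cohort(make_corpus(reports), CFG)
        demo = summarize_demographics(cohort)
        sums = demo.groupby("characteristic")["pct"].sum()
        assert np.allclose(sums, 100.0, atol=0.01)

    def test_weight_converted_before_binning(self):
        # 220 lbs = 99.8 kg -> 50~100 bin
        cohort, _, _ = build_cohort(make_corpus([
            target_report(primaryid=1, wt=220, wt_cod="LBS")]), CFG)
        demo = summarize_demographics(cohort)
        wt = demo[demo["characteristic"] == "Weight (kg)"].set_index("classification")
        assert wt.loc["50~100 kg", "n"] == 1


class TestProvenance:
    def test_all_us_cohort(self):
        cohort, _, _ = build_cohort(make_corpus(
            [target_report(primaryid=i) for i in range(3)]), CFG)
        by_country, by_year, _ = summarize_provenance(cohort)
        assert by_country["US"] == 3
        assert by_year[2021] == 3

    @pytest.mark.parametrize("code,label", [
        ("MD", "Physician"), ("CN", "Consumer"), ("HP", "Health Professional"),
        ("PH", "Pharmacist"), ("LW", "Missing"), (None, "Missing"),
    ])
    def test_reporter_mapping(self, code, label):
        assert reporter_label(code if code is not None else np.nan) == label


class TestSocMap:
    def test_known_pt_maps_to_soc(self, soc_map):
        assert map_pt_to_soc("Arthralgia", soc_map) == \
            "Musculoskeletal and connective tissue disorders"

    def test_unknown_pt_falls_back_to_unmapped(self, soc_map):
        assert map_pt_to_soc("Completely novel event", soc_map) == "Unmapped"

    def test_case_and_whitespace_insensitive(self, soc_map):
        assert map_pt_to_soc("  arthralgia ", soc_map) == \
            map_pt_to_soc("Arthralgia", soc_map)

    def test_load_from_delimited_file(self, tmp_path):
        path = tmp_path / "pt2soc.tsv"
        path.write_text("pt\tsoc\nArthralgia\tMusculoskeletal and connective tissue disorders\n")
        m = SocMap.from_file(path)
        assert m.lookup("Arthralgia") == "Musculoskeletal and connective tissue disorders"
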