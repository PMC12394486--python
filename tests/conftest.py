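"""Shared fixtures: hand-built corpora in the post-read schema."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from faers_signals.cohort_builder import SocMap


def _date(value) -> pd.Timestamp:
    return pd.NaT if value is None else pd.Timestamp(str(value))


def make_corpus(reports: list[dict]) -> dict:
    """Build an in-memory corpus (post-read schema) from report dicts.

    Each report dict supports keys: primaryid, caseid, fda_dt, event_dt,
    age, age_cod, wt, wt_cod, sex, occ_cod, country, drugs (list of dicts
    with seq/role/name/prod_ai/route/indi), pts, outcomes,
    ther (list of (seq, start_dt)).
    """
    demo_rows, drug_rows, reac_rows, indi_rows, outc_rows, ther_rows = [], [], [], [], [], []
    for i, rep in enumerate(reports):
        pid = rep.get("primaryid", 100 + i)
        demo_rows.append({
            "primaryid": pid,
            "caseid": rep.get("caseid", pid),
            "fda_dt": _date(rep.get("fda_dt", "2021-03-15")),
            "event_dt": _date(rep.get("event_dt")),
            "age": rep.get("age", np.nan),
            "age_cod": rep.get("age_cod", "YR" if rep.get("age") is not None else np.nan),
            "wt": rep.get("wt", np.nan),
            "wt_cod": rep.get("wt_cod", "KG" if rep.get("wt") is not None else np.nan),
            "sex": rep.get("sex", "F"),
            "occ_cod": rep.get("occ_cod", np.nan),
            "occr_country": rep.get("country", "US"),
            "fda_dt_imputed": False,
            "fda_dt_year": pd.NA,
            "event_dt_imputed": rep.get("event_dt_imputed", False),
            "event_dt_year": pd.NA,
        })
        for drug in rep.get("drugs", []):
            drug_rows.append({
                "primaryid": pid,
                "drug_seq": drug.get("seq", 1),
                "role_cod": drug.get("role", "PS"),
                "drugname": drug.get("name", "PEMBROLIZUMAB"),
                "prod_ai": drug.get("prod_ai", np.nan),
                "route": drug.get("route", np.nan),
            })
            if "indi" in drug:
                indi_rows.append({"primaryid": pid,
                                  "indi_drug_seq": drug.get("seq", 1),
                                  "indi_pt": drug["indi"]})
        for pt in rep.get("pts", []):
            reac_rows.append({"primaryid": pid, "pt": pt})
        for code in rep.get("outcomes", []):
            outc_rows.append({"primaryid": pid, "outc_cod": code})
        for seq, start in rep.get("ther", []):
            ther_rows.append({"primaryid": pid, "dsg_drug_seq": seq,
                              "start_dt": _date(start), "end_dt": pd.NaT,
                              "start_dt_imputed": rep.get("start_dt_imputed", False),
                              "start_dt_year": pd.NA,
                              "end_dt_imputed": False, "end_dt_year": pd.NA})

    def frame(rows, cols):
        df = pd.DataFrame(rows, columns=cols)
        for col in cols:
            if col.endswith("_dt"):
                df[col] = pd.to_datetime(df[col])
        return df

    return {
        "demo": frame(demo_rows, ["primaryid", "caseid", "fda_dt", "event_dt",
                                  "age", "age_cod", "wt", "wt_cod", "sex",
                                  "occ_cod", "occr_country", "fda_dt_imputed",
                                  "fda_dt_year", "event_dt_imputed", "event_dt_year"]),
        "drug": frame(drug_rows, ["primaryid", "drug_seq", "role_cod",
                                  "drugname", "prod_ai", "route"]),
        "reac": frame(reac_rows, ["primaryid", "pt"]),
        "indi": frame(indi_rows, ["primaryid", "indi_drug_seq", "indi_pt"]),
        "outc": frame(outc_rows, ["primaryid", "outc_cod"]),
        "ther": frame(ther_rows, ["primaryid", "dsg_drug_seq", "start_dt", "end_dt",
                                  "start_dt_imputed", "start_dt_year",
                                  "end_dt_imputed", "end_dt_year"]),
        "deleted_case_ids": set(),
    }


@pytest.fixture
def soc_map() -> SocMap:
    return SocMap({
        "Arthralgia": "Musculoskeletal and connective tissue disorders",
        "Immune-mediated hypothyroidism": "Endocrine disorders",
        "Nausea": "Gastrointestinal disorders",
        "Fatigue": "General disorders and administration site conditions",
    })
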