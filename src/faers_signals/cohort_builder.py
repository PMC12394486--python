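"""Cohort restriction, PT→SOC mapping, and demographic summaries.

The analysis cohort is the set of deduplicated reports in which the drug
of interest appears with a qualifying role code (primary suspect by
default) *and* that same drug row carries a whitelisted indication term —
the indication is joined on (PRIMARYID, drug sequence) so it must belong
to the matched drug, not merely co-occur in the report. Reports whose
matched drug has a missing or ambiguous indication ("cancer", "malignant
neoplasm", blank) are excluded from the cohort. Every other retained
report in the date window forms the disproportionality comparator
("background"); an alternative mode restricts the comparator to
whitelist-indication reports.

MedDRA itself is licensed and not shipped: the PT→SOC mapping is a
user-supplied two-column delimited file, with unmapped terms grouped
under the fallback SOC "Unmapped".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from faers_signals.faers_io import (
    normalize_age_series,
    normalize_weight_series,
    quarter_bounds,
)

logger = logging.getLogger(__name__)

DEFAULT_DRUG_PATTERNS = ("PEMBROLIZUMAB", "KEYTRUDA")

DEFAULT_INDICATION_WHITELIST = (
    "Endometrial cancer",
    "Endometrial carcinoma",
    "Endometrioid adenocarcinoma",
    "Uterine endometrioid adenocarcinoma",
    "Uterine cancer",
    "Endometrial neoplasm",
)

AMBIGUOUS_INDICATIONS = frozenset({"cancer", "malignant neoplasm"})

#: one outcome category per report: most severe first
OUTCOME_PRECEDENCE = ("DE", "LT", "DS", "HO", "CA", "RI", "OT")

OUTCOME_LABELS = {
    "DE": "Death", "LT": "Life-Threatening", "DS": "Disability",
    "HO": "Hospitalization", "CA": "Congenital Anomaly",
    "RI": "Required Intervention", "OT": "Other",
}

SERIOUS_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI"})

REPORTER_LABELS = {
    "CN": "Consumer", "HP": "Health Professional",
    "PH": "Pharmacist", "MD": "Physician",
}

ROUTE_PRECEDENCE = ("INTRAVENOUS", "PARENTERAL", "SUBCUTANEOUS", "ORAL")


class EmptyCohortError(RuntimeError):
    """No report survived the cohort filters; carries per-filter diagnostics."""

    def __init__(self, diagnostics: dict[str, int]):
        self.diagnostics = diagnostics
        super().__init__(f"empty cohort; filter diagnostics: {diagnostics}")


@dataclass
class CohortConfig:
    drug_name_patterns: tuple[str, ...] = DEFAULT_DRUG_PATTERNS
    role_codes: frozenset[str] = frozenset({"PS"})
    indication_whitelist: tuple[str, ...] = DEFAULT_INDICATION_WHITELIST
    date_window: tuple[str, str] = ("2016Q1", "2025Q1")
    sensitivity_window: tuple[str, str] | None = ("2021Q1", "2025Q1")
    background_scope: str = "full"  # or "whitelist_indication"

    def __post_init__(self) -> None:
        if not self.indication_whitelist:
            raise ValueError("indication whitelist must be non-empty")
        for window in (self.date_window, self.sensitivity_window):
            if window is not None:
                lo, hi = quarter_bounds(window[0])[0], quarter_bounds(window[1])[1]
                if lo > hi:
                    raise ValueError(f"window {window} is not well-ordered")
        if self.background_scope not in ("full", "whitelist_indication"):
            raise ValueError(f"unknown background scope {self.background_scope!r}")


class SocMap:
    """User-supplied PT→SOC mapping with a total lookup.

    Keys are matched case-insensitively after whitespace trimming; terms
    absent from the map fall back to the SOC "Unmapped" (one warning per
    distinct unmapped PT).
    """

    FALLBACK = "Unmapped"

    def __init__(self, mapping: dict[str, str]):
        self._map = {str(k).strip().lower(): str(v).strip() for k, v in mapping.items()}
        self._warned: set[str] = set()

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None) -> "SocMap":
        """Load a two-column (PT, SOC) delimited file; header optional."""
        text = Path(path).read_text(encoding="utf-8")
        if sep is None:
            sep = "\t" if "\t" in text.splitlines()[0] else ","
        df = pd.read_csv(Path(path), sep=sep, dtype=str, header=None,
                         names=["pt", "soc"], skip_blank_lines=True)
        if df.iloc[0]["pt"].strip().lower() in ("pt", "preferred term"):
            df = df.iloc[1:]
        return cls(dict(zip(df["pt"], df["soc"])))

    def lookup(self, pt: str) -> str:
        key = str(pt).strip().lower()
        soc = self._map.get(key)
        if soc is None:
            if key not in self._warned:
                logger.warning("PT %r has no SOC mapping; using %r", pt, self.FALLBACK)
                self._warned.add(key)
            return self.FALLBACK
        return soc


def map_pt_to_soc(pt: str, soc_map: SocMap) -> str:
    """Map one Preferred Term to its System Organ Class."""
    return soc_map.lookup(pt)


def _norm(series: pd.Series) -> pd.Series:
    return series.astype("string").str.strip().str.lower()


def _match_drug_rows(drug: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    name = drug["drugname"].astype("string").str.upper().fillna("")
    ai = drug["prod_ai"].astype("string").str.upper().fillna("")
    mask = pd.Series(False, index=drug.index)
    for pat in config.drug_name_patterns:
        p = pat.upper()
        mask |= name.str.contains(p, regex=False) | ai.str.contains(p, regex=False)
    mask &= drug["role_cod"].isin(config.role_codes)
    return drug[mask]


def _assemble_cases(corpus: dict[str, object], primaryids: pd.Series,
                    therapy_start: pd.DataFrame | None) -> pd.DataFrame:
    """Build one row per report with demographics and aggregated satellites."""
    demo = corpus["demo"]
    base = demo[demo["primaryid"].isin(primaryids)].copy()
    base["age_years"] = normalize_age_series(base["age"], base["age_cod"])
    base["weight_kg"] = normalize_weight_series(base["wt"], base["wt_cod"])

    def agg_set(table: str, col: str) -> dict:
        df = corpus[table]
        df = df[df["primaryid"].isin(primaryids) & df[col].notna()]
        sets: dict[int, set] = {}
        for pid, v in zip(df["primaryid"].to_numpy(), df[col].to_numpy()):
            sets.setdefault(pid, set()).add(str(v).strip())
        return {pid: frozenset(s) for pid, s in sets.items()}

    pts = agg_set("reac", "pt")
    outcomes = agg_set("outc", "outc_cod")
    routes = agg_set("drug", "route")

    pid = base["primaryid"]
    base["pts"] = pid.map(pts).apply(lambda v: v if isinstance(v, frozenset) else frozenset())
    base["outcomes"] = pid.map(outcomes).apply(lambda v: v if isinstance(v, frozenset) else frozenset())
    base["routes"] = pid.map(routes).apply(lambda v: v if isinstance(v, frozenset) else frozenset())

    if therapy_start is not None:
        base = base.merge(therapy_start, on="primaryid", how="left")
    else:
        base["therapy_start_dt"] = pd.NaT
        base["therapy_start_imputed"] = False
    keep = ["primaryid", "caseid", "age_years", "weight_kg", "sex", "occ_cod",
            "occr_country", "fda_dt", "event_dt", "event_dt_imputed",
            "outcomes", "pts", "routes", "therapy_start_dt", "therapy_start_imputed"]
    return base[keep].reset_index(drop=True)


def build_cohort(
    corpus: dict[str, object], config: CohortConfig,
    window: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Split the deduplicated corpus into (cohort, background) report frames.

    ``window`` overrides ``config.date_window`` (used for the sensitivity
    re-run). Raises :class:`EmptyCohortError` with per-filter counts when
    nothing survives.
    """
    window = window or config.date_window
    start, end = quarter_bounds(window[0])[0], quarter_bounds(window[1])[1]
    demo = corpus["demo"]
    in_window = demo["fda_dt"].notna() & demo["fda_dt"].between(start, end)
    window_ids = demo.loc[in_window, "primaryid"]

    diagnostics: dict[str, int] = {
        "retained_reports": int(len(demo)),
        "in_window": int(in_window.sum()),
    }

    matched = _match_drug_rows(corpus["drug"], config)
    matched = matched[matched["primaryid"].isin(window_ids)]
    diagnostics["drug_role_match"] = int(matched["primaryid"].nunique())

    indi = corpus["indi"]
    joined = matched.merge(
        indi, left_on=["primaryid", "drug_seq"],
        right_on=["primaryid", "indi_drug_seq"], how="left",
    )
    ind = _norm(joined["indi_pt"])
    whitelist = {w.strip().lower() for w in config.indication_whitelist}
    ok = ind.isin(whitelist).fillna(False)
    ambiguous = ind.isin(AMBIGUOUS_INDICATIONS) | ind.isna() | (ind == "")
    diagnostics["indication_missing_or_ambiguous"] = int(
        joined.loc[ambiguous & ~ok, "primaryid"].nunique())

    cohort_ids = joined.loc[ok.to_numpy(), "primaryid"].drop_duplicates()
    diagnostics["cohort"] = int(len(cohort_ids))
    if len(cohort_ids) == 0:
        raise EmptyCohortError(diagnostics)

    # earliest therapy start of the matched target drug per report
    ther = corpus["ther"]
    ther_match = matched[["primaryid", "drug_seq"]].merge(
        ther, left_on=["primaryid", "drug_seq"],
        right_on=["primaryid", "dsg_drug_seq"], how="inner",
    )
    ther_match = ther_match[ther_match["start_dt"].notna()]
    if len(ther_match):
        ther_match = ther_match.sort_values(["primaryid", "start_dt"])
        first = ther_match.drop_duplicates("primaryid", keep="first")
        therapy_start = first[["primaryid", "start_dt", "start_dt_imputed"]].rename(
            columns={"start_dt": "therapy_start_dt",
                     "start_dt_imputed": "therapy_start_imputed"})
    else:
        therapy_start = pd.DataFrame(
            {"primaryid": pd.Series(dtype="Int64"),
             "therapy_start_dt": pd.Series(dtype="datetime64[ns]"),
             "therapy_start_imputed": pd.Series(dtype=bool)})

    cohort = _assemble_cases(corpus, cohort_ids, therapy_start)
    cohort["therapy_start_imputed"] = (
        cohort["therapy_start_imputed"].astype("boolean").fillna(False).astype(bool))

    bg_ids = window_ids[~window_ids.isin(cohort_ids)]
    if config.background_scope == "whitelist_indication":
        has_wl = indi[_norm(indi["indi_pt"]).isin(whitelist).fillna(False)]["primaryid"]
        bg_ids = bg_ids[bg_ids.isin(has_wl)]
    background = _assemble_cases(corpus, bg_ids, None)
    diagnostics["background"] = int(len(background))
    return cohort, background, diagnostics


def _age_bin(age: float) -> str:
    if np.isnan(age):
        return "Missing"
    if age < 18:
        return "<18 years"
    if age < 65:
        return "18~64.9"
    if age <= 85:
        return "65~85"
    return ">85"


def _weight_bin(wt: float) -> str:
    if np.isnan(wt):
        return "Missing"
    if wt < 50:
        return "<50 kg"
    if wt <= 100:
        return "50~100 kg"
    return ">100 kg"


def primary_outcome(outcomes: frozenset) -> str:
    """Single outcome category per report by severity precedence."""
    for code in OUTCOME_PRECEDENCE:
        if code in outcomes:
            return OUTCOME_LABELS[code]
    return OUTCOME_LABELS["OT"]  # no outcome recorded counts as Other


def is_serious(outcomes: frozenset) -> bool:
    return bool(outcomes & SERIOUS_CODES)


def _primary_route(routes: frozenset) -> str:
    up = {str(r).strip().upper() for r in routes}
    for r in ROUTE_PRECEDENCE:
        if r in up:
            return r.capitalize()
    named = sorted(u for u in up if u)
    return named[0].capitalize() if named else "Missing"


def reporter_label(occ_cod) -> str:
    if pd.isna(occ_cod):
        return "Missing"
    return REPORTER_LABELS.get(str(occ_cod).strip().upper(), "Missing")


def summarize_demographics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Category counts and percentages over the cohort.

    One row per (characteristic, classification) with n and percentage of
    the cohort size; within each characteristic the percentages (Missing
    included) sum to 100.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    n = len(cohort)
    blocks: list[tuple[str, pd.Series]] = []

    blocks.append(("Weight (kg)", cohort["weight_kg"].apply(_weight_bin)))
    blocks.append(("Age (years)", cohort["age_years"].apply(_age_bin)))
    blocks.append(("Reporter type", cohort["occ_cod"].apply(reporter_label)))
    blocks.append(("Outcome", cohort["outcomes"].apply(primary_outcome)))
    blocks.append(("Serious and non-serious", cohort["outcomes"].apply(
        lambda o: "Serious cases" if is_serious(o) else "Non-serious cases")))
    country = cohort["occr_country"].astype("string").str.strip().str.upper()
    blocks.append(("Reported country", country.apply(
        lambda c: "United States" if c == "US" else "Others")))
    blocks.append(("Route of administration", cohort["routes"].apply(_primary_route)))

    rows = []
    for characteristic, series in blocks:
        counts = series.value_counts(dropna=False)
        for classification, count in counts.items():
            rows.append({
                "characteristic": characteristic,
                "classification": str(classification),
                "n": int(count),
                "pct": 100.0 * count / n,
            })
    return pd.DataFrame(rows, columns=["characteristic", "classification", "n", "pct"])


def summarize_provenance(
    cohort: pd.DataFrame,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Counts by country code, by report year (FDA receipt), by reporter type."""
    if cohort.empty:
        raise ValueError("cohort is empty")
    country = (cohort["occr_country"].astype("string").str.strip().str.upper()
               .fillna("Missing").replace("", "Missing"))
    by_country = country.value_counts()
    by_year = cohort["fda_dt"].dt.year.value_counts().sort_index()
    by_reporter = cohort["occ_cod"].apply(reporter_label).value_counts()
    return by_country, by_year, by_reporter
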