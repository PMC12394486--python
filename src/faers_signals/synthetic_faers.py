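"""Synthetic FAERS-shaped corpora with known ground truth.

The generator emits quarterly packages in exactly the ASCII dialect that
:mod:`faers_signals.faers_io` reads, with the structural nuisances a real
extract has — multi-version cases sharing a CASEID, deleted-case lists
(post-2019Q1 quarters only), missing demographics at configurable rates,
multi-PT reports, and therapy/event dates with log-normally distributed
onset delays — while keeping every drug–event reporting rate analytic, so
recovery of injected associations can be tested exactly.

The generative model is deliberately simple: reports are independent and
single-drug. Each report draws a drug from ``drug_vocab``; reports of the
target drug draw an indication from ``indication_vocab`` (whitelisted,
ambiguous, or other) and a role code, while background reports draw a
non-whitelisted indication. Each PT in ``pt_vocab`` is included with its
base probability, multiplied by ``rate_ratio`` for an injected
(drug pattern, indication, reaction) triple when the report matches the
drug pattern and carries that indication. In addition, every report draws
exactly one "primary complaint" PT from ``complaint_vocab`` — a vocabulary
disjoint from ``pt_vocab`` with the same distribution in both arms — so
reports are never reaction-free (they are not in FAERS) without
disturbing the analytic rates of the analyzed PTs.

Randomness is seeded per quarter from ``(seed, quarter index)``, so any
quarter regenerates independently and a fixed seed yields byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from faers_signals.faers_io import (
    LBS_TO_KG,
    RawQuarter,
    parse_quarter_label,
    quarter_bounds,
)

TARGET_DRUG_PATTERNS = ("PEMBROLIZUMAB", "KEYTRUDA")


@dataclass(frozen=True)
class Injection:
    """One injected drug–event association with a known rate ratio."""

    drug_pattern: str
    indication_pt: str
    reaction_pt: str
    rate_ratio: float


@dataclass(frozen=True)
class IndicationTerm:
    term: str
    kind: str  # "whitelist" | "ambiguous" | "other"
    p_target: float  # probability given a target-drug report


DEFAULT_DRUG_VOCAB: tuple[tuple[str, float], ...] = (
    ("PEMBROLIZUMAB", 0.10),
    ("NIVOLUMAB", 0.15),
    ("METFORMIN", 0.25),
    ("ATORVASTATIN", 0.25),
    ("LISINOPRIL", 0.25),
)

DEFAULT_PT_VOCAB: tuple[tuple[str, str, float], ...] = (
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.04),
    ("Myalgia", "Musculoskeletal and connective tissue disorders", 0.02),
    ("Fatigue", "General disorders and administration site conditions", 0.08),
    ("Drug ineffective", "General disorders and administration site conditions", 0.05),
    ("Nausea", "Gastrointestinal disorders", 0.06),
    ("Diarrhoea", "Gastrointestinal disorders", 0.05),
    ("Rash pruritic", "Skin and subcutaneous tissue disorders", 0.02),
    ("Hepatic enzyme increased", "Investigations", 0.015),
    ("Immune-mediated hypothyroidism", "Endocrine disorders", 0.01),
    ("Thyroid disorder", "Endocrine disorders", 0.01),
    ("Headache", "Nervous system disorders", 0.05),
    ("Pyrexia", "General disorders and administration site conditions", 0.04),
)

#: every report's guaranteed single complaint; probabilities sum to 1 and the
#: terms never overlap pt_vocab, so injected/null rates stay exactly analytic
DEFAULT_COMPLAINT_VOCAB: tuple[tuple[str, str, float], ...] = (
    ("Off label use", "Injury, poisoning and procedural complications", 0.30),
    ("Malaise", "General disorders and administration site conditions", 0.25),
    ("Product use issue", "Injury, poisoning and procedural complications", 0.20),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.15),
    ("Dizziness", "Nervous system disorders", 0.10),
)

DEFAULT_INJECTED: tuple[Injection, ...] = (
    Injection("PEMBROLIZUMAB", "Endometrial cancer", "Immune-mediated hypothyroidism", 5.0),
)

DEFAULT_INDICATION_VOCAB: tuple[IndicationTerm, ...] = (
    IndicationTerm("Endometrial cancer", "whitelist", 0.80),
    IndicationTerm("Malignant neoplasm", "ambiguous", 0.10),
    IndicationTerm("Melanoma", "other", 0.10),
)

#: missingness fractions mirroring what large spontaneous-report cohorts show
DEFAULT_MISSINGNESS: dict[str, float] = {
    "age": 0.51,
    "weight": 0.82,
    "event_dt": 0.40,
    "therapy_start": 0.45,
    "route": 0.65,
    "occ": 0.008,
    "sex": 0.05,
}

DEFAULT_OUTCOME_PROBS: dict[str, float] = {
    "DE": 0.0757, "DS": 0.0107, "HO": 0.1848, "LT": 0.0125, "OT": 0.7163,
}

DEFAULT_OCC_PROBS: dict[str, float] = {
    "CN": 0.5652, "MD": 0.2776, "HP": 0.1297, "PH": 0.0275,
}

OTHER_COUNTRIES = ("JP", "FR", "DE", "GB", "CA")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic corpus; defaults define the study conditions."""

    n_reports: int = 10_000
    quarters: tuple[str, ...] = ("2021Q1", "2021Q2", "2021Q3", "2021Q4")
    drug_vocab: tuple[tuple[str, float], ...] = DEFAULT_DRUG_VOCAB
    pt_vocab: tuple[tuple[str, str, float], ...] = DEFAULT_PT_VOCAB
    complaint_vocab: tuple[tuple[str, str, float], ...] = DEFAULT_COMPLAINT_VOCAB
    injected: tuple[Injection, ...] = DEFAULT_INJECTED
    indication_vocab: tuple[IndicationTerm, ...] = DEFAULT_INDICATION_VOCAB
    target_drug_patterns: tuple[str, ...] = TARGET_DRUG_PATTERNS
    target_role_probs: tuple[tuple[str, float], ...] = (("PS", 1.0),)
    duplicate_rate: float = 0.10
    deletion_rate: float = 0.02
    missingness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    onset_model: tuple[float, float] = (21.0, 1.1)  # (median days, log-scale sigma)
    outcome_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    us_share: float = 0.757
    seed: int = 0

    def validate(self) -> None:
        for label in self.quarters:
            parse_quarter_label(label)
        for probs, what in ((dict(self.drug_vocab), "drug_vocab"),
                            (self.outcome_probs, "outcome_probs")):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{what} probabilities sum to {total}, not 1")
        if not np.isclose(sum(t.p_target for t in self.indication_vocab), 1.0):
            raise ValueError("indication p_target values must sum to 1")
        for _, _, p in self.pt_vocab:
            if not 0 <= p <= 1:
                raise ValueError(f"base probability {p} outside [0, 1]")
        if not np.isclose(sum(p for _, _, p in self.complaint_vocab), 1.0):
            raise ValueError("complaint_vocab probabilities must sum to 1")
        overlap = {pt for pt, _, _ in self.pt_vocab} & {pt for pt, _, _ in self.complaint_vocab}
        if overlap:
            raise ValueError(f"complaint_vocab overlaps pt_vocab: {sorted(overlap)}")
        for rate, what in ((self.duplicate_rate, "duplicate_rate"),
                           (self.deletion_rate, "deletion_rate"),
                           *((v, f"missingness[{k}]") for k, v in self.missingness.items())):
            if not 0 <= rate <= 1:
                raise ValueError(f"{what} = {rate} outside [0, 1]")
        base = {pt: p for pt, _, p in self.pt_vocab}
        for inj in self.injected:
            if inj.rate_ratio <= 0:
                raise ValueError(f"rate_ratio must be > 0 for {inj}")
            if inj.reaction_pt not in base:
                raise ValueError(f"injected reaction {inj.reaction_pt!r} not in pt_vocab")
            if base[inj.reaction_pt] * inj.rate_ratio > 1:
                raise ValueError(
                    f"infeasible probability for ({inj.drug_pattern!r}, "
                    f"{inj.reaction_pt!r}): base {base[inj.reaction_pt]} x "
                    f"ratio {inj.rate_ratio} > 1")


def _matches(pattern: str, names: np.ndarray, ais: np.ndarray) -> np.ndarray:
    p = pattern.upper()
    return (np.char.find(names.astype(str), p) >= 0) | (np.char.find(ais.astype(str), p) >= 0)


def _generate_quarter(spec: SyntheticSpec, qi: int, n_q: int) -> RawQuarter:
    label = spec.quarters[qi]
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), qi]))
    q_start, q_end = quarter_bounds(label)
    q_days = (q_end - q_start).days + 1

    caseid = (qi + 1) * 10_000_000 + np.arange(n_q, dtype=np.int64)
    primaryid = caseid * 10 + 2  # retained version; duplicates get +1

    drug_names = np.array([n for n, _ in spec.drug_vocab])
    drug_probs = np.array([p for _, p in spec.drug_vocab])
    drug_idx = rng.choice(len(drug_names), size=n_q, p=drug_probs)
    drugname = drug_names[drug_idx].astype(object)
    prod_ai = np.full(n_q, np.nan, dtype=object)

    is_target = np.zeros(n_q, dtype=bool)
    for pat in spec.target_drug_patterns:
        is_target |= np.char.find(drugname.astype(str), pat.upper()) >= 0
    # brand-name variant: half the target reports carry the brand name with
    # the generic as active ingredient
    brand = is_target & (rng.random(n_q) < 0.5)
    if spec.target_drug_patterns:
        generic = spec.target_drug_patterns[0]
        prod_ai[brand] = generic
        drugname[brand] = "KEYTRUDA" if generic == "PEMBROLIZUMAB" else generic

    ind_terms = np.array([t.term for t in spec.indication_vocab], dtype=object)
    p_target_ind = np.array([t.p_target for t in spec.indication_vocab])
    non_wl = [i for i, t in enumerate(spec.indication_vocab) if t.kind != "whitelist"]
    indication = np.empty(n_q, dtype=object)
    n_t = int(is_target.sum())
    indication[is_target] = ind_terms[rng.choice(len(ind_terms), size=n_t, p=p_target_ind)]
    indication[~is_target] = ind_terms[np.array(non_wl)][
        rng.integers(0, len(non_wl), size=n_q - n_t)]

    roles = np.full(n_q, "PS", dtype=object)
    role_names = [r for r, _ in spec.target_role_probs]
    role_probs = np.array([p for _, p in spec.target_role_probs])
    roles[is_target] = np.array(role_names, dtype=object)[
        rng.choice(len(role_names), size=n_t, p=role_probs / role_probs.sum())]

    # reaction draws: base probability, boosted for injected triples
    pts = np.array([pt for pt, _, _ in spec.pt_vocab], dtype=object)
    base = np.array([p for _, _, p in spec.pt_vocab])
    probs = np.tile(base, (n_q, 1))
    names_u = np.char.upper(drugname.astype(str))
    ais_u = np.char.upper(np.where(pd.isna(prod_ai), "", prod_ai).astype(str))
    for inj in spec.injected:
        mask = _matches(inj.drug_pattern, names_u, ais_u) & (indication == inj.indication_pt)
        j = int(np.where(pts == inj.reaction_pt)[0][0])
        probs[mask, j] = np.minimum(base[j] * inj.rate_ratio, 1.0)
    react = rng.random((n_q, len(pts))) < probs

    # guaranteed single complaint, identically distributed in both arms
    c_terms = np.array([pt for pt, _, _ in spec.complaint_vocab], dtype=object)
    c_probs = np.array([p for _, _, p in spec.complaint_vocab])
    complaint = c_terms[rng.choice(len(c_terms), size=n_q, p=c_probs / c_probs.sum())]

    miss = spec.missingness
    age_years = np.clip(rng.normal(66.0, 12.0, n_q), 18.0, 95.0).round(0)
    age_dec = rng.random(n_q) < 0.10
    age = np.where(age_dec, age_years / 10.0, age_years)
    age_cod = np.where(age_dec, "DEC", "YR").astype(object)
    age_missing = rng.random(n_q) < miss.get("age", 0.0)

    wt_kg = np.clip(rng.normal(75.0, 16.0, n_q), 35.0, 150.0).round(1)
    wt_lbs = rng.random(n_q) < 0.15
    wt = np.where(wt_lbs, (wt_kg / LBS_TO_KG).round(1), wt_kg)
    wt_cod = np.where(wt_lbs, "LBS", "KG").astype(object)
    wt_missing = rng.random(n_q) < miss.get("weight", 0.0)

    sex = np.where(is_target, "F", np.where(rng.random(n_q) < 0.5, "F", "M")).astype(object)
    sex[rng.random(n_q) < miss.get("sex", 0.0)] = np.nan

    country = np.where(
        rng.random(n_q) < spec.us_share, "US",
        np.array(OTHER_COUNTRIES, dtype=object)[rng.integers(0, len(OTHER_COUNTRIES), n_q)],
    ).astype(object)

    occ_names = list(DEFAULT_OCC_PROBS)
    occ_p = np.array(list(DEFAULT_OCC_PROBS.values()))
    occ = np.array(occ_names, dtype=object)[rng.choice(len(occ_names), n_q, p=occ_p / occ_p.sum())]
    occ[rng.random(n_q) < miss.get("occ", 0.0)] = np.nan

    fda_dt = q_start + pd.to_timedelta(rng.integers(0, q_days, n_q), unit="D")

    median_days, sigma = spec.onset_model
    onset = np.where(
        is_target,
        np.maximum(0, rng.lognormal(np.log(median_days), sigma, n_q).round(0)),
        rng.integers(0, 91, n_q),
    ).astype(int)
    delay = rng.integers(0, 31, n_q)
    start_dt = fda_dt - pd.to_timedelta(onset + delay, unit="D")
    event_dt = start_dt + pd.to_timedelta(onset, unit="D")
    event_missing = rng.random(n_q) < miss.get("event_dt", 0.0)
    start_missing = rng.random(n_q) < miss.get("therapy_start", 0.0)
    event_series = pd.Series(event_dt)
    event_series[event_missing] = pd.NaT

    out_names = list(spec.outcome_probs)
    out_p = np.array(list(spec.outcome_probs.values()))
    outcome = np.array(out_names, dtype=object)[
        rng.choice(len(out_names), n_q, p=out_p / out_p.sum())]
    extra_mask = rng.random(n_q) < 0.05
    extra_code = np.where(rng.random(n_q) < 0.5, "HO", "OT").astype(object)

    route = np.where(is_target, "INTRAVENOUS",
                     np.where(rng.random(n_q) < 0.5, "ORAL", "INTRAVENOUS")).astype(object)
    route[rng.random(n_q) < miss.get("route", 0.0)] = np.nan

    demo = pd.DataFrame({
        "primaryid": pd.array(primaryid, dtype="Int64"),
        "caseid": pd.array(caseid, dtype="Int64"),
        "fda_dt": pd.Series(fda_dt),
        "event_dt": event_series,
        "age": np.where(age_missing, np.nan, age),
        "age_cod": np.where(age_missing, np.nan, age_cod),
        "wt": np.where(wt_missing, np.nan, wt),
        "wt_cod": np.where(wt_missing, np.nan, wt_cod),
        "sex": sex,
        "occ_cod": occ,
        "occr_country": country,
    })
    demo["fda_dt_imputed"] = False
    demo["fda_dt_year"] = demo["fda_dt"].dt.year.astype("Int32")
    demo["event_dt_imputed"] = False
    demo["event_dt_year"] = demo["event_dt"].dt.year.astype("Int32")

    drug = pd.DataFrame({
        "primaryid": pd.array(primaryid, dtype="Int64"),
        "drug_seq": pd.array(np.ones(n_q, dtype=np.int64), dtype="Int64"),
        "role_cod": roles,
        "drugname": drugname,
        "prod_ai": prod_ai,
        "route": route,
    })

    rep_i, pt_j = np.nonzero(react)
    reac = pd.DataFrame({
        "primaryid": pd.array(np.concatenate([primaryid, primaryid[rep_i]]), dtype="Int64"),
        "pt": np.concatenate([complaint, pts[pt_j]]),
    })

    indi = pd.DataFrame({
        "primaryid": pd.array(primaryid, dtype="Int64"),
        "indi_drug_seq": pd.array(np.ones(n_q, dtype=np.int64), dtype="Int64"),
        "indi_pt": indication,
    })

    outc = pd.DataFrame({
        "primaryid": pd.array(np.concatenate([primaryid, primaryid[extra_mask]]), dtype="Int64"),
        "outc_cod": np.concatenate([outcome, extra_code[extra_mask]]),
    }).sort_values("primaryid", kind="mergesort").reset_index(drop=True)

    has_start = ~start_missing
    ther = pd.DataFrame({
        "primaryid": pd.array(primaryid[has_start], dtype="Int64"),
        "dsg_drug_seq": pd.array(np.ones(int(has_start.sum()), dtype=np.int64), dtype="Int64"),
        "start_dt": pd.Series(start_dt[has_start]).reset_index(drop=True),
        "end_dt": pd.Series(pd.NaT, index=range(int(has_start.sum()))),
    })
    for col in ("start_dt", "end_dt"):
        ther[f"{col}_imputed"] = False
        ther[f"{col}_year"] = ther[col].dt.year.astype("Int32")

    # multi-version cases: an earlier superseded version of the same case
    dup_mask = rng.random(n_q) < spec.duplicate_rate
    if dup_mask.any():
        idx = np.nonzero(dup_mask)[0]
        delta = rng.integers(0, 30, len(idx))  # 0 => FDA_DT tie
        old = demo.iloc[idx].copy()
        old["primaryid"] = pd.array(caseid[idx] * 10 + 1, dtype="Int64")
        old["fda_dt"] = old["fda_dt"] - pd.to_timedelta(delta, unit="D")
        old["fda_dt_year"] = old["fda_dt"].dt.year.astype("Int32")
        demo = pd.concat([demo, old], ignore_index=True)
        old_ids = dict(zip(primaryid[idx], caseid[idx] * 10 + 1))
        for name, df in (("drug", drug), ("reac", reac), ("indi", indi),
                         ("outc", outc), ("ther", ther)):
            sat = df[df["primaryid"].isin(old_ids)].copy()
            sat["primaryid"] = pd.array(
                [old_ids[p] for p in sat["primaryid"]], dtype="Int64")
            if name == "drug":
                drug = pd.concat([drug, sat], ignore_index=True)
            elif name == "reac":
                reac = pd.concat([reac, sat], ignore_index=True)
            elif name == "indi":
                indi = pd.concat([indi, sat], ignore_index=True)
            elif name == "outc":
                outc = pd.concat([outc, sat], ignore_index=True)
            else:
                ther = pd.concat([ther, sat], ignore_index=True)

    deleted: set[int] = set()
    year, _ = parse_quarter_label(label)
    if year >= 2019:
        del_mask = rng.random(n_q) < spec.deletion_rate
        deleted = set(int(c) for c in caseid[del_mask])

    for df in (demo, drug, reac, indi, outc, ther):
        df.sort_values("primaryid", kind="mergesort", inplace=True,
                       ignore_index=True)
    return RawQuarter(quarter_label=label, demo=demo, drug=drug, reac=reac,
                      indi=indi, outc=outc, ther=ther, deleted_case_ids=deleted)


def generate(spec: SyntheticSpec) -> list[RawQuarter]:
    """Generate all quarters of a synthetic corpus (deterministic in seed)."""
    spec.validate()
    n_quarters = len(spec.quarters)
    counts = [spec.n_reports // n_quarters] * n_quarters
    for i in range(spec.n_reports % n_quarters):
        counts[i] += 1
    return [_generate_quarter(spec, qi, counts[qi]) for qi in range(n_quarters)]


def ground_truth(spec: SyntheticSpec) -> pd.DataFrame:
    """Expected rates and cell counts for every injected pair.

    ``expected_a``/``expected_c`` are post-deletion expectations at the
    spec's total report count; ``true_rate_ratio`` is the injected
    reporting-rate ratio (capped at the feasibility bound).
    """
    spec.validate()
    base = {pt: p for pt, _, p in spec.pt_vocab}
    drug_probs = dict(spec.drug_vocab)
    role_p = dict(spec.target_role_probs)
    ind_p = {t.term: t.p_target for t in spec.indication_vocab}
    n_eff = spec.n_reports * (1.0 - spec.deletion_rate)

    rows = []
    for inj in spec.injected:
        # the brand-name variant keeps the generic in prod_ai, so a generic
        # pattern still matches every report of that vocabulary entry
        p_drug = sum(p for name, p in drug_probs.items()
                     if inj.drug_pattern.upper() in name.upper())
        p_cohort = p_drug * ind_p.get(inj.indication_pt, 0.0) * role_p.get("PS", 0.0)
        p_react = min(base[inj.reaction_pt] * inj.rate_ratio, 1.0)
        rows.append({
            "drug_pattern": inj.drug_pattern,
            "indication_pt": inj.indication_pt,
            "reaction_pt": inj.reaction_pt,
            "true_rate_ratio": p_react / base[inj.reaction_pt],
            "p_cohort": p_cohort,
            "expected_a": n_eff * p_cohort * p_react,
            "expected_c": n_eff * (1.0 - p_cohort) * base[inj.reaction_pt],
        })
    return pd.DataFrame(rows, columns=["drug_pattern", "indication_pt", "reaction_pt",
                                       "true_rate_ratio", "p_cohort",
                                       "expected_a", "expected_c"])


def default_soc_mapping(spec: SyntheticSpec) -> dict[str, str]:
    """PT→SOC mapping implied by the spec's vocabulary (for tests/pipelines)."""
    mapping = {pt: soc for pt, soc, _ in spec.pt_vocab}
    mapping.update({pt: soc for pt, soc, _ in spec.complaint_vocab})
    return mapping
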