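"""End-to-end orchestration: load → dedup → cohort → signals → onset.

The pipeline is fully deterministic: all randomness lives in the
synthetic generator, and every output file is written with fixed float
formatting and sorted keys, so identical configuration (and seed) yields
byte-identical result bundles. A run manifest records the report count
surviving each stage, and a methods-echo file records every threshold in
effect, so the middle of the funnel stays auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from faers_signals import case_processing, onset_analysis, signal_stats
from faers_signals.case_processing import decisions_to_frame
from faers_signals.cohort_builder import (
    CohortConfig,
    SocMap,
    build_cohort,
    summarize_demographics,
    summarize_provenance,
)
from faers_signals.faers_io import RawQuarter, combine_quarters, read_quarter
from faers_signals.signal_stats import SignalThresholds
from faers_signals.synthetic_faers import SyntheticSpec, default_soc_mapping, generate

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.4f"


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source (directories or synthetic)."""

    input_dir: str | Path | None = None
    quarters: tuple[str, ...] = ()
    synthetic: SyntheticSpec | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    soc_mapping: dict[str, str] | str | Path | None = None
    ic_dialect: str = "log2-transform"
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    rank_k: int = 30
    quantile_method: str = "linear"
    output_dir: str | Path = "results"
    render_figures: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one input source: input_dir or synthetic spec")
        if self.rank_k < 1:
            raise ValueError("rank_k must be >= 1")


@dataclass
class ResultBundle:
    manifest: dict
    cohort: pd.DataFrame
    background: pd.DataFrame
    signals: pd.DataFrame
    top_frequency: pd.DataFrame
    top_strength: pd.DataFrame
    demographics: pd.DataFrame
    provenance: tuple[pd.Series, pd.Series, pd.Series]
    onset_records: pd.DataFrame
    onset_excluded: dict[str, int]
    onset_histogram: pd.Series
    onset_summary: pd.DataFrame
    onset_cdf: pd.DataFrame
    dedup_audit: pd.DataFrame


def load_quarters(config: RunConfig) -> list[RawQuarter]:
    if config.synthetic is not None:
        return generate(config.synthetic)
    return [read_quarter(config.input_dir, label) for label in config.quarters]


def resolve_soc_map(config: RunConfig) -> SocMap:
    src = config.soc_mapping
    if src is None:
        if config.synthetic is not None:
            return SocMap(default_soc_mapping(config.synthetic))
        return SocMap({})
    if isinstance(src, dict):
        return SocMap(src)
    return SocMap.from_file(src)


def analyze(
    quarters: list[RawQuarter],
    config: RunConfig,
    window: tuple[str, str] | None = None,
) -> ResultBundle:
    """Run every analysis stage over already-loaded quarters."""
    soc_map = resolve_soc_map(config)
    corpus = combine_quarters(quarters)
    n_loaded = len(corpus["demo"])

    retained, dedup_decisions = case_processing.deduplicate(corpus["demo"])
    n_dedup = len(retained)
    retained, deleted_decisions = case_processing.remove_deleted(
        retained, corpus["deleted_case_ids"])
    n_after_delete = len(retained)
    corpus = case_processing.filter_satellites(corpus, retained)

    cohort, background, diagnostics = build_cohort(corpus, config.cohort, window=window)

    signals = signal_stats.compute_signals(
        cohort, background, soc_map=soc_map,
        ic_dialect=config.ic_dialect, thresholds=config.thresholds)
    top_freq = signal_stats.rank_results(signals, mode="frequency", k=config.rank_k)
    top_strength = signal_stats.rank_results(signals, mode="strength", k=config.rank_k)

    demographics = summarize_demographics(cohort)
    provenance = summarize_provenance(cohort)

    records, excluded = onset_analysis.compute_onset(cohort, soc_map=soc_map)
    histogram = onset_analysis.bin_onset(records) if len(records) else pd.Series(dtype=int)
    summary = (onset_analysis.summarize_by_soc(records, method=config.quantile_method)
               if len(records) else pd.DataFrame())
    cdf = (onset_analysis.cumulative_timeline(records)
           if len(records) else pd.DataFrame())

    manifest = {
        "loaded_report_versions": n_loaded,
        "after_deduplication": n_dedup,
        "after_deleted_removal": n_after_delete,
        "in_window": diagnostics["in_window"],
        "cohort": diagnostics["cohort"],
        "background": diagnostics["background"],
        "filter_diagnostics": diagnostics,
        "quarters": [q.quarter_label for q in quarters],
        "per_quarter": {q.quarter_label: q.manifest for q in quarters},
    }
    audit = decisions_to_frame(dedup_decisions + deleted_decisions)
    return ResultBundle(
        manifest=manifest, cohort=cohort, background=background,
        signals=signals, top_frequency=top_freq, top_strength=top_strength,
        demographics=demographics, provenance=provenance,
        onset_records=records, onset_excluded=excluded,
        onset_histogram=histogram, onset_summary=summary, onset_cdf=cdf,
        dedup_audit=audit,
    )


def _methods_echo(config: RunConfig) -> dict:
    th = config.thresholds
    return {
        "ic_dialect": config.ic_dialect,
        "quantile_method": config.quantile_method,
        "rank_k": config.rank_k,
        "z_quantile": th.z,
        "criteria": {
            "ror": {"min_a": th.min_a, "ci_lower_gt": th.ror_lower},
            "prr": {"min_a": th.min_a, "ci_lower_gt": th.prr_lower,
                    "prr_ge": th.prr_min, "chi2_ge": th.chi2_min},
            "bcpnn": {"ic025_gt": th.ic025_min},
            "mgps": {"ebgm05_gt": th.ebgm05_min},
        },
        "cohort": {
            "drug_name_patterns": list(config.cohort.drug_name_patterns),
            "role_codes": sorted(config.cohort.role_codes),
            "indication_whitelist": list(config.cohort.indication_whitelist),
            "date_window": list(config.cohort.date_window),
            "background_scope": config.cohort.background_scope,
        },
    }


def write_bundle(bundle: ResultBundle, config: RunConfig, prefix: str = "") -> Path:
    """Serialize a result bundle under the configured output directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def p(name: str) -> Path:
        return outdir / f"{prefix}{name}"

    with open(p("manifest.json"), "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=str)
    with open(p("methods_echo.json"), "w") as fh:
        json.dump(_methods_echo(config), fh, indent=2, sort_keys=True)

    bundle.demographics.to_csv(p("demographics.tsv"), sep="\t", index=False,
                               float_format="%.2f")
    by_country, by_year, by_reporter = bundle.provenance
    by_country.rename_axis("country").rename("n").to_csv(p("provenance_country.tsv"), sep="\t")
    by_year.rename_axis("year").rename("n").to_csv(p("provenance_year.tsv"), sep="\t")
    by_reporter.rename_axis("reporter").rename("n").to_csv(p("provenance_reporter.tsv"), sep="\t")

    signal_stats.export_forest(bundle.signals.sort_values("pt").reset_index(drop=True)
                               if len(bundle.signals) else bundle.signals,
                               p("signals.tsv"))
    if len(bundle.top_frequency):
        signal_stats.export_forest(bundle.top_frequency, p("top_frequency.tsv"),
                                   render_figure=config.render_figures)
    if len(bundle.top_strength):
        signal_stats.export_forest(bundle.top_strength, p("top_strength.tsv"),
                                   render_figure=config.render_figures)

    if len(bundle.onset_histogram):
        bundle.onset_histogram.rename_axis("interval_days").rename("n").to_csv(
            p("onset_histogram.tsv"), sep="\t")
    if len(bundle.onset_summary):
        bundle.onset_summary.to_csv(p("onset_summary.tsv"), sep="\t", index=False,
                                    float_format="%.2f")
    if len(bundle.onset_cdf):
        bundle.onset_cdf.to_csv(p("onset_cdf.tsv"), sep="\t", index=False,
                                float_format="%.6f")
    with open(p("onset_exclusions.json"), "w") as fh:
        json.dump(bundle.onset_excluded, fh, indent=2, sort_keys=True)
    bundle.dedup_audit.to_csv(p("dedup_audit.tsv"), sep="\t", index=False)
    return outdir


def run_pipeline(config: RunConfig, write: bool = True) -> ResultBundle:
    """Execute the full analysis and (optionally) write all export files."""
    quarters = load_quarters(config)
    bundle = analyze(quarters, config)
    if write:
        write_bundle(bundle, config)
    return bundle


def run_sensitivity(config: RunConfig, write: bool = True
                    ) -> tuple[ResultBundle, pd.DataFrame]:
    """Re-run the pipeline on the post-approval date window.

    Outputs carry a ``sensitivity_`` prefix. Returns the sensitivity
    bundle plus a per-PT comparison of main-vs-sensitivity ROR.
    """
    window = config.cohort.sensitivity_window
    if window is None:
        raise ValueError("config.cohort.sensitivity_window is not set")
    quarters = load_quarters(config)
    main = analyze(quarters, config)
    sens = analyze(quarters, config, window=window)
    comparison = main.signals[["pt", "n", "ror", "ror_lo", "ror_hi"]].merge(
        sens.signals[["pt", "n", "ror", "ror_lo", "ror_hi"]],
        on="pt", suffixes=("_main", "_sensitivity"))
    if write:
        write_bundle(sens, config, prefix="sensitivity_")
        comparison.round(4).to_csv(
            Path(config.output_dir) / "sensitivity_comparison.tsv",
            sep="\t", index=False, float_format="%.4f")
    return sens, comparison
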