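"""YAML configuration loading for the command-line interface.

A run configuration names exactly one input source — a directory of
quarterly packages (``input_dir`` + ``quarters``) or a ``synthetic``
generator spec — plus the cohort definition and analysis options. See
the README for a worked example.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from faers_signals.cohort_builder import CohortConfig
from faers_signals.pipeline import RunConfig
from faers_signals.signal_stats import SignalThresholds
from faers_signals.synthetic_faers import Injection, IndicationTerm, SyntheticSpec


class ConfigError(ValueError):
    """Malformed or inconsistent configuration file."""


def synthetic_spec_from_dict(d: dict) -> SyntheticSpec:
    kwargs = dict(d)
    if "injected" in kwargs:
        kwargs["injected"] = tuple(
            Injection(*row) if not isinstance(row, Injection) else row
            for row in kwargs["injected"])
    if "indication_vocab" in kwargs:
        kwargs["indication_vocab"] = tuple(
            IndicationTerm(*row) if not isinstance(row, IndicationTerm) else row
            for row in kwargs["indication_vocab"])
    for key in ("quarters", "drug_vocab", "pt_vocab", "target_drug_patterns",
                "target_role_probs", "onset_model"):
        if key in kwargs:
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v
                                for v in kwargs[key]) if key != "onset_model" \
                else tuple(kwargs[key])
    try:
        return SyntheticSpec(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad synthetic spec: {exc}") from exc


def cohort_config_from_dict(d: dict) -> CohortConfig:
    kwargs = dict(d)
    for key in ("drug_name_patterns", "indication_whitelist", "date_window",
                "sensitivity_window"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    if "role_codes" in kwargs:
        kwargs["role_codes"] = frozenset(kwargs["role_codes"])
    try:
        return CohortConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad cohort config: {exc}") from exc


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML file into a :class:`RunConfig`."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")

    kwargs = dict(raw)
    if "synthetic" in kwargs and kwargs["synthetic"] is not None:
        kwargs["synthetic"] = synthetic_spec_from_dict(kwargs["synthetic"])
    if "cohort" in kwargs and kwargs["cohort"] is not None:
        kwargs["cohort"] = cohort_config_from_dict(kwargs["cohort"])
    if "thresholds" in kwargs and kwargs["thresholds"] is not None:
        try:
            kwargs["thresholds"] = SignalThresholds(**kwargs["thresholds"])
        except TypeError as exc:
            raise ConfigError(f"bad thresholds: {exc}") from exc
    if "quarters" in kwargs:
        kwargs["quarters"] = tuple(kwargs["quarters"])
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad run config: {exc}") from exc
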