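"""Typed configuration objects and the YAML/JSON loader.

Two configuration kinds exist: a :class:`~psakit.simulate.CohortConfig`
describing how to generate a synthetic cohort, and an :class:`AnalysisConfig`
describing how to analyze one.  ``load_config`` dispatches on an optional
``kind`` key (``cohort`` / ``analysis``) or, failing that, on which schema
the keys match.  Unknown keys are an error listing the valid ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .simulate import CohortConfig, ConfigError, GroupParams


@dataclass
class AnalysisConfig:
    """Parameters of the analysis pipeline.

    ``published_cutoffs`` are the literature screening thresholds applied in
    the screening-classification stage (PSAD 0.15 ng/mL/g from the Epstein
    active-surveillance criteria; PSAMD 0.012 ug/g); the tumor-volume
    significance threshold is 0.5 cm^3.
    """

    grouping: str = "race_ethnicity"
    metrics: tuple[str, ...] = ("psa", "psad", "psam", "psamd")
    tv_threshold: float = 0.5
    published_cutoffs: dict = field(default_factory=lambda: {"psad": 0.15, "psamd": 0.012})
    fixed_specificity: float = 0.80
    bootstrap_reps: int = 2000
    cutoff_criterion: str = "upper_left"
    bsa_mode: str = "meters"
    strict_io: bool = True
    seed: int = 0
    output_formats: tuple[str, ...] = ("csv",)

    def validate(self) -> None:
        if self.tv_threshold <= 0:
            raise ConfigError("tv_threshold must be > 0")
        if not 0 < self.fixed_specificity < 1:
            raise ConfigError("fixed_specificity must be in (0, 1)")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")
        if self.cutoff_criterion not in ("upper_left", "youden"):
            raise ConfigError("cutoff_criterion must be 'upper_left' or 'youden'")
        if self.bsa_mode not in ("meters", "dubois-cm"):
            raise ConfigError("bsa_mode must be 'meters' or 'dubois-cm'")


def _check_keys(data: dict, valid: set[str], context: str) -> None:
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"{context}: unknown key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
        )


def _coerce_tuples(cls, data: dict) -> dict:
    """YAML yields lists where the dataclasses expect tuples."""
    out = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list):
            value = out[f.name]
            out[f.name] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
    return out


def cohort_config_from_dict(data: dict) -> CohortConfig:
    data = dict(data)
    data.pop("kind", None)
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    _check_keys(data, valid, "cohort config")
    groups_data = data.pop("groups", None)
    config = CohortConfig(**_coerce_tuples(CohortConfig, data))
    if groups_data is not None:
        group_fields = {f.name for f in dataclasses.fields(GroupParams)}
        groups = dict(config.groups)
        for name, overrides in groups_data.items():
            _check_keys(overrides, group_fields, f"group {name!r}")
            if name in groups:
                groups[name] = dataclasses.replace(
                    groups[name], **_coerce_tuples(GroupParams, overrides)
                )
            else:
                groups[name] = GroupParams(**_coerce_tuples(GroupParams, overrides))
        config.groups = groups
    config.validate()
    return config


def analysis_config_from_dict(data: dict) -> AnalysisConfig:
    data = dict(data)
    data.pop("kind", None)
    valid = {f.name for f in dataclasses.fields(AnalysisConfig)}
    _check_keys(data, valid, "analysis config")
    config = AnalysisConfig(**_coerce_tuples(AnalysisConfig, data))
    config.validate()
    return config


def load_config(path: str | Path) -> Union[CohortConfig, AnalysisConfig]:
    """Load a YAML or JSON config file into its typed object.

    An empty file yields an all-defaults :class:`AnalysisConfig`.  The kind
    is taken from an explicit ``kind: cohort|analysis`` key, or inferred from
    which schema the keys belong to (ambiguous or mixed keys are an error).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    kind = data.get("kind")
    if kind == "cohort":
        return cohort_config_from_dict(data)
    if kind == "analysis":
        return analysis_config_from_dict(data)
    if kind is not None:
        raise ConfigError(f"{path}: unknown kind {kind!r}; valid kinds: cohort, analysis")
    cohort_keys = {f.name for f in dataclasses.fields(CohortConfig)}
    analysis_keys = {f.name for f in dataclasses.fields(AnalysisConfig)}
    keys = set(data)
    if keys <= analysis_keys:
        return analysis_config_from_dict(data)
    if keys <= cohort_keys:
        return cohort_config_from_dict(data)
    raise ConfigError(
        f"{path}: keys {sorted(keys - (cohort_keys | analysis_keys))} match neither config kind; "
        f"cohort keys: {sorted(cohort_keys)}; analysis keys: {sorted(analysis_keys)}"
    )
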