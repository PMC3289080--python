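"""Declarative run configuration: one file holding every module's knobs.

The config file is JSON or YAML with up to three blocks — ``preprocess``,
``correction`` and ``analysis`` — whose keys mirror the corresponding
dataclass fields.  Every field has a default; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .correction import CorrectionConfig
from .errors import InputError
from .preprocess import PreprocessConfig
from .suppression_analysis import AnalysisConfig


@dataclass(frozen=True)
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def _build(cls, values: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - allowed
    if unknown:
        raise InputError(f"unknown {context} config key(s): {sorted(unknown)}")
    return cls(**values)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from a JSON/YAML file; None gives all defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    doc = doc or {}
    if not isinstance(doc, dict):
        raise InputError(f"{path}: config root must be a mapping")
    unknown = set(doc) - {"preprocess", "correction", "analysis"}
    if unknown:
        raise InputError(f"unknown config block(s): {sorted(unknown)}")
    correction = _build(CorrectionConfig, doc.get("correction", {}), "correction")
    analysis_values = dict(doc.get("analysis", {}))
    analysis_values["correction"] = correction
    return RunConfig(
        preprocess=_build(PreprocessConfig, doc.get("preprocess", {}), "preprocess"),
        correction=correction,
        analysis=_build(AnalysisConfig, analysis_values, "analysis"),
    )
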