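"""YAML/JSON configuration for model, frequency and run parameters."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .likelihood import AlleleFrequencies, ModelFamily, PenetranceModel

_KEYS = {"family", "f_m", "f_f_skewed", "f_f_random", "eps", "q_s", "q_t", "condition_on_proband"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    model: PenetranceModel
    freqs: AlleleFrequencies
    condition_on_proband: bool = False


def parse_analysis_config(doc: dict) -> AnalysisConfig:
    unknown = set(doc) - _KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "family" not in doc:
        raise ConfigError("config must name a model 'family'")
    try:
        family = ModelFamily(doc["family"])
    except ValueError:
        valid = ", ".join(f.value for f in ModelFamily)
        raise ConfigError(f"unknown model family {doc['family']!r}; expected one of: {valid}") from None
    model_kwargs = {k: float(doc[k]) for k in ("f_m", "f_f_skewed", "f_f_random", "eps") if k in doc}
    freq_kwargs = {k: float(doc[k]) for k in ("q_s", "q_t") if k in doc}
    try:
        model = PenetranceModel(family=family, **model_kwargs)
        freqs = AlleleFrequencies(**freq_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from None
    return AnalysisConfig(
        model=model,
        freqs=freqs,
        condition_on_proband=bool(doc.get("condition_on_proband", False)),
    )


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    text = Path(path).read_text(encoding="utf-8")
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return parse_analysis_config(doc)
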