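"""Run configuration: a strict YAML layer over the library dataclasses."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .fitness import InferenceOptions
from .simulate import SimDesign

__all__ = ["load_config", "sim_design_from_config", "inference_options_from_config",
           "ConfigError"]


class ConfigError(ValueError):
    pass


_SIM_EXTRA_KEYS = {
    "concentrations",
    "replicates",
    "lineage_sd",
    "replicate_sd",
    "dose_response_coef",
    "outlier_shifts",
    "seed",
}


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, Mapping):
        raise ConfigError("config must be a mapping")
    return dict(data)


def _strict(section: Mapping[str, Any], allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {name}: {sorted(unknown)}")


def sim_design_from_config(cfg: Mapping[str, Any]) -> tuple[SimDesign, dict]:
    """Build a SimDesign plus experiment-level extras from a `sim` section.

    Unknown keys are rejected rather than ignored, so typos fail loudly.
    """
    section = dict(cfg.get("sim", {}))
    design_keys = {f.name for f in fields(SimDesign)}
    _strict(section, design_keys | _SIM_EXTRA_KEYS, "sim")
    extras = {k: section.pop(k) for k in list(section) if k in _SIM_EXTRA_KEYS}
    try:
        design = SimDesign(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid sim design: {exc}") from exc
    return design, extras


def inference_options_from_config(cfg: Mapping[str, Any]) -> InferenceOptions:
    section = dict(cfg.get("inference", {}))
    allowed = {f.name for f in fields(InferenceOptions)}
    _strict(section, allowed, "inference")
    if "s_bounds" in section:
        section["s_bounds"] = tuple(section["s_bounds"])
    try:
        return InferenceOptions(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid inference options: {exc}") from exc
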