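"""Experiment configuration loading (TOML or YAML)."""

from __future__ import annotations

import pathlib
import tomllib
from dataclasses import replace

import yaml

from .experiment import (
    BayesBConfig,
    ExperimentConfig,
    GAConfig,
    GenomeConfig,
    HistoricalConfig,
    ROHConfig,
    desk_config,
    paper_config,
)

__all__ = ["load_config"]

_SECTIONS = {
    "genome": GenomeConfig,
    "historical": HistoricalConfig,
    "bayesb": BayesBConfig,
    "ga": GAConfig,
    "roh": ROHConfig,
}


def load_config(path: str | pathlib.Path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a TOML or YAML file.

    An optional top-level ``preset`` key ("desk" or "paper") selects the
    baseline; sections ``[genome] [historical] [bayesb] [ga] [roh]`` and the
    ``[experiment]`` table override individual fields.
    """
    path = pathlib.Path(path)
    if path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    elif path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")
    preset = raw.pop("preset", "paper")
    if preset == "desk":
        cfg = desk_config()
    elif preset == "paper":
        cfg = paper_config()
    else:
        raise ValueError(f"unknown preset {preset!r}")
    overrides = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            overrides[section] = replace(getattr(cfg, section), **raw.pop(section))
    exp = raw.pop("experiment", {})
    for key in ("schemes", "heritabilities"):
        if key in exp:
            exp[key] = tuple(exp[key])
    unknown = set(raw)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    cfg = replace(cfg, **overrides, **exp)
    cfg.validate()
    return cfg
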