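"""YAML run configuration: validation and assembly of the typed configs."""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigurationError
from .evaluate import EvalConfig
from .selectors import (SelectorSpec, get_selector_spec, supervised_pool,
                        unsupervised_pool)
from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "load_config"]

_SECTIONS = {"synthetic", "eval", "selectors", "pools", "exclusion", "log_level"}


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, assembled from YAML."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    selector_overrides: dict[str, dict[str, Any]] = field(default_factory=dict)
    supervised: list[SelectorSpec] = field(default_factory=supervised_pool)
    unsupervised: list[SelectorSpec] = field(default_factory=unsupervised_pool)
    auc_floor: float = 0.5
    time_ceiling: float = 1800.0
    log_level: str = "INFO"

    def spec_with_overrides(self, spec: SelectorSpec) -> SelectorSpec:
        """Apply the config's per-selector hyperparameter overrides."""
        overrides = self.selector_overrides.get(spec.id, {})
        if not overrides:
            return spec
        params = dict(spec.hyperparameters)
        params.update(overrides)
        return dataclasses.replace(spec, hyperparameters=params)


def _build_dataclass(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown keys in config section {section!r}: {sorted(unknown)}"
        )
    return cls(**data)


def load_config(path: str | os.PathLike | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; unknown sections or keys are rejected."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config root must be a mapping, got "
                                     f"{type(data).__name__}")
    if overrides:
        data = {**data, **overrides}

    unknown = set(data) - _SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")

    cfg = RunConfig()
    if "synthetic" in data:
        cfg.synthetic = _build_dataclass(SyntheticConfig,
                                         data["synthetic"] or {}, "synthetic")
        cfg.synthetic.validate()
    if "eval" in data:
        cfg.eval = _build_dataclass(EvalConfig, data["eval"] or {}, "eval")
        cfg.eval.validate()
    if "selectors" in data:
        sel = data["selectors"] or {}
        if not isinstance(sel, dict):
            raise ConfigurationError("'selectors' must map selector id -> params")
        cfg.selector_overrides = {
            get_selector_spec(k).id: dict(v or {}) for k, v in sel.items()
        }
    if "pools" in data:
        pools = data["pools"] or {}
        bad = set(pools) - {"supervised", "unsupervised"}
        if bad:
            raise ConfigurationError(f"unknown pool keys: {sorted(bad)}")
        if "supervised" in pools:
            cfg.supervised = [get_selector_spec(s) for s in pools["supervised"]]
        if "unsupervised" in pools:
            cfg.unsupervised = [get_selector_spec(s) for s in pools["unsupervised"]]
        for spec in cfg.supervised:
            if spec.kind != "supervised":
                raise ConfigurationError(f"{spec.id} is not a supervised selector")
        for spec in cfg.unsupervised:
            if spec.kind != "unsupervised":
                raise ConfigurationError(f"{spec.id} is not an unsupervised selector")
    if "exclusion" in data:
        excl = data["exclusion"] or {}
        bad = set(excl) - {"auc_floor", "time_ceiling"}
        if bad:
            raise ConfigurationError(f"unknown exclusion keys: {sorted(bad)}")
        cfg.auc_floor = float(excl.get("auc_floor", cfg.auc_floor))
        cfg.time_ceiling = float(excl.get("time_ceiling", cfg.time_ceiling))
    if "log_level" in data:
        cfg.log_level = str(data["log_level"])
    return cfg
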