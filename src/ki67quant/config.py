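"""Flat dotted-key pipeline configuration.

One file (YAML) configures every stage; unknown keys are rejected by
name so typos fail loudly.  CLI flags override file values, file values
override the documented defaults, and every run logs the fully resolved
configuration next to its outputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULTS: dict = {
    "preprocess.window_radius": 5,
    "preprocess.gaussian_sigma": None,   # None -> window_radius / 3
    "features.excess_kurtosis": False,
    "cluster.seed": 42,
    "cluster.tol": 1e-4,
    "cluster.max_iter": 300,
    "cluster.restarts": 5,
    "cluster.subsample_n": 50_000,
    "morphology.min_area": 100,
    "morphology.h_maxima": 1.0,
    "morphology.relief": "neg_distance",
    "grading.bands": [5.0, 25.0, 50.0, 100.0],
    "overlay.dab_color": [230, 126, 34],
    "overlay.hema_color": [142, 68, 173],
}


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved flat configuration with attribute-free dotted access."""

    values: dict = dc_field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def get(self, key: str):
        if key not in self.values:
            raise ConfigError(f"unknown configuration key: {key}")
        return self.values[key]

    def with_overrides(self, overrides: dict | None) -> "PipelineConfig":
        if not overrides:
            return self
        merged = copy.deepcopy(self.values)
        for key, value in overrides.items():
            if key not in DEFAULTS:
                raise ConfigError(f"unknown configuration key: {key}")
            merged[key] = value
        return PipelineConfig(values=merged)

    def as_dict(self) -> dict:
        return copy.deepcopy(self.values)


def _flatten(tree: dict, prefix: str = "") -> dict:
    """Allow nested YAML sections as well as literal dotted keys."""
    flat = {}
    for key, value in tree.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, prefix=f"{dotted}."))
        else:
            flat[dotted] = value
    return flat


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Defaults, overlaid with an optional YAML file, then explicit overrides."""
    cfg = PipelineConfig()
    if path is not None:
        try:
            tree = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if tree is None:
            tree = {}
        if not isinstance(tree, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = cfg.with_overrides(_flatten(tree))
    return cfg.with_overrides(overrides)
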