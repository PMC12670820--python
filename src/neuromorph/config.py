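"""YAML/JSON run configuration.

One file mirrors every tunable stage: cohort spec, feature bank,
morphometry and statistics.  Unknown keys are rejected; every run can dump
the fully resolved configuration back to disk for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .features import FeatureConfig
from .morphometry import MorphometryConfig
from .pipeline import PipelineConfig
from .stats import StatsConfig
from .synthetic import CohortSpec

__all__ = ["load_run_config", "dump_run_config", "resolved_config_dict"]

_SECTIONS = ("cohort", "features", "morphometry", "stats", "pipeline")


def load_run_config(path: str | Path | None = None, overrides: dict | None = None):
    """Build (CohortSpec, PipelineConfig) from a YAML/JSON file.

    Missing sections fall back to package defaults; ``overrides`` (same
    nested layout) wins over the file.
    """
    raw: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        raw = (
            json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        ) or {}
    for section, values in (overrides or {}).items():
        raw.setdefault(section, {}).update(values)
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    def section(name):
        d = dict(raw.get(name) or {})
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return d

    spec = CohortSpec(**section("cohort"))
    pipeline = PipelineConfig(
        feature_config=FeatureConfig(**section("features")),
        morphometry=MorphometryConfig(**section("morphometry")),
        stats=StatsConfig(**section("stats")),
        **section("pipeline"),
    )
    return spec, pipeline


def resolved_config_dict(spec: CohortSpec, config: PipelineConfig) -> dict:
    """The fully resolved configuration, JSON/YAML-serializable."""
    return dict(
        cohort={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(spec).items()},
        features={k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in vars(config.feature_config).items()},
        morphometry=asdict(config.morphometry),
        stats=asdict(config.stats),
        pipeline=dict(
            n_trees=config.n_trees,
            max_pixels_per_class=config.max_pixels_per_class,
        ),
    )


def dump_run_config(spec: CohortSpec, config: PipelineConfig, path: str | Path) -> Path:
    """Write the resolved configuration echo next to a run's outputs."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(resolved_config_dict(spec, config), fh, sort_keys=False)
    return path
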