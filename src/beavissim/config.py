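"""Structured run configuration (YAML) with strict validation.

A saved :class:`RunConfig` re-runs to identical outputs: it carries the
global seed, the panel-generator overrides, the null-scan settings and the
experiment grid.  Unknown keys are rejected with their full field path, so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["ConfigError", "ThresholdConfig", "ExperimentSection", "RunConfig",
           "load_config", "save_config"]


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, path: str = ""):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        where = f"{path}." if path else ""
        raise ConfigError(f"unknown key(s): {', '.join(where + k for k in sorted(unknown))}")
    kwargs = {}
    for name, f in allowed.items():
        if name not in data:
            continue
        val = data[name]
        sub = _NESTED.get((cls, name))
        if sub is not None:
            val = _from_dict(sub, val, f"{path}.{name}" if path else name)
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[name] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path or cls.__name__}: {e}") from e


@dataclass
class ThresholdConfig:
    n_scans: int = 2000
    alpha: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_scans < 20:
            raise ValueError("n_scans must be at least 20")


@dataclass
class ExperimentSection:
    sample_sizes: tuple[int, ...] = (100, 185, 500, 878)
    z_grid: tuple[float, ...] = (0.05, 0.10, 0.20)
    kind: str = "biallelic"
    base_replicates: int = 1000
    min_detections: int = 30
    escalation_cap: int = 6

    def __post_init__(self):
        if self.kind not in ("biallelic", "multiallelic"):
            raise ValueError("kind must be 'biallelic' or 'multiallelic'")
        if any(not (0.0 < z < 1.0) for z in self.z_grid):
            raise ValueError("z values must lie in (0, 1)")


@dataclass
class RunConfig:
    seed: int = 0
    design: str = "mpp"
    out_dir: str = "results"
    verbosity: int = 1
    panel: dict = field(default_factory=dict)  # PanelConfig overrides
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    experiment: ExperimentSection = field(default_factory=ExperimentSection)

    def __post_init__(self):
        if self.design not in ("gwas", "mpp"):
            raise ValueError("design must be 'gwas' or 'mpp'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["experiment"]["sample_sizes"] = list(self.experiment.sample_sizes)
        d["experiment"]["z_grid"] = list(self.experiment.z_grid)
        return d


_NESTED = {
    (RunConfig, "thresholds"): ThresholdConfig,
    (RunConfig, "experiment"): ExperimentSection,
}


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _from_dict(RunConfig, data or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
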