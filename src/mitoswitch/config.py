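"""Run configuration and manifests for reproducible pipelines.

A config file is a small YAML mapping with up to four sections —
``params`` (rate-constant overrides), ``population`` (median/sd/
n_quantiles/n_cells/seed), ``classification`` (mitotic_threshold,
endpoint_time) and ``generator`` (n_cells, n_repeats, seed) — all
optional.  Unknown sections or keys are rejected by name: almost every
such key is a typo of a rate constant.  Every CLI run writes a manifest
JSON next to its outputs recording the command, the resolved config, the
parameter-set hash and all seeds, so any output can be regenerated
exactly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .params import PARAM_NAMES, ParameterSet, default_parameters
from .population import PopulationSpec
from .simulate import ClassificationConfig

__all__ = ["RunConfig", "RunManifest", "load_config"]

_SECTIONS = {
    "params": set(PARAM_NAMES),
    "population": {"median", "sd", "n_quantiles", "n_cells", "seed"},
    "classification": {"mitotic_threshold", "endpoint_time"},
    "generator": {"n_cells", "n_repeats", "seed"},
}


@dataclass(frozen=True)
class RunConfig:
    params: ParameterSet
    population: PopulationSpec
    classification: ClassificationConfig
    generator: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or an empty file yields
    the canonical defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
    unknown_sections = set(raw) - set(_SECTIONS)
    if unknown_sections:
        raise ValueError(f"unknown config section(s): {', '.join(sorted(unknown_sections))}")
    for section, keys in _SECTIONS.items():
        body = raw.get(section) or {}
        if not isinstance(body, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        bad = set(body) - keys
        if bad:
            raise ValueError(
                f"unknown key(s) in section {section!r}: {', '.join(sorted(bad))}")

    params = default_parameters().with_(
        **{k: float(v) for k, v in (raw.get("params") or {}).items()})
    population = PopulationSpec(**(raw.get("population") or {}))
    classification = ClassificationConfig(**(raw.get("classification") or {}))
    return RunConfig(params=params, population=population,
                     classification=classification,
                     generator=dict(raw.get("generator") or {}), raw=raw)


@dataclass
class RunManifest:
    command: str
    config: dict
    params_digest: str
    seeds: dict
    package_version: str
    timestamp: str = ""
    platform: str = ""

    @classmethod
    def create(cls, command: str, config: RunConfig, seeds: dict) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config=config.raw,
            params_digest=config.params.digest(),
            seeds={k: int(v) for k, v in seeds.items()},
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            platform=platform.platform(),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
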