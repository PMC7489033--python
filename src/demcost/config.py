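"""YAML configuration loading for the pipeline.

A single config file can hold three sections — ``costs``, ``simulation``
and ``generator`` — whose keys mirror the corresponding dataclass fields.
Missing sections or keys fall back to the model defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml

from .costs import CostParameters
from .errors import ConfigurationError
from .projection import SimulationConfig
from .registry import GeneratorConfig

__all__ = ["load_config", "cost_parameters_from_dict", "simulation_config_from_dict",
           "generator_config_from_dict", "PipelineConfig"]


class PipelineConfig:
    """Bundle of the three configurable stages."""

    def __init__(
        self,
        costs: CostParameters,
        simulation: SimulationConfig,
        generator: GeneratorConfig,
    ) -> None:
        self.costs = costs
        self.simulation = simulation
        self.generator = generator


def _only_known(section: dict[str, Any], cls: type, name: str) -> dict[str, Any]:
    known = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
    unknown = set(section) - known
    if unknown:
        raise ConfigurationError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return section


def cost_parameters_from_dict(section: dict[str, Any]) -> CostParameters:
    return CostParameters(**_only_known(dict(section), CostParameters, "costs"))


def simulation_config_from_dict(section: dict[str, Any]) -> SimulationConfig:
    return SimulationConfig(**_only_known(dict(section), SimulationConfig, "simulation"))


def generator_config_from_dict(section: dict[str, Any]) -> GeneratorConfig:
    section = dict(section)
    if "true_matrix" in section:
        section["true_matrix"] = np.asarray(section["true_matrix"], dtype=float)
    return GeneratorConfig(**_only_known(section, GeneratorConfig, "generator"))


def load_config(path: Optional[Union[str, Path]] = None) -> PipelineConfig:
    """Load a pipeline config; ``None`` returns all defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must hold a mapping at top level")
    return PipelineConfig(
        costs=cost_parameters_from_dict(data.get("costs", {})),
        simulation=simulation_config_from_dict(data.get("simulation", {})),
        generator=generator_config_from_dict(data.get("generator", {})),
    )
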