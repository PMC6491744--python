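"""Experiment configuration schema (YAML/JSON) and network builders."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .grid_modules import GridModuleParams
from .location_layer import LocationLayerParams
from .network import Network, NetworkConfig
from .sensory_layer import SensoryLayerParams
from .synthetic_objects import generate_objects, make_feature_encoding

__all__ = ["Config", "ModulesConfig", "SensoryConfig", "ThresholdsConfig",
           "ObjectsConfig", "RunConfig", "build_network", "build_world"]


@dataclass(frozen=True)
class ModulesConfig:
    """Location-layer geometry.

    ``scale_policy='half_object_width'`` sets every module's scale to half
    the coordinate span of the object grid (the 4x4 unit-spaced grid has
    width 3, so scale 1.5); an explicit ``scale`` overrides it.  ``sigma``
    and ``delta_phi`` default to the w=6 entorhinal baseline rescaled to keep
    the bump a fixed size relative to the cells.
    """

    n: int = 10
    cells_per_axis: int = 10
    scale_policy: str = "half_object_width"
    scale: float | None = None
    sigma: float | None = None
    delta_phi: float | None = None


@dataclass(frozen=True)
class SensoryConfig:
    columns: int = 150
    cells_per_column: int = 16
    feature_sparsity: int = 10


@dataclass(frozen=True)
class ThresholdsConfig:
    theta_loc: int = 8
    theta_in_fraction: float = 0.8


@dataclass(frozen=True)
class ObjectsConfig:
    num: int = 50
    points: int = 10
    grid: int = 4
    pool: int = 40
    distribution: str = "uniform"


@dataclass(frozen=True)
class RunConfig:
    passes_limit: int = 4
    seeds: int = 10
    traversals_per_object: int = 1


@dataclass(frozen=True)
class Config:
    modules: ModulesConfig = field(default_factory=ModulesConfig)
    sensory: SensoryConfig = field(default_factory=SensoryConfig)
    thresholds: ThresholdsConfig = field(default_factory=ThresholdsConfig)
    objects: ObjectsConfig = field(default_factory=ObjectsConfig)
    run: RunConfig = field(default_factory=RunConfig)

    # -- construction --------------------------------------------------

    @staticmethod
    def from_dict(data: dict) -> "Config":
        sections = {
            "modules": ModulesConfig,
            "sensory": SensoryConfig,
            "thresholds": ThresholdsConfig,
            "objects": ObjectsConfig,
            "run": RunConfig,
        }
        kwargs = {}
        for name, cls in sections.items():
            kwargs[name] = cls(**data.get(name, {}))
        unknown = set(data) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return Config(**kwargs)

    @staticmethod
    def from_file(path) -> "Config":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return Config.from_dict(yaml.safe_load(text) or {})
        return Config.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **section_overrides) -> "Config":
        """Copy with per-section field overrides, e.g.
        ``cfg.with_(modules={'cells_per_axis': 20}, objects={'pool': 10})``."""
        updates = {}
        for name, fields in section_overrides.items():
            updates[name] = replace(getattr(self, name), **fields)
        return replace(self, **updates)

    # -- derived quantities --------------------------------------------

    @property
    def module_scale(self) -> float:
        if self.modules.scale is not None:
            return self.modules.scale
        if self.modules.scale_policy == "half_object_width":
            return (self.objects.grid - 1) / 2.0
        raise ValueError(f"unknown scale policy: {self.modules.scale_policy!r}")

    @property
    def theta_in(self) -> int:
        return int(np.ceil(self.modules.n * self.thresholds.theta_in_fraction))

    def network_config(self) -> NetworkConfig:
        m = self.modules
        if m.sigma is not None or m.delta_phi is not None:
            sigma = m.sigma if m.sigma is not None else 0.18172 * 6 / m.cells_per_axis
            dphi = (
                m.delta_phi
                if m.delta_phi is not None
                else (1.0 / 3.0) * 6 / m.cells_per_axis
            )
            mods = tuple(
                GridModuleParams(
                    scale=self.module_scale,
                    orientation=i * 60.0 / m.n,
                    cells_per_axis=m.cells_per_axis,
                    bump_sigma=sigma,
                    readout_resolution=dphi,
                )
                for i in range(m.n)
            )
            location = LocationLayerParams(mods, self.thresholds.theta_loc)
        else:
            location = LocationLayerParams.default(
                num_modules=m.n,
                cells_per_axis=m.cells_per_axis,
                scale=self.module_scale,
                dendrite_threshold=self.thresholds.theta_loc,
            )
        sensory = SensoryLayerParams(
            num_minicolumns=self.sensory.columns,
            cells_per_column=self.sensory.cells_per_column,
            dendrite_threshold=self.theta_in,
        )
        return NetworkConfig(location=location, sensory=sensory, max_passes=self.run.passes_limit)


def build_world(config: Config, rng: np.random.Generator):
    """Generate the object set and feature encoding a config describes."""
    objects = generate_objects(
        num_objects=config.objects.num,
        points_per_object=config.objects.points,
        grid_size=config.objects.grid,
        pool_size=config.objects.pool,
        feature_distribution=config.objects.distribution,
        rng=rng,
    )
    encoding = make_feature_encoding(
        pool_size=config.objects.pool,
        num_minicolumns=config.sensory.columns,
        sparsity=config.sensory.feature_sparsity,
        rng=rng,
    )
    return objects, encoding


def build_network(config: Config, encoding) -> Network:
    return Network(config.network_config(), encoding)
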