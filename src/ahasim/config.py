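"""Run configuration: structured text in, validated dataclasses out.

Config files are YAML with one block per subsystem (world, architecture,
agent, actions, evolution, metrics) plus a master seed and the agent mode.
Validation is fail-fast: unknown keys and violated invariants raise
:class:`ConfigurationError` naming the offending key, before any simulation
starts.  The fully resolved config (all defaults filled in) round-trips
through ``to_dict``/``from_dict`` and is what output artifacts embed for
provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .agent import AgentConfig
from .cognition import Architecture, CircuitSpec
from .environment import FoodZone, WorldConfig
from .errors import ConfigurationError
from .evolution import EvolutionConfig
from .genome import FIELD_RANGES
from .perception import AGENT_MODES

__all__ = ["MetricsConfig", "RunConfig", "load_config"]


@dataclass
class MetricsConfig:
    arousal_threshold: float = 0.7
    k: int = 10                  # steps before/after a switch for the reduction test
    entropy_window: int = 50
    min_bout: int = 20
    d_max: int = 5
    arousal_tol: float = 0.05


@dataclass
class RunConfig:
    seed: int = 0
    mode: str = "full_workspace"
    lifespan: int = 300
    world: WorldConfig = field(default_factory=WorldConfig)
    architecture: Optional[Architecture] = None   # None -> default architecture
    agent: AgentConfig = field(default_factory=AgentConfig)
    action_costs: dict[str, float] = field(default_factory=dict)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    genome_overrides: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in AGENT_MODES:
            raise ConfigurationError(f"mode: unknown agent mode {self.mode!r}")
        if self.lifespan < 0:
            raise ConfigurationError("lifespan: must be >= 0")
        self.world.validate()
        self.evolution.validate()
        for key, v in self.genome_overrides.items():
            base = key.rsplit(".", 1)[-1]
            if base not in FIELD_RANGES:
                raise ConfigurationError(f"genome_overrides.{key}: unknown genome field")
            lo, hi = FIELD_RANGES[base]
            if not lo <= v <= hi:
                raise ConfigurationError(
                    f"genome_overrides.{key}: {v} outside legal range [{lo}, {hi}]")
        g = self.genome_overrides
        if ("hysteresis_lo" in g and "hysteresis_hi" in g
                and g["hysteresis_lo"] > g["hysteresis_hi"]):
            raise ConfigurationError(
                "genome_overrides.hysteresis_lo exceeds genome_overrides.hysteresis_hi")
        for a, c in self.action_costs.items():
            if c < 0:
                raise ConfigurationError(f"action_costs.{a}: must be >= 0")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "mode": self.mode,
            "lifespan": self.lifespan,
            "world": _world_to_dict(self.world),
            "agent": dataclasses.asdict(self.agent),
            "action_costs": dict(self.action_costs),
            "evolution": _evo_to_dict(self.evolution),
            "metrics": dataclasses.asdict(self.metrics),
            "genome_overrides": dict(self.genome_overrides),
        }
        if self.architecture is not None:
            d["architecture"] = {
                "circuits": [{"id": c.circuit_id, "valence": c.valence,
                              "modalities": list(c.modalities)}
                             for c in self.architecture.circuits],
                "priority": list(self.architecture.priority),
                "evolve_modulators": self.architecture.evolve_modulators,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {"seed", "mode", "lifespan", "world", "architecture", "agent",
                 "action_costs", "evolution", "metrics", "genome_overrides"}
        for key in d:
            if key not in known:
                raise ConfigurationError(f"unknown config key {key!r}")
        cfg = cls(
            seed=int(d.get("seed", 0)),
            mode=d.get("mode", "full_workspace"),
            lifespan=int(d.get("lifespan", 300)),
            world=_world_from_dict(d.get("world", {})),
            architecture=_arch_from_dict(d["architecture"]) if "architecture" in d else None,
            agent=_build(AgentConfig, d.get("agent", {}), "agent"),
            action_costs=dict(d.get("action_costs", {})),
            evolution=_evo_from_dict(d.get("evolution", {})),
            metrics=_build(MetricsConfig, d.get("metrics", {}), "metrics"),
            genome_overrides=dict(d.get("genome_overrides", {})),
        )
        cfg.validate()
        return cfg


def _build(cls, d: dict, block: str):
    names = {f.name for f in dataclasses.fields(cls)}
    for key in d:
        if key not in names:
            raise ConfigurationError(f"unknown config key {block}.{key!r}")
    kwargs = dict(d)
    if "start_pos" in kwargs and kwargs["start_pos"] is not None:
        kwargs["start_pos"] = tuple(kwargs["start_pos"])
    return cls(**kwargs)


def _world_to_dict(w: WorldConfig) -> dict:
    d = dataclasses.asdict(w)
    d["food_zones"] = [dataclasses.asdict(z) for z in w.food_zones]
    d["water_cells"] = [list(c) for c in w.water_cells]
    if w.predator_home is not None:
        d["predator_home"] = list(w.predator_home)
    return d


def _world_from_dict(d: dict) -> WorldConfig:
    d = dict(d)
    if "food_zones" in d:
        d["food_zones"] = [_build(FoodZone, z, "world.food_zones") for z in d["food_zones"]]
    if d.get("predator_home") is not None:
        d["predator_home"] = tuple(d["predator_home"])
    if "water_cells" in d:
        d["water_cells"] = [tuple(c) for c in d["water_cells"]]
    return _build(WorldConfig, d, "world")


def _evo_to_dict(e: EvolutionConfig) -> dict:
    d = dataclasses.asdict(e)
    d["fitness_weights"] = list(e.fitness_weights)
    return d


def _evo_from_dict(d: dict) -> EvolutionConfig:
    d = dict(d)
    if "fitness_weights" in d:
        d["fitness_weights"] = tuple(d["fitness_weights"])
    return _build(EvolutionConfig, d, "evolution")


def _arch_from_dict(d: dict) -> Architecture:
    known = {"circuits", "priority", "evolve_modulators"}
    for key in d:
        if key not in known:
            raise ConfigurationError(f"unknown config key architecture.{key!r}")
    circuits = []
    for c in d.get("circuits", []):
        for key in c:
            if key not in {"id", "valence", "modalities"}:
                raise ConfigurationError(f"unknown config key architecture.circuits.{key!r}")
        circuits.append(CircuitSpec(circuit_id=c["id"],
                                    valence=c.get("valence", "negative"),
                                    modalities=tuple(c["modalities"])))
    return Architecture(circuits=tuple(circuits),
                        priority=tuple(d.get("priority", ())),
                        evolve_modulators=bool(d.get("evolve_modulators", True)))


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run-config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    return RunConfig.from_dict(data)
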