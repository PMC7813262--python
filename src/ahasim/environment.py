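"""The virtual world: a toroidal grid with stochastic food, a roaming
predator, optional water, and the stimulus field each agent senses.

The world is deliberately minimal — just enough geometry for approach/avoid
behaviour to have consequences.  Distances are toroidal Chebyshev (8-neighbour
moves), and stimulus magnitude falls off with distance through a bounded
kernel, by default ``1 / (1 + d)``.

Stimulus modalities
-------------------
``food_cue``, ``predator_cue``, ``water_cue``, ``conspecific_cue`` are
external; ``gut_emptiness`` (``1 - energy/energy_max``) and ``thirst_level``
(``1 - hydration``) are generated internally by the sensing agent;
``ambiguous_cue`` is zero in the world and injected only by the experiment
harness as a probe stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError

EXTERNAL_MODALITIES = ("food_cue", "predator_cue", "water_cue", "conspecific_cue")
INTERNAL_MODALITIES = ("gut_emptiness", "thirst_level")
PROBE_MODALITIES = ("ambiguous_cue",)
MODALITIES = EXTERNAL_MODALITIES + INTERNAL_MODALITIES + PROBE_MODALITIES

Cell = tuple[int, int]

# 8-neighbour (Chebyshev) move set, fixed order for deterministic tie-breaks
NEIGHBOUR_STEPS: tuple[Cell, ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
)


@dataclass
class FoodZone:
    """A rectangular patch with its own arrival rate and item value."""

    x0: int
    y0: int
    x1: int  # inclusive
    y1: int  # inclusive
    rate: float
    value: float

    def cells(self) -> list[Cell]:
        return [(x, y) for x in range(self.x0, self.x1 + 1) for y in range(self.y0, self.y1 + 1)]


@dataclass
class WorldConfig:
    width: int = 15
    height: int = 15
    # food
    food_rate: float = 0.15          # Poisson arrivals per step, whole grid
    food_value: float = 12.0         # energy units per item
    initial_food: int = 8
    food_zones: list[FoodZone] = field(default_factory=list)  # if set, replaces uniform arrivals
    phantom_food_cue: float = 0.0    # constant food cue with no corresponding item (unsatisfiable need)
    # predator
    predator: bool = True
    predator_bias: float = 0.3       # probability of stepping toward nearest agent
    predator_home: Optional[Cell] = None  # if set, predator stays within predator_range of home
    predator_range: int = 2
    p_capture: float = 0.12          # capture probability when within distance 1
    freeze_capture_factor: float = 0.3  # multiplier on p_capture if prey just froze
    # water
    water: bool = False
    water_everywhere: bool = False
    water_cells: list[Cell] = field(default_factory=list)
    # sensing
    noise_sd: float = 0.0            # Gaussian perceptual noise, applied to every modality
    kernel: str = "inverse"          # "inverse": 1/(1+d); "exp": exp(-d/exp_scale)
    exp_scale: float = 3.0

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ConfigurationError("grid dimensions must be >= 1")
        if self.food_rate < 0:
            raise ConfigurationError("food_rate must be >= 0")
        if not 0.0 <= self.predator_bias <= 1.0:
            raise ConfigurationError("predator_bias must lie in [0, 1]")
        if not 0.0 <= self.p_capture <= 1.0:
            raise ConfigurationError("p_capture must lie in [0, 1]")
        if self.kernel not in ("inverse", "exp"):
            raise ConfigurationError(f"unknown stimulus kernel {self.kernel!r}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class InternalState:
    """The sensing agent's physiology, source of the internal modalities."""

    energy: float
    energy_max: float
    hydration: float = 1.0
    alive: bool = True

    @property
    def gut_emptiness(self) -> float:
        return min(1.0, max(0.0, 1.0 - self.energy / self.energy_max))

    @property
    def thirst_level(self) -> float:
        return min(1.0, max(0.0, 1.0 - self.hydration))


@dataclass
class World:
    config: WorldConfig
    food: dict[Cell, float] = field(default_factory=dict)   # cell -> energy value
    predator_pos: Optional[Cell] = None
    agents: dict[str, Cell] = field(default_factory=dict)
    time: int = 0

    def wrap(self, cell: Cell) -> Cell:
        return (cell[0] % self.config.width, cell[1] % self.config.height)

    def distance(self, a: Cell, b: Cell) -> int:
        return toroidal_chebyshev(a, b, self.config.width, self.config.height)


def toroidal_chebyshev(a: Cell, b: Cell, width: int, height: int) -> int:
    """Chebyshev distance on the torus (symmetric, bounded by half the grid)."""
    dx = abs(a[0] - b[0])
    dy = abs(a[1] - b[1])
    dx = min(dx, width - dx)
    dy = min(dy, height - dy)
    return max(dx, dy)


def stimulus_kernel(d: float, config: WorldConfig) -> float:
    """Bounded, monotone-decreasing stimulus magnitude at distance ``d``."""
    if config.kernel == "exp":
        return float(np.exp(-d / config.exp_scale))
    return 1.0 / (1.0 + d)


def make_world(config: WorldConfig, rng: np.random.Generator,
               agents: Optional[dict[str, Cell]] = None) -> World:
    """Initialise a world: seed food, place the predator, register agents."""
    config.validate()
    w = World(config=config, agents=dict(agents or {}))
    if config.predator:
        if config.predator_home is not None:
            w.predator_pos = w.wrap(config.predator_home)
        else:
            w.predator_pos = (int(rng.integers(config.width)), int(rng.integers(config.height)))
    for _ in range(config.initial_food):
        _drop_food(w, rng)
    return w


def _drop_food(world: World, rng: np.random.Generator,
               zone: Optional[FoodZone] = None) -> None:
    cfg = world.config
    if zone is None and cfg.food_zones:
        zone = cfg.food_zones[int(rng.integers(len(cfg.food_zones)))]
    if zone is not None:
        cells = zone.cells()
        cell = world.wrap(cells[int(rng.integers(len(cells)))])
        value = zone.value
    else:
        cell = (int(rng.integers(cfg.width)), int(rng.integers(cfg.height)))
        value = cfg.food_value
    world.food[cell] = world.food.get(cell, 0.0) + value


def step_world(world: World, rng: np.random.Generator) -> World:
    """Advance world dynamics one timestep (in place; also returned).

    Food arrives as Poisson events; the predator performs a biased random
    walk toward the nearest agent.  Agent movement, eating and capture are
    applied by the agent loop, not here.
    """
    cfg = world.config
    if cfg.food_zones:
        for zone in cfg.food_zones:
            for _ in range(int(rng.poisson(zone.rate))):
                _drop_food(world, rng, zone)
    elif cfg.food_rate > 0:
        for _ in range(int(rng.poisson(cfg.food_rate))):
            _drop_food(world, rng)
    if cfg.predator and world.predator_pos is not None:
        world.predator_pos = _predator_step(world, rng)
    world.time += 1
    return world


def _toward_step(world: World, src: Cell, dst: Cell) -> Cell:
    """Unit Chebyshev step from src toward dst along the shortest toroidal path."""
    cfg = world.config
    step = []
    for axis, size in ((0, cfg.width), (1, cfg.height)):
        d = (dst[axis] - src[axis]) % size
        if d == 0:
            step.append(0)
        elif d <= size - d:
            step.append(1)
        else:
            step.append(-1)
    return world.wrap((src[0] + step[0], src[1] + step[1]))


def _predator_step(world: World, rng: np.random.Generator) -> Cell:
    cfg = world.config
    pos = world.predator_pos
    assert pos is not None
    if world.agents and rng.random() < cfg.predator_bias:
        target_id = min(world.agents, key=lambda aid: (world.distance(pos, world.agents[aid]), aid))
        nxt = _toward_step(world, pos, world.agents[target_id])
    else:
        dx, dy = NEIGHBOUR_STEPS[int(rng.integers(len(NEIGHBOUR_STEPS)))]
        nxt = world.wrap((pos[0] + dx, pos[1] + dy))
    if cfg.predator_home is not None:
        home = world.wrap(cfg.predator_home)
        if world.distance(nxt, home) > cfg.predator_range:
            return pos  # leash: refuse moves that leave the home range
    return nxt


def emit_stimuli(world: World, agent_id: str, internal: InternalState,
                 rng: Optional[np.random.Generator] = None) -> dict[str, float]:
    """The raw stimulus field an agent senses at its current position.

    External cues sum a distance kernel over sources (clamped to [0, 1]);
    internal cues read the agent's physiology.  With ``noise_sd > 0`` every
    modality receives independent Gaussian noise before clamping, which
    requires ``rng``; with ``noise_sd == 0`` the field is deterministic.
    """
    cfg = world.config
    if agent_id not in world.agents:
        raise LookupError(f"agent {agent_id!r} not present in world")
    pos = world.agents[agent_id]

    food_cue = cfg.phantom_food_cue
    for cell in world.food:
        food_cue += stimulus_kernel(world.distance(pos, cell), cfg)

    if cfg.predator and world.predator_pos is not None:
        predator_cue = stimulus_kernel(world.distance(pos, world.predator_pos), cfg)
    else:
        predator_cue = 0.0

    water_cue = 0.0
    if cfg.water:
        if cfg.water_everywhere:
            water_cue = 1.0
        elif cfg.water_cells:
            water_cue = max(stimulus_kernel(world.distance(pos, world.wrap(c)), cfg)
                            for c in cfg.water_cells)

    conspecific_cue = 0.0
    others = [c for aid, c in world.agents.items() if aid != agent_id]
    if others:
        conspecific_cue = max(stimulus_kernel(world.distance(pos, c), cfg) for c in others)

    s = {
        "food_cue": food_cue,
        "predator_cue": predator_cue,
        "water_cue": water_cue,
        "conspecific_cue": conspecific_cue,
        "gut_emptiness": internal.gut_emptiness,
        "thirst_level": internal.thirst_level,
        "ambiguous_cue": 0.0,
    }
    if cfg.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        for m in MODALITIES:
            s[m] = s[m] + float(rng.normal(0.0, cfg.noise_sd))
    return {m: min(1.0, max(0.0, v)) for m, v in s.items()}
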