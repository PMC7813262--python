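"""The per-timestep life of one agent in one world.

Each step: sense → attend → appraise (motivation competition, realized
arousal, prediction error of the previous decision) → dissipate → select an
action by re-entrant prediction → act (movement, eating, drinking, energy
costs) → world dynamics advance → capture check.  Every step appends one
row to the agent trace, the observable surface all welfare metrics are
computed from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .actions import (ActionRepertoire, DecisionRecord, ForwardModel,
                      record_prediction_error, select_action)
from .cognition import Architecture, GOSState, appraise, dissipate, initial_gos
from .environment import (MODALITIES, NEIGHBOUR_STEPS, InternalState, World,
                          WorldConfig, emit_stimuli, make_world, step_world)
from .errors import DeadEndError
from .perception import attend
from .rng import child_rng

__all__ = ["AgentConfig", "SimHooks", "SimResult", "simulate_agent", "trace_columns"]


@dataclass
class AgentConfig:
    energy_max: float = 100.0
    initial_energy: float = 60.0
    dehydration_rate: float = 0.0   # hydration loss per step (0 disables thirst dynamics)
    start_pos: Optional[tuple[int, int]] = None


@dataclass
class SimHooks:
    """Experiment-harness intervention points (all optional).

    ``stimulus_override`` clamps chosen modalities after sensing (e.g. a
    fixed gut emptiness, or an injected ambiguous probe);  ``gos_hold``
    forces the dominant circuit and arousal after each appraisal (holding an
    agent in a state);  ``dissipation_enabled`` switches the arousal-decay
    mechanism on or off.
    """

    stimulus_override: Optional[dict[str, float]] = None
    gos_hold: Optional[tuple[str, float]] = None
    dissipation_enabled: bool = True


@dataclass
class SimResult:
    trace: Optional[pd.DataFrame]
    survived: bool
    cause_of_death: Optional[str]   # None | "starvation" | "predation"
    internal: InternalState
    steps_lived: int
    world: World


def trace_columns(arch: Architecture) -> list[str]:
    cols = ["t"]
    cols += [f"s_{m}" for m in MODALITIES]
    cols += [f"w_{m}" for m in MODALITIES]
    cols += [f"M_{cid}" for cid in arch.ids]
    cols += ["dominant", "arousal", "predicted_arousal", "action",
             "prediction_error", "energy", "alive"]
    return cols


def _move_toward(world: World, pos, target):
    from .environment import _toward_step
    return _toward_step(world, pos, target)


def _flee_step(world: World, pos):
    """Neighbour cell maximising distance to the predator (deterministic)."""
    best = pos
    best_d = world.distance(pos, world.predator_pos)
    for dx, dy in NEIGHBOUR_STEPS:
        cand = world.wrap((pos[0] + dx, pos[1] + dy))
        d = world.distance(cand, world.predator_pos)
        if d > best_d:
            best, best_d = cand, d
    return best


def _apply_action(world: World, agent_id: str, internal: InternalState,
                  action: str, repertoire: ActionRepertoire, acfg: AgentConfig,
                  rng: np.random.Generator) -> None:
    pos = world.agents[agent_id]
    if action == "eat":
        reachable = [c for c in world.food if world.distance(pos, c) <= 1]
        if reachable:
            cell = min(reachable, key=lambda c: (world.distance(pos, c), c))
            internal.energy = min(acfg.energy_max, internal.energy + world.food[cell])
            del world.food[cell]
            world.agents[agent_id] = cell
    elif action == "approach_food" and world.food:
        target = min(world.food, key=lambda c: (world.distance(pos, c), c))
        world.agents[agent_id] = _move_toward(world, pos, target)
    elif action == "flee" and world.predator_pos is not None:
        world.agents[agent_id] = _flee_step(world, pos)
    elif action == "explore":
        dx, dy = NEIGHBOUR_STEPS[int(rng.integers(len(NEIGHBOUR_STEPS)))]
        world.agents[agent_id] = world.wrap((pos[0] + dx, pos[1] + dy))
    elif action == "drink":
        internal.hydration = 1.0
    # freeze / rest: stay put
    internal.energy -= repertoire.costs.get(action, 0.0)
    if action != "drink":
        internal.hydration = max(0.0, internal.hydration - acfg.dehydration_rate)


def simulate_agent(genome, arch: Architecture, world_config: WorldConfig,
                   mode: str = "full_workspace", lifespan: int = 300,
                   seed: int = 0, *, rng: Optional[np.random.Generator] = None,
                   agent_config: Optional[AgentConfig] = None,
                   repertoire: Optional[ActionRepertoire] = None,
                   forward_model: Optional[ForwardModel] = None,
                   hooks: Optional[SimHooks] = None,
                   collect_trace: bool = True) -> SimResult:
    """Run one agent for up to ``lifespan`` steps (or until death).

    Fully deterministic given ``(genome, configs, seed)``.  When ``rng`` is
    given it is used directly (the caller owns stream derivation).
    """
    rng = rng if rng is not None else child_rng(seed, "agent")
    acfg = agent_config or AgentConfig()
    hooks = hooks or SimHooks()
    repertoire = repertoire or ActionRepertoire()
    fm = forward_model or ForwardModel(
        world_config=world_config, costs=dict(repertoire.costs),
        dehydration_rate=acfg.dehydration_rate, energy_max=acfg.energy_max)

    aid = "a0"
    start = acfg.start_pos or (int(rng.integers(world_config.width)),
                               int(rng.integers(world_config.height)))
    world = make_world(world_config, rng, agents={aid: start})
    internal = InternalState(energy=acfg.initial_energy, energy_max=acfg.energy_max)
    gos = initial_gos(arch)
    rows: list[dict] = [] if collect_trace else None
    prev_dr: Optional[DecisionRecord] = None
    cause = None
    steps = 0

    for t in range(lifespan):
        s = emit_stimuli(world, aid, internal, rng)
        if hooks.stimulus_override:
            for m, v in hooks.stimulus_override.items():
                s[m] = min(1.0, max(0.0, v))
        percept = attend(s, gos, genome, mode, arch)
        motivations, gos = appraise(percept, arch, gos, genome)
        if hooks.gos_hold is not None:
            held_dom, held_a = hooks.gos_hold
            gos = GOSState(dominant=held_dom, arousal=held_a,
                           bout_length=gos.bout_length)
        realized_arousal = gos.arousal
        pe = float("nan")
        if prev_dr is not None:
            pe = record_prediction_error(prev_dr, realized_arousal).prediction_error
        gos = dissipate(gos, genome, enabled=hooks.dissipation_enabled)

        available = repertoire.available(world, aid, internal)
        try:
            action, dr = select_action(available, s, gos, genome, fm, mode,
                                       arch, internal, rng)
        except DeadEndError:
            action, dr = "rest", DecisionRecord(predicted={}, chosen="rest",
                                                predicted_arousal=float("nan"))
        prev_dr = dr

        row = None
        if collect_trace:
            row = {"t": t}
            row.update({f"s_{m}": s[m] for m in MODALITIES})
            row.update({f"w_{m}": percept.weights[m] for m in MODALITIES})
            row.update({f"M_{cid}": motivations[cid] for cid in arch.ids})
            row.update({"dominant": gos.dominant, "arousal": realized_arousal,
                        "predicted_arousal": dr.predicted_arousal, "action": action,
                        "prediction_error": pe, "energy": internal.energy})

        _apply_action(world, aid, internal, action, repertoire, acfg, rng)
        if internal.energy <= 0:
            internal.alive = False
            cause = "starvation"
        step_world(world, rng)
        if (internal.alive and world.config.predator and world.predator_pos is not None
                and world.distance(world.agents[aid], world.predator_pos) <= 1):
            p = world.config.p_capture
            if action == "freeze":
                p *= world.config.freeze_capture_factor
            if rng.random() < p:
                internal.alive = False
                cause = "predation"

        steps = t + 1
        if collect_trace:
            row["alive"] = internal.alive
            rows.append(row)
        if not internal.alive:
            break

    trace = None
    if collect_trace:
        trace = pd.DataFrame(rows, columns=trace_columns(arch))
    return SimResult(trace=trace, survived=internal.alive, cause_of_death=cause,
                     internal=internal, steps_lived=steps, world=world)
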