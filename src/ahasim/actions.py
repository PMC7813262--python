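"""Re-entrant action selection: "what would it feel".

For every available action the agent applies its forward model to obtain the
stimulus field it expects after the action, re-runs the *same* attention and
appraisal machinery (same genome parameters — the unity property of the
workspace), and reads off the predicted arousal.  With a negative-valence
dominant it picks the action with the lowest predicted arousal (highest for
positive valence); exact ties are broken uniformly at random from the seeded
stream.  The purely reactive tier instead uses a fixed reflex table on the
raw stimulus field.

The forward model is the agent's expectation, configured independently of
the true world dynamics; the mismatch between the two is what makes the
prediction error a non-trivial signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cognition import Architecture, GOSState, appraise, motivation
from .environment import InternalState, World, WorldConfig, stimulus_kernel
from .errors import ConfigurationError, DeadEndError, ModeError
from .perception import attend

__all__ = [
    "ACTIONS", "DEFAULT_ACTION_COSTS", "FOOD_CONSISTENT", "DANGER_CONSISTENT",
    "ActionRepertoire", "ForwardModel", "DecisionRecord",
    "predict_arousal", "select_action", "record_prediction_error", "reflex_action",
]

ACTIONS = ("eat", "approach_food", "flee", "freeze", "drink", "explore", "rest")

# Energetic cost per action, in energy units per step.
DEFAULT_ACTION_COSTS: dict[str, float] = {
    "eat": 0.2,
    "approach_food": 0.5,
    "flee": 0.8,
    "freeze": 0.05,
    "drink": 0.2,
    "explore": 0.5,
    "rest": 0.1,
}

# Operational mapping used by the judgement-bias readout.
FOOD_CONSISTENT = frozenset({"eat", "approach_food"})
DANGER_CONSISTENT = frozenset({"flee", "freeze"})


@dataclass(frozen=True)
class ActionRepertoire:
    actions: tuple[str, ...] = ACTIONS
    costs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ACTION_COSTS))

    def __post_init__(self):
        if not self.actions:
            raise ConfigurationError("action repertoire must not be empty")
        for a in self.actions:
            if self.costs.get(a, 0.0) < 0:
                raise ConfigurationError(f"action {a!r} has negative cost")

    def available(self, world: World, agent_id: str, internal: InternalState) -> list[str]:
        """Deterministic availability given world + agent state."""
        cfg = world.config
        pos = world.agents[agent_id]
        out = []
        for a in self.actions:
            if a == "eat":
                # food on the current or an adjacent cell can be taken this step
                ok = any(world.distance(pos, c) <= 1 for c in world.food)
            elif a == "approach_food":
                ok = bool(world.food)
            elif a == "flee":
                ok = cfg.predator and world.predator_pos is not None
            elif a == "drink":
                ok = cfg.water and (
                    cfg.water_everywhere
                    or any(world.distance(pos, world.wrap(c)) <= 1 for c in cfg.water_cells))
            else:  # freeze, explore, rest, (reproduce if configured)
                ok = True
            if ok:
                out.append(a)
        return out


def _kernel_shift(cue: float, delta: int, wcfg: WorldConfig) -> float:
    """Expected cue after the source distance changes by ``delta`` steps.

    Inverts the stimulus kernel at the current cue, shifts the implied
    distance, and re-applies the kernel.  A zero cue stays zero.
    """
    if cue <= 0.0:
        return 0.0
    if cue >= 1.0:
        d = 0.0
    elif wcfg.kernel == "exp":
        d = -wcfg.exp_scale * math.log(cue)
    else:
        d = 1.0 / cue - 1.0
    return min(1.0, stimulus_kernel(max(0.0, d + delta), wcfg))


@dataclass(frozen=True)
class ForwardModel:
    """Per-action deterministic percept-transition expectations.

    ``expected_meal`` is the gut-emptiness reduction the agent expects from
    eating (defaults to the configured food value as a fraction of maximum
    energy); ``freeze_discount`` is the expected predator-cue attenuation
    from freezing (the predator losing track of motionless prey);
    ``dehydration_rate`` is the expected per-step thirst growth.
    """

    world_config: WorldConfig
    costs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ACTION_COSTS))
    expected_meal: Optional[float] = None
    freeze_discount: float = 0.7
    dehydration_rate: float = 0.0
    energy_max: float = 100.0

    def predict(self, s: dict[str, float], internal: InternalState, action: str
                ) -> dict[str, float]:
        """Predicted stimulus field after ``action`` (pure, bounded)."""
        wcfg = self.world_config
        p = dict(s)
        # metabolic bookkeeping every action shares
        cost = self.costs.get(action, 0.0)
        p["gut_emptiness"] = s["gut_emptiness"] + cost / self.energy_max
        p["thirst_level"] = s["thirst_level"] + self.dehydration_rate
        if action == "eat":
            meal = self.expected_meal
            if meal is None:
                meal = wcfg.food_value / self.energy_max
            p["gut_emptiness"] -= meal
            p["food_cue"] = s["food_cue"] * 0.25  # the eaten item is gone
        elif action == "approach_food":
            meal = self.expected_meal
            if meal is None:
                meal = wcfg.food_value / self.energy_max
            cue = _kernel_shift(s["food_cue"], -1, wcfg)
            p["food_cue"] = cue
            # anticipated relief: closing in on food brings the meal into the
            # agent's predicted near future, in proportion to its proximity
            p["gut_emptiness"] -= meal * cue
        elif action == "flee":
            p["predator_cue"] = _kernel_shift(s["predator_cue"], +1, wcfg)
        elif action == "freeze":
            p["predator_cue"] = s["predator_cue"] * self.freeze_discount
        elif action == "drink":
            p["thirst_level"] = 0.0
        # explore / rest: no expected change to external cues
        return {m: min(1.0, max(0.0, v)) for m, v in p.items()}


@dataclass
class DecisionRecord:
    """One action-selection event, including the per-option predictions."""

    predicted: dict[str, float]          # action -> predicted arousal
    chosen: str
    predicted_arousal: float             # prediction for the chosen action (NaN in reactive tier)
    realized_arousal: Optional[float] = None
    prediction_error: Optional[float] = None


def predict_arousal(action: str, s: dict[str, float], gos: GOSState, genome,
                    fm: ForwardModel, mode: str, arch: Architecture,
                    internal: InternalState) -> float:
    """Arousal the agent expects to feel after ``action``.

    Runs the predicted stimuli through the same attention gate and appraisal
    the realized pathway uses (one shared parameter set).  In the
    ``single_reentrant`` tier the prediction runs through the dominant
    circuit only; in ``full_workspace`` the whole competition is re-entered
    and the predicted dominant's arousal is returned.  Pure function.
    """
    if mode == "reactive":
        raise ModeError("the reactive tier has no re-entrant prediction")
    predicted_s = fm.predict(s, internal, action)
    percept = attend(predicted_s, gos, genome, mode, arch)
    if mode == "single_reentrant":
        return motivation(percept, arch.circuit(gos.dominant), genome)
    _, predicted_gos = appraise(percept, arch, gos, genome)
    return predicted_gos.arousal


def reflex_action(s: dict[str, float], available: list[str]) -> str:
    """Fixed stimulus–response table for the reactive tier.

    A deterministic function of the raw stimulus field alone: the strongest
    of the predator/food cues triggers its reflex (flee; eat when standing
    on food, i.e. the cue saturates, otherwise approach), anything else
    explores.  Falls back along a fixed preference order if the reflex
    action is unavailable.
    """
    pred = s.get("predator_cue", 0.0)
    food = s.get("food_cue", 0.0)
    if pred > 0.0 and pred >= food:
        preference = ["flee", "freeze", "explore", "rest"]
    elif food > 0.0:
        if food >= 0.5:  # cue level of food within reach
            preference = ["eat", "approach_food", "explore", "rest"]
        else:
            preference = ["approach_food", "explore", "rest"]
    else:
        preference = ["explore", "rest"]
    for a in preference:
        if a in available:
            return a
    return available[0]


def select_action(available: list[str], s: dict[str, float], gos: GOSState,
                  genome, fm: ForwardModel, mode: str, arch: Architecture,
                  internal: InternalState, rng: np.random.Generator
                  ) -> tuple[str, DecisionRecord]:
    """Choose the next action and record the decision.

    Re-entrant tiers minimise predicted arousal over the available actions
    (maximise, if the dominant circuit has positive valence); exact ties are
    broken uniformly with the seeded stream.  The reactive tier consults the
    reflex table instead and records no predictions.
    """
    if not available:
        raise DeadEndError("no action available")
    if mode == "reactive":
        a = reflex_action(s, available)
        return a, DecisionRecord(predicted={}, chosen=a, predicted_arousal=float("nan"))
    predicted = {
        a: predict_arousal(a, s, gos, genome, fm, mode, arch, internal)
        for a in available
    }
    positive = arch.circuit(gos.dominant).valence == "positive"
    best = max(predicted.values()) if positive else min(predicted.values())
    tied = [a for a in available if predicted[a] == best]
    chosen = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
    return chosen, DecisionRecord(predicted=predicted, chosen=chosen,
                                  predicted_arousal=predicted[chosen])


def record_prediction_error(dr: DecisionRecord, realized_arousal: float) -> DecisionRecord:
    """Fill in the realized arousal and ``|realized - predicted|``."""
    dr.realized_arousal = realized_arousal
    if math.isnan(dr.predicted_arousal):
        dr.prediction_error = float("nan")
    else:
        dr.prediction_error = abs(realized_arousal - dr.predicted_arousal)
    return dr
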