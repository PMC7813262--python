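"""Re-entrant prediction, action selection and prediction error."""

import dataclasses
import math

import numpy as np
import pytest

from ahasim import (ActionRepertoire, DecisionRecord, ForwardModel, GOSState,
                    InternalState, ModeError, WorldConfig, predict_arousal,
                    select_action, simulate_agent)
from ahasim.actions import record_prediction_error, reflex_action
from ahasim.cognition import default_architecture
from ahasim.environment import MODALITIES
from ahasim.errors import DeadEndError
from ahasim.genome import random_genome
from ahasim.rng import child_rng


def frame(**values):
    s = {m: 0.0 for m in MODALITIES}
    s.update(values)
    return s


@pytest.fixture()
def fm():
    return ForwardModel(world_config=WorldConfig())


@pytest.fixture()
def internal():
    return InternalState(energy=40.0, energy_max=100.0)


def test_reactive_mode_has_no_prediction(genome, arch, fm, internal):
    with pytest.raises(ModeError):
        predict_arousal("rest", frame(), GOSState("hunger", 0.5), genome, fm,
                        "reactive", arch, internal)


def test_rest_in_static_world_predicts_current_arousal(arch, fm, internal):
    """With zero action cost, resting predicts exactly the appraised arousal."""
    from ahasim.cognition import appraise
    genome = random_genome(arch, child_rng(1, "g"))
    zero_cost = ForwardModel(world_config=WorldConfig(),
                             costs={a: 0.0 for a in ActionRepertoire().actions})
    s = frame(food_cue=0.3, gut_emptiness=0.6)
    gos = GOSState("hunger", 0.0)  # zero arousal: attention gate fully open
    from ahasim.perception import attend
    _, appraised = appraise(attend(s, gos, genome, "full_workspace", arch),
                            arch, gos, genome)
    predicted = predict_arousal("rest", s, gos, genome, zero_cost,
                                "full_workspace", arch, internal)
    assert predicted == pytest.approx(appraised.arousal)


def test_eating_beats_resting_when_hungry_on_food(genome, arch, fm, internal):
    """Eating strictly reduces gut emptiness, so its predicted arousal is lower."""
    s = frame(food_cue=1.0, gut_emptiness=0.8)
    gos = GOSState("hunger", 0.6)
    a_eat = predict_arousal("eat", s, gos, genome, fm, "full_workspace", arch, internal)
    a_rest = predict_arousal("rest", s, gos, genome, fm, "full_workspace", arch, internal)
    assert a_eat < a_rest


def test_single_reentrant_runs_one_circuit(fm, internal):
    from ahasim.cognition import Architecture, CircuitSpec
    from ahasim.genome import LinkParams, Genome
    arch1 = Architecture(circuits=(
        CircuitSpec("hunger", "negative", ("food_cue", "gut_emptiness")),))
    g = Genome(link_params={("hunger", "food_cue"): LinkParams(1.0, 0.5, 1.0),
                            ("hunger", "gut_emptiness"): LinkParams(1.0, 0.5, 1.0)},
               attention_strength=0.5, hysteresis_lo=0.0, hysteresis_hi=0.1,
               dissipation_rate=0.0, dissipation_onset=10)
    s = frame(food_cue=0.5, gut_emptiness=0.5)
    a = predict_arousal("rest", s, GOSState("hunger", 0.0), g, fm,
                        "single_reentrant", arch1, internal)
    assert 0.0 <= a <= 1.0


class TestSelectAction:
    def test_argmin_of_predicted_arousal(self, genome, arch, fm, internal):
        s = frame(predator_cue=0.8, gut_emptiness=0.2)
        gos = GOSState("fear", 0.7)
        available = ["flee", "rest"]
        action, dr = select_action(available, s, gos, genome, fm,
                                   "full_workspace", arch, internal,
                                   child_rng(0, "sel"))
        assert action == min(available, key=lambda a: dr.predicted[a])

    def test_brute_force_oracle_equivalence(self, arch, fm):
        """select_action == independent exhaustive minimisation, every call."""
        rng = child_rng(7, "oracle")
        for i in range(300):
            genome = random_genome(arch, rng)
            s = {m: float(rng.uniform()) for m in MODALITIES}
            gos = GOSState(arch.ids[int(rng.integers(len(arch.ids)))],
                           float(rng.uniform()))
            internal = InternalState(energy=float(rng.uniform(1, 100)),
                                     energy_max=100.0)
            available = ["eat", "approach_food", "flee", "freeze", "explore", "rest"]
            action, dr = select_action(available, s, gos, genome, fm,
                                       "full_workspace", arch, internal,
                                       child_rng(7, "tie", i))
            # independent oracle: explicit loop over predict_arousal
            best = math.inf
            argmin = []
            for a in available:
                v = predict_arousal(a, s, gos, genome, fm, "full_workspace",
                                    arch, internal)
                if v < best:
                    best, argmin = v, [a]
                elif v == best:
                    argmin.append(a)
            assert action in argmin
            assert dr.predicted_arousal == best

    def test_uniform_tie_break(self, arch, internal):
        """All-equal predictions: each action chosen ~ 1/n of the time."""
        genome = random_genome(arch, child_rng(2, "g"))
        equal_costs = ForwardModel(world_config=WorldConfig(predator=False),
                                   costs={a: 0.1 for a in ("freeze", "explore", "rest")})
        s = frame(gut_emptiness=0.5)
        gos = GOSState("hunger", 0.3)
        available = ["freeze", "explore", "rest"]
        rng = child_rng(3, "ties")
        counts = {a: 0 for a in available}
        n = 6000
        for _ in range(n):
            action, dr = select_action(available, s, gos, genome, equal_costs,
                                       "full_workspace", arch, internal, rng)
            counts[action] += 1
        assert len(set(dr.predicted.values())) == 1  # genuinely tied
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        for a in available:
            assert abs(counts[a] / n - 1 / 3) < 4 * se

    def test_empty_available_raises_dead_end(self, genome, arch, fm, internal):
        with pytest.raises(DeadEndError):
            select_action([], frame(), GOSState("hunger", 0.1), genome, fm,
                          "full_workspace", arch, internal, child_rng(0, "x"))

    def test_reactive_depends_only_on_raw_stimuli(self, genome, arch, fm, internal):
        """Identical frames => identical reflex, whatever the GOS history."""
        rng = child_rng(4, "frames")
        available = ["eat", "approach_food", "flee", "freeze", "explore", "rest"]
        for _ in range(200):
            s = {m: float(rng.uniform()) for m in MODALITIES}
            actions = set()
            for dom in arch.ids:
                for arousal in (0.0, 0.5, 1.0):
                    a, _ = select_action(available, s, GOSState(dom, arousal),
                                         genome, fm, "reactive", arch, internal,
                                         child_rng(0, "t"))
                    actions.add(a)
            assert len(actions) == 1


def test_prediction_error_arithmetic():
    dr = DecisionRecord(predicted={"rest": 0.2}, chosen="rest", predicted_arousal=0.2)
    out = record_prediction_error(dr, 0.5)
    assert out.prediction_error == pytest.approx(0.3)
    out = record_prediction_error(
        DecisionRecord(predicted={}, chosen="rest", predicted_arousal=0.4), 0.4)
    assert out.prediction_error == 0.0


def test_exact_forward_model_gives_zero_error_in_static_world(arch):
    """No noise, no food, no predator: predictions match realized arousal."""
    genome = random_genome(arch, child_rng(5, "g"))
    wcfg = WorldConfig(food_rate=0.0, initial_food=0, predator=False, noise_sd=0.0)
    res = simulate_agent(genome, arch, wcfg, lifespan=100, seed=9)
    pe = res.trace["prediction_error"].to_numpy()
    pe = pe[~np.isnan(pe)]
    assert len(pe) > 0
    assert np.max(pe) < 1e-9


def test_unity_same_parameters_drive_both_pathways(arch, fm, internal):
    """Perturbing one genome parameter shifts appraisal and prediction alike."""
    from ahasim.cognition import appraise
    from ahasim.perception import attend
    g1 = random_genome(arch, child_rng(6, "g"))
    lp = g1.link_params[("hunger", "gut_emptiness")]
    g2 = dataclasses.replace(g1)
    g2.link_params = dict(g1.link_params)
    g2.link_params[("hunger", "gut_emptiness")] = dataclasses.replace(lp, half_sat=lp.half_sat / 2)
    s = frame(gut_emptiness=0.6, food_cue=0.2)
    gos = GOSState("hunger", 0.0)
    realized = {}
    predicted = {}
    for tag, g in (("base", g1), ("perturbed", g2)):
        _, ap = appraise(attend(s, gos, g, "full_workspace", arch), arch, gos, g)
        realized[tag] = ap.arousal
        zero_cost = ForwardModel(world_config=WorldConfig(),
                                 costs={a: 0.0 for a in ActionRepertoire().actions})
        predicted[tag] = predict_arousal("rest", s, gos, g, zero_cost,
                                         "full_workspace", arch, internal)
    # same direction and same magnitude of change through both pathways
    assert realized["perturbed"] != realized["base"]
    assert predicted["perturbed"] - predicted["base"] == pytest.approx(
        realized["perturbed"] - realized["base"])


def test_subjective_divergence_of_identical_genomes():
    """Same genome, identical deterministic worlds, different internal state:
    the agents resolve the food/danger conflict differently and their action
    sequences diverge."""
    from ahasim.agent import AgentConfig, SimHooks
    from ahasim.cognition import Architecture, CircuitSpec
    from ahasim.genome import Genome, LinkParams
    arch = Architecture(circuits=(
        CircuitSpec("hunger", "negative", ("food_cue", "gut_emptiness")),
        CircuitSpec("fear", "negative", ("predator_cue",))))
    lp = LinkParams(gain=2.0, half_sat=0.5, weight=1.0)
    genome = Genome(link_params={("hunger", "food_cue"): lp,
                                 ("hunger", "gut_emptiness"): lp,
                                 ("fear", "predator_cue"): lp},
                    attention_strength=0.8, hysteresis_lo=0.02,
                    hysteresis_hi=0.08, dissipation_rate=0.0,
                    dissipation_onset=60)
    # static conflict frame: food and danger cues held equal for both agents
    wcfg = WorldConfig(food_rate=0.0, initial_food=0, noise_sd=0.0,
                       predator=True, predator_home=(10, 10), predator_range=0)
    hooks = SimHooks(stimulus_override={"food_cue": 0.5, "predator_cue": 0.5})
    runs = []
    for e0 in (95.0, 10.0):
        res = simulate_agent(genome, arch, wcfg, lifespan=40, seed=12,
                             agent_config=AgentConfig(initial_energy=e0,
                                                      start_pos=(3, 3)),
                             hooks=hooks)
        runs.append(res.trace["action"].tolist())
    n = min(len(runs[0]), len(runs[1]))
    assert n > 0 and runs[0][:n] != runs[1][:n]
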