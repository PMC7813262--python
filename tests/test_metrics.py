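"""Welfare metrics on hand-built traces with hand-derived expected values."""

import math

import numpy as np
import pandas as pd
import pytest

from ahasim.metrics import (ambiguity_bias, behavioural_entropy,
                            detect_displacement, stress_index, summarize)
from ahasim.rng import child_rng


def make_trace(actions=None, dominant=None, arousal=None, pe=None):
    n = max(len(x) for x in (actions, dominant, arousal) if x is not None)
    df = pd.DataFrame({
        "t": range(n),
        "action": actions if actions is not None else ["rest"] * n,
        "dominant": dominant if dominant is not None else ["hunger"] * n,
        "arousal": arousal if arousal is not None else [0.5] * n,
        "prediction_error": pe if pe is not None else [0.0] * n,
    })
    return df


class TestBehaviouralEntropy:
    def test_degenerate_distribution_zero_bits(self):
        t = make_trace(actions=["rest"] * 40)
        assert behavioural_entropy(t, window=10).max() == 0.0

    def test_uniform_four_actions_two_bits(self):
        t = make_trace(actions=["eat", "flee", "rest", "explore"] * 10)
        ent = behavioural_entropy(t, window=40)
        assert ent.iloc[0] == pytest.approx(2.0)

    def test_half_quarter_quarter_is_1_5_bits(self):
        actions = ["eat"] * 2 + ["flee"] + ["rest"]
        t = make_trace(actions=actions * 5)
        ent = behavioural_entropy(t, window=len(t))
        assert ent.iloc[0] == pytest.approx(1.5)

    def test_window_longer_than_trace_gives_single_value(self):
        t = make_trace(actions=["eat", "rest"] * 3)
        ent = behavioural_entropy(t, window=100)
        assert len(ent) == 1 and ent.iloc[0] == pytest.approx(1.0)

    def test_bounded_by_log2_distinct_actions(self):
        rng = child_rng(1, "ent")
        acts = [str(rng.integers(5)) for _ in range(200)]
        for h in behavioural_entropy(make_trace(actions=acts), window=20):
            assert 0.0 <= h <= math.log2(5) + 1e-12


class TestStressIndex:
    def test_calm_trace_zero(self):
        t = make_trace(arousal=[0.0] * 100)
        assert stress_index(t) == 0.0

    def test_constant_high_arousal_no_switches(self):
        t = make_trace(arousal=[1.0] * 100)
        assert stress_index(t) == pytest.approx(1.0)

    def test_hand_built_trace_value(self):
        """0.5 high fraction x (1 + 2 non-reducing switches / 100 steps) = 1.5."""
        dominant = (["hunger"] * 20 + ["fear"] * 20 + ["hunger"] * 10
                    + ["hunger"] * 50)
        arousal = [0.9] * 50 + [0.1] * 50
        t = make_trace(dominant=dominant, arousal=arousal)
        assert stress_index(t, arousal_threshold=0.7, k=10) == pytest.approx(1.5)

    def test_zero_when_below_threshold(self):
        dominant = ["hunger", "fear"] * 50
        t = make_trace(dominant=dominant, arousal=[0.3] * 100)
        assert stress_index(t, arousal_threshold=0.7) == 0.0


class TestDisplacement:
    def flat(self, n, circuit, a=0.8):
        return [circuit] * n, [a] * n

    def test_single_circuit_trace_empty(self):
        t = make_trace(dominant=["hunger"] * 80)
        assert detect_displacement(t, min_bout=20) == []

    def test_short_interruption_detected(self):
        dom = ["hunger"] * 30 + ["fear"] * 2 + ["hunger"] * 30
        t = make_trace(dominant=dom, arousal=[0.8] * len(dom))
        events = detect_displacement(t, min_bout=20, d_max=5)
        assert len(events) == 1
        ev = events[0]
        assert (ev.start, ev.length, ev.circuit) == (30, 2, "fear")

    def test_long_interruption_not_displacement(self):
        dom = ["hunger"] * 30 + ["fear"] * 20 + ["hunger"] * 30
        t = make_trace(dominant=dom, arousal=[0.8] * len(dom))
        assert detect_displacement(t, min_bout=20, d_max=5) == []

    def test_arousal_reduction_disqualifies(self):
        """If the pre-bout was succeeding (arousal falling), no displacement."""
        dom = ["hunger"] * 30 + ["fear"] * 2 + ["hunger"] * 30
        arousal = list(np.linspace(0.9, 0.3, 30)) + [0.3] * 2 + [0.3] * 30
        t = make_trace(dominant=dom, arousal=arousal)
        assert detect_displacement(t, min_bout=20, d_max=5) == []


class TestAmbiguityBias:
    def test_identical_distributions_zero_bias(self):
        responses = [("hunger", "food")] * 5 + [("hunger", "danger")] * 5 \
            + [("fear", "food")] * 5 + [("fear", "danger")] * 5
        ab = ambiguity_bias(responses, n_boot=200, rng=child_rng(0, "b"))
        assert ab.bias == 0.0

    def test_extreme_bias_is_one(self):
        responses = [("hunger", "food")] * 10 + [("fear", "danger")] * 10
        ab = ambiguity_bias(responses, n_boot=200, rng=child_rng(0, "b"))
        assert ab.bias == 1.0

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError):
            ambiguity_bias([("hunger", "food")])

    def test_bootstrap_ci_covers_true_bias(self):
        """Binomial Monte-Carlo: p = (0.7, 0.3) per condition, bias 0.4."""
        rng = child_rng(3, "mc")
        covered = 0
        reps = 60
        for r in range(reps):
            responses = [("hunger", "food" if rng.random() < 0.7 else "danger")
                         for _ in range(100)]
            responses += [("fear", "food" if rng.random() < 0.3 else "danger")
                          for _ in range(100)]
            ab = ambiguity_bias(responses, n_boot=300, rng=child_rng(3, "boot", r))
            covered += ab.ci_low <= 0.4 <= ab.ci_high
        # nominal 95% coverage; allow generous Monte-Carlo slack
        assert covered / reps > 0.8
        assert abs(ab.bias - 0.4) < 0.2


def test_summary_is_pure_function_of_trace():
    dom = ["hunger"] * 30 + ["fear"] * 2 + ["hunger"] * 30
    t = make_trace(dominant=dom, arousal=[0.8] * len(dom),
                   actions=["rest", "eat"] * 31, pe=[0.1] * 62)
    s1 = summarize(t)
    s2 = summarize(t.copy())
    assert s1 == s2
    assert s1.displacement_count == 1
    assert s1.mean_prediction_error == pytest.approx(0.1)
    assert s1.high_arousal_fraction == 1.0
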