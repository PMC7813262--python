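"""Observable welfare and stress indicators computed from agent traces.

All metrics are pure functions of the trace: they can be recomputed
bit-identically from a saved trace file, and none of them claims to measure
phenomenal experience — they quantify trace-level constructs (arousal load,
state-switching efficiency, behavioural diversity, judgement bias,
displacement activity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "behavioural_entropy", "stress_index", "detect_displacement",
    "DisplacementEvent", "ambiguity_bias", "AmbiguityBias",
    "WelfareSummary", "summarize",
]


def _entropy_bits(actions: Sequence[str]) -> float:
    counts = pd.Series(actions).value_counts().to_numpy(dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def behavioural_entropy(trace: pd.DataFrame, window: int, step: int = 1) -> pd.Series:
    """Shannon entropy (bits) of action frequencies in sliding windows.

    Windows of length ``window`` advance by ``step`` rows; a window longer
    than the trace yields a single whole-trace value.  Bounded by
    ``log2(number of distinct actions in the window)``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    actions = trace["action"].tolist()
    n = len(actions)
    if n == 0:
        return pd.Series(dtype=float)
    if window >= n:
        return pd.Series([_entropy_bits(actions)], index=[0])
    starts = range(0, n - window + 1, step)
    return pd.Series([_entropy_bits(actions[i:i + window]) for i in starts],
                     index=list(starts))


def _switch_indices(dominant: Sequence[str]) -> list[int]:
    return [i for i in range(1, len(dominant)) if dominant[i] != dominant[i - 1]]


def stress_index(trace: pd.DataFrame, arousal_threshold: float = 0.7,
                 k: int = 10) -> float:
    """Persistent high arousal, penalised by ineffective state switching.

    ``high_arousal_fraction * (1 + rate_of_non_reducing_switches_per_100_steps)``
    where a switch counts as non-reducing if the mean arousal in the ``k``
    steps after it is >= the mean in the ``k`` steps before.  Zero whenever
    arousal never exceeds the threshold.
    """
    if len(trace) == 0:
        raise ValueError("trace is empty")
    arousal = trace["arousal"].to_numpy(dtype=float)
    haf = float(np.mean(arousal > arousal_threshold))
    if haf == 0.0:
        return 0.0
    non_reducing = 0
    for i in _switch_indices(trace["dominant"].tolist()):
        before = arousal[max(0, i - k):i]
        after = arousal[i:i + k]
        if len(before) and len(after) and after.mean() >= before.mean():
            non_reducing += 1
    rate = 100.0 * non_reducing / len(trace)
    return haf * (1.0 + rate)


@dataclass(frozen=True)
class DisplacementEvent:
    start: int          # trace row index where the interruption begins
    length: int         # steps of the interruption
    circuit: str        # dominant circuit of the interrupting bout


def _bouts(dominant: Sequence[str]) -> list[tuple[int, int, str]]:
    """(start, length, circuit) for each maximal run of a dominant circuit."""
    out = []
    start = 0
    for i in range(1, len(dominant) + 1):
        if i == len(dominant) or dominant[i] != dominant[start]:
            out.append((start, i - start, dominant[start]))
            start = i
    return out


def detect_displacement(trace: pd.DataFrame, min_bout: int = 20,
                        d_max: int = 5, arousal_tol: float = 0.05
                        ) -> list[DisplacementEvent]:
    """Short alien interruptions of long, unrelieved same-circuit bouts.

    An event is a maximal interruption of total length <= ``d_max`` whose
    circuits all differ from the flanking bouts, where both flanks are
    >= ``min_bout`` steps long, share the same dominant circuit, and the
    preceding flank shows no net arousal reduction (end >= start -
    ``arousal_tol``) — i.e. the interrupted behaviour was not succeeding at
    lowering arousal.
    """
    if min_bout < 1:
        raise ValueError("min_bout must be >= 1")
    dominant = trace["dominant"].tolist()
    arousal = trace["arousal"].to_numpy(dtype=float)
    bouts = _bouts(dominant)
    events: list[DisplacementEvent] = []
    i = 0
    while i < len(bouts):
        start_i, len_i, circ_i = bouts[i]
        if len_i < min_bout:
            i += 1
            continue
        # find the next bout of the same circuit that is itself long enough
        j = i + 1
        interruption = 0
        while j < len(bouts) and bouts[j][2] != circ_i:
            interruption += bouts[j][1]
            j += 1
        if j < len(bouts) and j > i + 1 and bouts[j][1] >= min_bout \
                and interruption <= d_max:
            a0 = arousal[start_i]
            a1 = arousal[start_i + len_i - 1]
            if a1 >= a0 - arousal_tol:
                first_alien = bouts[i + 1]
                events.append(DisplacementEvent(start=first_alien[0],
                                                length=interruption,
                                                circuit=first_alien[2]))
            i = j
        else:
            i += 1
    return events


@dataclass(frozen=True)
class AmbiguityBias:
    bias: float
    p_food_given_hunger: float
    p_food_given_fear: float
    ci_low: float
    ci_high: float
    n_hunger: int
    n_fear: int


def ambiguity_bias(responses: Sequence[tuple[str, str]], n_boot: int = 1000,
                   rng: Optional[np.random.Generator] = None,
                   ci: float = 0.95) -> AmbiguityBias:
    """Judgement-bias statistic from ambiguous-probe responses.

    ``responses`` are ``(gos_at_probe, classification)`` pairs with
    classification in {"food", "danger", "other"}.  The bias is
    ``P(food | hunger) - P(food | fear)``: positive means the hungry state
    interprets the ambiguous cue as food more often than the fearful state
    does.  The confidence interval is a percentile bootstrap over probes
    within each condition (seeded).
    """
    hunger = np.array([1.0 if cls == "food" else 0.0
                       for gos, cls in responses if gos == "hunger"])
    fear = np.array([1.0 if cls == "food" else 0.0
                     for gos, cls in responses if gos == "fear"])
    if len(hunger) == 0 or len(fear) == 0:
        raise ValueError("each GOS condition needs at least one probe")
    p_h, p_f = float(hunger.mean()), float(fear.mean())
    if rng is None:
        rng = np.random.default_rng(0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bh = hunger[rng.integers(len(hunger), size=len(hunger))].mean()
        bf = fear[rng.integers(len(fear), size=len(fear))].mean()
        boots[b] = bh - bf
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return AmbiguityBias(bias=p_h - p_f, p_food_given_hunger=p_h,
                         p_food_given_fear=p_f, ci_low=float(lo),
                         ci_high=float(hi), n_hunger=len(hunger), n_fear=len(fear))


@dataclass(frozen=True)
class WelfareSummary:
    mean_arousal: float
    high_arousal_fraction: float
    gos_switch_rate: float          # switches per 100 steps
    mean_bout_length: float
    behavioural_entropy: float      # mean over sliding windows, bits
    mean_prediction_error: float
    displacement_count: int
    stress_index: float


def summarize(trace: pd.DataFrame, arousal_threshold: float = 0.7, k: int = 10,
              entropy_window: int = 50, min_bout: int = 20, d_max: int = 5,
              arousal_tol: float = 0.05) -> WelfareSummary:
    """All scalar welfare indicators for one trace."""
    if len(trace) == 0:
        raise ValueError("trace is empty")
    arousal = trace["arousal"].to_numpy(dtype=float)
    switches = _switch_indices(trace["dominant"].tolist())
    bouts = _bouts(trace["dominant"].tolist())
    pe = trace["prediction_error"].to_numpy(dtype=float)
    pe = pe[~np.isnan(pe)]
    ent = behavioural_entropy(trace, entropy_window)
    return WelfareSummary(
        mean_arousal=float(arousal.mean()),
        high_arousal_fraction=float(np.mean(arousal > arousal_threshold)),
        gos_switch_rate=100.0 * len(switches) / len(trace),
        mean_bout_length=float(np.mean([b[1] for b in bouts])),
        behavioural_entropy=float(ent.mean()) if len(ent) else math.nan,
        mean_prediction_error=float(pe.mean()) if len(pe) else math.nan,
        displacement_count=len(detect_displacement(trace, min_bout, d_max, arousal_tol)),
        stress_index=stress_index(trace, arousal_threshold, k),
    )
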