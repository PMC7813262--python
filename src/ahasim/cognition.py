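"""The appraisal core of the subjective internal model.

Each survival circuit integrates its linked, attention-gated stimuli into a
motivation in [0, 1] through genome-encoded Hill response functions.  The
motivations compete; the strongest holds the global organismic state (GOS),
a single winner-take-all dominant whose strength is the agent's arousal.

Two mechanisms shape the competition over time:

* **Hysteresis** — a challenger must beat the incumbent by a margin
  ``theta(A) = hysteresis_hi - (hysteresis_hi - hysteresis_lo) * A``.  Small
  stimulus fluctuations are tolerated, giving the dominant state continuity;
  the margin shrinks with arousal so a genuinely stronger need can seize
  control in urgent situations.
* **Dissipation** — under prolonged single-circuit dominance (bout length
  past a genome-encoded onset) arousal decays geometrically, emulating
  neuronal exhaustion.  Lower arousal relaxes top-down attention, which is
  what gives alternative circuits their chance at the next appraisal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ConfigurationError

__all__ = [
    "CircuitSpec", "Architecture", "GOSState", "initial_gos",
    "hill", "motivation", "switching_threshold", "appraise", "dissipate",
    "default_architecture",
]


@dataclass(frozen=True)
class CircuitSpec:
    """One survival circuit: a labelled perception→motivation pathway."""

    circuit_id: str
    valence: str                    # "negative" (hunger, fear, thirst) or "positive"
    modalities: tuple[str, ...]     # stimulus modalities feeding this circuit

    def __post_init__(self):
        if self.valence not in ("negative", "positive"):
            raise ConfigurationError(f"invalid valence {self.valence!r}")
        if not self.modalities:
            raise ConfigurationError(f"circuit {self.circuit_id!r} has no linked modalities")


@dataclass(frozen=True)
class Architecture:
    """The fixed circuit set an agent is built from.

    ``priority`` is the deterministic tie-break order for the competition
    (defaults to declaration order).
    """

    circuits: tuple[CircuitSpec, ...]
    priority: tuple[str, ...] = ()
    evolve_modulators: bool = True  # attention/hysteresis/dissipation genes evolvable?

    def __post_init__(self):
        if not self.circuits:
            raise ConfigurationError("architecture must declare at least one circuit")
        ids = [c.circuit_id for c in self.circuits]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate circuit ids")
        if not self.priority:
            object.__setattr__(self, "priority", tuple(ids))
        elif set(self.priority) != set(ids):
            raise ConfigurationError("priority order must name every circuit exactly once")

    def circuit(self, circuit_id: str) -> CircuitSpec:
        for c in self.circuits:
            if c.circuit_id == circuit_id:
                return c
        raise KeyError(circuit_id)

    def linked(self, circuit_id: str) -> tuple[str, ...]:
        return self.circuit(circuit_id).modalities

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.circuit_id for c in self.circuits)


def default_architecture(water: bool = False) -> Architecture:
    """Hunger + fear (and thirst when the world has water).

    The ambiguous probe cue feeds both hunger and fear, so the interpretation
    an agent gives it is decided by attention and the current dominant state.
    """
    circuits = [
        CircuitSpec("hunger", "negative", ("food_cue", "gut_emptiness", "ambiguous_cue")),
        CircuitSpec("fear", "negative", ("predator_cue", "ambiguous_cue")),
    ]
    if water:
        circuits.append(CircuitSpec("thirst", "negative", ("water_cue", "thirst_level")))
    return Architecture(circuits=tuple(circuits))


@dataclass(frozen=True)
class GOSState:
    """The global workspace summary: one dominant circuit and its arousal."""

    dominant: str
    arousal: float
    bout_length: int = 1
    last_predicted_arousal: Optional[float] = None


def initial_gos(arch: Architecture) -> GOSState:
    return GOSState(dominant=arch.priority[0], arousal=0.0, bout_length=1)


def hill(x: float, gain: float, half_sat: float) -> float:
    """Saturating Hill response: ``x**g / (x**g + h**g)``; 0 at x = 0."""
    if x <= 0.0:
        return 0.0
    xg = x ** gain
    return xg / (xg + half_sat ** gain)


def motivation(percept, circuit: CircuitSpec, genome) -> float:
    """Weighted mean of Hill responses over the circuit's gated stimuli.

    ``M_c = sum_m w_m R_m(s_m) / sum_m w_m`` with per-link parameters from
    the genome.  Raises if every link weight is zero (undefined
    normalisation).
    """
    num = 0.0
    den = 0.0
    gated = percept.gated if hasattr(percept, "gated") else percept
    for m in circuit.modalities:
        lp = genome.link_params[(circuit.circuit_id, m)]
        num += lp.weight * hill(gated[m], lp.gain, lp.half_sat)
        den += lp.weight
    if den == 0.0:
        raise ConfigurationError(
            f"circuit {circuit.circuit_id!r}: all link weights are zero")
    return num / den


def switching_threshold(genome, arousal: float) -> float:
    """Hysteresis margin theta(A), linear from hi (calm) to lo (aroused)."""
    a = min(1.0, max(0.0, arousal))
    return genome.hysteresis_hi - (genome.hysteresis_hi - genome.hysteresis_lo) * a


def appraise(percept, arch: Architecture, prev: GOSState, genome
             ) -> tuple[dict[str, float], GOSState]:
    """One round of motivation competition.

    Computes every circuit's motivation from the gated percept, then lets
    the strongest challenger contest the incumbent: dominance switches iff
    ``M_challenger > M_incumbent + theta(prev.arousal)``.  Arousal is set to
    the (new) dominant's motivation; bout length increments on continuity
    and resets to 1 on a switch.  Ties break by the architecture's priority
    order.  Exactly one circuit is dominant afterwards.
    """
    motivations = {c.circuit_id: motivation(percept, c, genome) for c in arch.circuits}
    if prev.dominant not in motivations:
        raise ConfigurationError(f"previous dominant {prev.dominant!r} not in architecture")

    rank = {cid: i for i, cid in enumerate(arch.priority)}
    challengers = [cid for cid in motivations if cid != prev.dominant]
    dominant = prev.dominant
    if challengers:
        best = min(challengers, key=lambda cid: (-motivations[cid], rank[cid]))
        if motivations[best] > motivations[prev.dominant] + switching_threshold(genome, prev.arousal):
            dominant = best

    if dominant == prev.dominant:
        gos = GOSState(dominant=dominant, arousal=motivations[dominant],
                       bout_length=prev.bout_length + 1,
                       last_predicted_arousal=prev.last_predicted_arousal)
    else:
        gos = GOSState(dominant=dominant, arousal=motivations[dominant], bout_length=1,
                       last_predicted_arousal=prev.last_predicted_arousal)
    return motivations, gos


def dissipate(gos: GOSState, genome, enabled: bool = True) -> GOSState:
    """Spontaneous arousal decay during prolonged single-circuit dominance.

    Once the current bout has lasted at least ``dissipation_onset`` steps,
    arousal is multiplied by ``1 - dissipation_rate``.  The dominant circuit
    itself is never changed here; re-competition happens at the next
    appraisal, under the broader attention that lower arousal allows.
    """
    if not enabled or gos.bout_length < genome.dissipation_onset:
        return gos
    return replace(gos, arousal=gos.arousal * (1.0 - genome.dissipation_rate))
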