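"""Top-down attention: from raw stimuli to the gated percept.

The global organismic state and arousal jointly decide which stimuli the
agent uses.  Modalities linked to the dominant circuit pass unattenuated
(gate weight 1); every other modality is suppressed linearly in arousal with
a genome-encoded slope, ``w_m = clamp(1 - attention_strength * A, 0, 1)``.
Internal modalities are gated exactly like external ones.  In the purely
reactive tier there is no top-down gating at all.

Because the gate depends on the agent's current state, two agents with
identical genomes in identical environments perceive differently whenever
their states differ — the mechanical sense in which perception here is
subjective.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cognition import Architecture, GOSState
from .environment import MODALITIES

__all__ = ["Percept", "attend", "AGENT_MODES"]

AGENT_MODES = ("reactive", "single_reentrant", "full_workspace")


@dataclass(frozen=True)
class Percept:
    """Attention-gated stimulus magnitudes plus the gate weights applied."""

    gated: dict[str, float]
    weights: dict[str, float]
    raw: dict[str, float]


def attend(s: dict[str, float], gos: GOSState, genome, mode: str,
           arch: Architecture) -> Percept:
    """Apply the GOS/arousal-dependent top-down gate to a stimulus field."""
    if mode not in AGENT_MODES:
        raise ValueError(f"unknown agent mode {mode!r}")
    if mode == "reactive":
        weights = {m: 1.0 for m in s}
    else:
        linked = set(arch.linked(gos.dominant))
        off_gate = min(1.0, max(0.0, 1.0 - genome.attention_strength * gos.arousal))
        weights = {m: (1.0 if m in linked else off_gate) for m in s}
    gated = {m: s[m] * weights[m] for m in s}
    return Percept(gated=gated, weights=weights, raw=dict(s))
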