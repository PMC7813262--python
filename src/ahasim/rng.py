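"""Deterministic random-stream derivation.

Every stochastic component of the simulator draws from a ``numpy`` Generator
derived from a single master seed plus a structured key (e.g. ``("eval",
generation, agent_index)``).  Streams are spawned through
``numpy.random.SeedSequence`` with a counter-based spawn key, so adding new
consumers (more agents, more replicates) never perturbs existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def _key_part(part: int | str) -> int:
    """Map a key component to a uint32 for use in a spawn key."""
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8")) & 0xFFFFFFFF
    raise TypeError(f"rng key parts must be int or str, got {type(part).__name__}")


def child_seed_sequence(master_seed: int, *key: int | str) -> np.random.SeedSequence:
    if master_seed < 0:
        raise ValueError("master_seed must be non-negative")
    return np.random.SeedSequence(int(master_seed), spawn_key=tuple(_key_part(p) for p in key))


def child_rng(master_seed: int, *key: int | str) -> np.random.Generator:
    """A Generator for the stream identified by ``(master_seed, *key)``.

    The same arguments always yield an identical stream, on any platform.
    """
    return np.random.default_rng(child_seed_sequence(master_seed, *key))
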