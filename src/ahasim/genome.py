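"""Heritable encoding of the subjective internal model.

Every parameter that shapes how an agent perceives, appraises and predicts
is carried on a real-valued genome: one (gain, half_sat, weight) triple per
(circuit, modality) link of the perception→motivation response function,
plus the attention slope, the two hysteresis bounds of the state-switching
threshold, and the arousal-dissipation parameters.  Architecture parameters
are therefore products of selection, not hand-tuning.

Genetic operators are the standard real-coded pair: per-field Gaussian
mutation (sd scaled to each field's legal range) and uniform crossover.
Out-of-range values are clamped, which keeps the operators deterministic
given the random stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import ConfigurationError, IncompatibleGenomesError

__all__ = [
    "LinkParams", "Genome", "random_genome", "mutate", "crossover",
    "save_population", "load_population", "FIELD_RANGES", "MODULATOR_FIELDS",
]

# Legal (and sampling) ranges for every scalar gene.
FIELD_RANGES: dict[str, tuple[float, float]] = {
    "gain": (0.2, 4.0),            # Hill exponent of the response function
    "half_sat": (0.01, 1.0),       # stimulus at half-maximal response
    # strictly positive floor so no circuit can evolve an all-zero weight set,
    # which would leave its motivation normalisation undefined
    "weight": (0.001, 1.0),        # contribution to the circuit's motivation
    "attention_strength": (0.0, 1.0),
    "hysteresis_lo": (0.0, 0.3),
    "hysteresis_hi": (0.0, 0.3),
    "dissipation_rate": (0.0, 0.95),
    "dissipation_onset": (1, 60),  # integer, timesteps
}

# Non-link genes modulating attention/switching/dissipation; can be frozen
# (excluded from mutation and crossover) via the architecture config.
MODULATOR_FIELDS = (
    "attention_strength", "hysteresis_lo", "hysteresis_hi",
    "dissipation_rate", "dissipation_onset",
)

LINK_SUBFIELDS = ("gain", "half_sat", "weight")


@dataclass(frozen=True)
class LinkParams:
    """Response-function parameters of one perception→motivation link."""

    gain: float
    half_sat: float
    weight: float


@dataclass
class Genome:
    link_params: dict[tuple[str, str], LinkParams]
    attention_strength: float
    hysteresis_lo: float
    hysteresis_hi: float
    dissipation_rate: float
    dissipation_onset: int

    # -- scalar-field view (canonical order) used by the genetic operators --

    def scalar_names(self) -> list[str]:
        names = []
        for (cid, mid) in sorted(self.link_params):
            for sub in LINK_SUBFIELDS:
                names.append(f"{cid}.{mid}.{sub}")
        names.extend(MODULATOR_FIELDS)
        return names

    def scalar_items(self) -> Iterator[tuple[str, float]]:
        for (cid, mid) in sorted(self.link_params):
            lp = self.link_params[(cid, mid)]
            for sub in LINK_SUBFIELDS:
                yield f"{cid}.{mid}.{sub}", getattr(lp, sub)
        for name in MODULATOR_FIELDS:
            yield name, getattr(self, name)

    @staticmethod
    def _range_of(name: str) -> tuple[float, float]:
        base = name.rsplit(".", 1)[-1] if "." in name else name
        return FIELD_RANGES[base]

    @classmethod
    def from_scalars(cls, values: dict[str, float]) -> "Genome":
        links: dict[tuple[str, str], dict[str, float]] = {}
        mods: dict[str, float] = {}
        for name, v in values.items():
            if name in MODULATOR_FIELDS:
                mods[name] = v
            else:
                cid, mid, sub = name.rsplit(".", 2)
                links.setdefault((cid, mid), {})[sub] = v
        lo, hi = mods["hysteresis_lo"], mods["hysteresis_hi"]
        if lo > hi:  # keep the switching-band invariant after any operator
            lo, hi = hi, lo
        return cls(
            link_params={k: LinkParams(**d) for k, d in links.items()},
            attention_strength=mods["attention_strength"],
            hysteresis_lo=lo,
            hysteresis_hi=hi,
            dissipation_rate=mods["dissipation_rate"],
            dissipation_onset=int(round(mods["dissipation_onset"])),
        )

    # -- serialization: flat JSON, link params keyed "circuit.modality" --

    def to_dict(self) -> dict:
        return {
            "link_params": {
                f"{cid}.{mid}": {"gain": lp.gain, "half_sat": lp.half_sat, "weight": lp.weight}
                for (cid, mid), lp in sorted(self.link_params.items())
            },
            "attention_strength": self.attention_strength,
            "hysteresis_lo": self.hysteresis_lo,
            "hysteresis_hi": self.hysteresis_hi,
            "dissipation_rate": self.dissipation_rate,
            "dissipation_onset": self.dissipation_onset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        links = {}
        for key, lp in d["link_params"].items():
            cid, mid = key.split(".", 1)
            links[(cid, mid)] = LinkParams(**lp)
        return cls(
            link_params=links,
            attention_strength=d["attention_strength"],
            hysteresis_lo=d["hysteresis_lo"],
            hysteresis_hi=d["hysteresis_hi"],
            dissipation_rate=d["dissipation_rate"],
            dissipation_onset=int(d["dissipation_onset"]),
        )


def _clamp(v: float, lo: float, hi: float) -> float:
    return min(hi, max(lo, v))


def random_genome(arch, rng: np.random.Generator) -> Genome:
    """Draw a genome uniformly within legal ranges for ``arch``'s link set.

    ``arch`` must expose ``circuits``, each with ``circuit_id`` and
    ``modalities``.  Deterministic given the random stream.
    """
    circuits = list(arch.circuits)
    if not circuits:
        raise ConfigurationError("architecture declares no survival circuits")
    links: dict[tuple[str, str], LinkParams] = {}
    for c in circuits:
        if not c.modalities:
            raise ConfigurationError(f"circuit {c.circuit_id!r} has no linked modalities")
        for m in c.modalities:
            links[(c.circuit_id, m)] = LinkParams(
                gain=float(rng.uniform(*FIELD_RANGES["gain"])),
                half_sat=float(rng.uniform(*FIELD_RANGES["half_sat"])),
                weight=float(rng.uniform(*FIELD_RANGES["weight"])),
            )
    h1 = float(rng.uniform(*FIELD_RANGES["hysteresis_lo"]))
    h2 = float(rng.uniform(*FIELD_RANGES["hysteresis_hi"]))
    lo_r, hi_r = FIELD_RANGES["dissipation_onset"]
    return Genome(
        link_params=links,
        attention_strength=float(rng.uniform(*FIELD_RANGES["attention_strength"])),
        hysteresis_lo=min(h1, h2),
        hysteresis_hi=max(h1, h2),
        dissipation_rate=float(rng.uniform(*FIELD_RANGES["dissipation_rate"])),
        dissipation_onset=int(rng.integers(lo_r, hi_r + 1)),
    )


def mutate(g: Genome, mut_rate: float, mut_sd: float, rng: np.random.Generator,
           frozen_fields: Iterable[str] = ()) -> Genome:
    """Per-scalar Gaussian mutation.

    Each scalar gene is independently perturbed with probability
    ``mut_rate`` by Gaussian noise with sd ``mut_sd`` scaled to the field's
    range width, then clamped to its legal range.  The input genome is not
    modified.  Fields named in ``frozen_fields`` are never touched.
    """
    if not 0.0 <= mut_rate <= 1.0:
        raise ValueError("mut_rate must lie in [0, 1]")
    if mut_sd < 0:
        raise ValueError("mut_sd must be >= 0")
    frozen = set(frozen_fields)
    out: dict[str, float] = {}
    for name, v in g.scalar_items():
        if name not in frozen and rng.random() < mut_rate:
            lo, hi = Genome._range_of(name)
            v = _clamp(v + float(rng.normal(0.0, mut_sd * (hi - lo))), lo, hi)
        out[name] = v
    return Genome.from_scalars(out)


def crossover(a: Genome, b: Genome, rng: np.random.Generator,
              frozen_fields: Iterable[str] = ()) -> Genome:
    """Uniform crossover: each scalar copied from ``a`` or ``b`` with p=1/2.

    The two hysteresis bounds are inherited jointly (one coin for the pair)
    so that every offspring scalar is literally one parent's scalar while the
    ``lo <= hi`` invariant is preserved.  Frozen fields always come from
    parent ``a``.
    """
    if set(a.link_params) != set(b.link_params):
        raise IncompatibleGenomesError("parents built from different architectures")
    frozen = set(frozen_fields)
    av = dict(a.scalar_items())
    bv = dict(b.scalar_items())
    out = {}
    for name in a.scalar_names():
        if name == "hysteresis_hi":
            continue  # inherited together with hysteresis_lo below
        if name in frozen:
            out[name] = av[name]
        else:
            out[name] = av[name] if rng.random() < 0.5 else bv[name]
        if name == "hysteresis_lo":
            src = av if out[name] == av[name] else bv
            out["hysteresis_hi"] = src["hysteresis_hi"]
    return Genome.from_scalars(out)


def save_population(path: str | Path, genomes: list[Genome],
                    metadata: dict | None = None) -> None:
    payload = {"metadata": metadata or {}, "genomes": [g.to_dict() for g in genomes]}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_population(path: str | Path) -> tuple[list[Genome], dict]:
    payload = json.loads(Path(path).read_text())
    return [Genome.from_dict(d) for d in payload["genomes"]], payload.get("metadata", {})
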