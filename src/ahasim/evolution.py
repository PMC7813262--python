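"""Generational genetic algorithm over agent genomes.

Each generation, every genome lives one life in its own copy of the world
(deterministic per-agent sub-seeds derived from the master seed), earning a
fitness ``w1*survived + w2*terminal_energy/energy_max + w3*offspring``.
The next generation keeps the best genomes unchanged (elitism) and fills
the rest by tournament (or truncation) selection, uniform crossover and
Gaussian mutation.  Welfare indicators are deliberately never part of the
fitness: welfare is measured on evolved agents, not optimised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .agent import AgentConfig, simulate_agent
from .cognition import Architecture
from .environment import WorldConfig
from .errors import ConfigurationError
from .genome import Genome, MODULATOR_FIELDS, crossover, mutate, random_genome
from .rng import child_rng

__all__ = ["EvolutionConfig", "FitnessRecord", "evaluate_population",
           "next_generation", "evolve", "EvolutionResult"]


@dataclass
class EvolutionConfig:
    pop_size: int = 50
    n_generations: int = 20
    lifespan: int = 300
    selection: str = "tournament"        # or "truncation"
    tournament_k: int = 3
    truncation_fraction: float = 0.5
    elitism_count: int = 2
    mut_rate: float = 0.15
    mut_sd: float = 0.15
    fitness_weights: tuple[float, float, float] = (1.0, 1.0, 2.0)  # survival, energy, offspring
    fixed_eval_seeds: bool = True    # same world stream per population slot every generation
    seed: int = 0

    def validate(self) -> None:
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be >= 2")
        if not 0 <= self.elitism_count < self.pop_size:
            raise ConfigurationError("elitism_count must lie in [0, pop_size)")
        if self.selection not in ("tournament", "truncation"):
            raise ConfigurationError(f"unknown selection scheme {self.selection!r}")
        if self.tournament_k < 1:
            raise ConfigurationError("tournament_k must be >= 1")
        if not 0.0 < self.truncation_fraction <= 1.0:
            raise ConfigurationError("truncation_fraction must lie in (0, 1]")


@dataclass
class FitnessRecord:
    agent_id: int
    survived: bool
    terminal_energy: float
    offspring_count: int
    fitness: float


def evaluate_population(genomes: list[Genome], arch: Architecture,
                        world_config: WorldConfig, lifespan: int,
                        master_seed: int, generation: int = 0,
                        mode: str = "full_workspace",
                        agent_config: Optional[AgentConfig] = None,
                        weights: tuple[float, float, float] = (1.0, 1.0, 2.0),
                        fixed_eval_seeds: bool = True) -> list[FitnessRecord]:
    """Simulate every genome for one lifetime and score it.

    With ``fixed_eval_seeds`` every genome is evaluated on one and the same
    world stream (independent of generation and population slot): identical
    genomes always earn identical fitness, which is what makes elitism's
    max-fitness-non-decreasing guarantee exact.  With it off, sub-seeds are
    derived per (generation, slot) and every life is an independent draw.
    """
    if not genomes:
        raise ConfigurationError("cannot evaluate an empty population")
    acfg = agent_config or AgentConfig()
    w1, w2, w3 = weights
    records = []
    for i, g in enumerate(genomes):
        key = ("eval",) if fixed_eval_seeds else ("eval", generation, i)
        rng = child_rng(master_seed, *key)
        res = simulate_agent(g, arch, world_config, mode=mode, lifespan=lifespan,
                             rng=rng, agent_config=acfg, collect_trace=False)
        offspring = 0  # reproduction circuit not enabled in the default architecture
        fitness = (w1 * float(res.survived)
                   + w2 * max(0.0, res.internal.energy) / acfg.energy_max
                   + w3 * offspring)
        records.append(FitnessRecord(agent_id=i, survived=res.survived,
                                     terminal_energy=res.internal.energy,
                                     offspring_count=offspring, fitness=fitness))
    return records


def _select_parent(order: list[int], fitness: list[float], ec: EvolutionConfig,
                   rng: np.random.Generator) -> int:
    n = len(fitness)
    if ec.selection == "tournament":
        k = min(ec.tournament_k, n)
        contenders = rng.choice(n, size=k, replace=False)
        # best by fitness; ties by lower index (stable)
        return int(min(contenders, key=lambda i: (-fitness[int(i)], int(i))))
    pool = order[:max(1, int(round(ec.truncation_fraction * n)))]
    return int(pool[int(rng.integers(len(pool)))])


def next_generation(records: list[FitnessRecord], genomes: list[Genome],
                    ec: EvolutionConfig, rng: np.random.Generator,
                    frozen_fields: tuple[str, ...] = ()) -> list[Genome]:
    """Elites pass unchanged; the rest come from selection → crossover → mutation."""
    if len(records) != len(genomes):
        raise ValueError("records and genomes must be aligned")
    ec.validate()
    fitness = [r.fitness for r in records]
    order = sorted(range(len(genomes)), key=lambda i: (-fitness[i], i))
    out: list[Genome] = [genomes[i] for i in order[:ec.elitism_count]]
    while len(out) < ec.pop_size:
        pa = _select_parent(order, fitness, ec, rng)
        pb = _select_parent(order, fitness, ec, rng)
        child = crossover(genomes[pa], genomes[pb], rng, frozen_fields=frozen_fields)
        child = mutate(child, ec.mut_rate, ec.mut_sd, rng, frozen_fields=frozen_fields)
        out.append(child)
    return out


@dataclass
class EvolutionResult:
    population: list[Genome]
    summary: pd.DataFrame            # per generation: min/median/max fitness, survival fraction
    best: Genome
    records: list[FitnessRecord]     # final generation


def evolve(arch: Architecture, world_config: WorldConfig, ec: EvolutionConfig,
           mode: str = "full_workspace",
           agent_config: Optional[AgentConfig] = None,
           genome_overrides: Optional[dict[str, float]] = None) -> EvolutionResult:
    """Run the full GA and return the final population with a summary table.

    ``genome_overrides`` pins named scalar genome fields (e.g.
    ``attention_strength``) to fixed values in the initial population; with
    ``arch.evolve_modulators`` off the modulator genes additionally stay
    untouched by mutation and crossover, so only the perception→motivation
    response functions adapt.
    """
    ec.validate()
    if not arch.evolve_modulators:
        frozen_fields = MODULATOR_FIELDS
    else:
        frozen_fields = ()
    init_rng = child_rng(ec.seed, "init")
    population = [random_genome(arch, init_rng) for _ in range(ec.pop_size)]
    if genome_overrides:
        population = [
            Genome.from_scalars({name: genome_overrides.get(name, v)
                                 for name, v in g.scalar_items()})
            for g in population
        ]
    summary_rows = []
    records: list[FitnessRecord] = []
    for gen in range(ec.n_generations + 1):
        records = evaluate_population(population, arch, world_config, ec.lifespan,
                                      ec.seed, generation=gen, mode=mode,
                                      agent_config=agent_config,
                                      weights=ec.fitness_weights,
                                      fixed_eval_seeds=ec.fixed_eval_seeds)
        fits = np.array([r.fitness for r in records])
        summary_rows.append({
            "generation": gen,
            "min_fitness": float(fits.min()),
            "median_fitness": float(np.median(fits)),
            "max_fitness": float(fits.max()),
            "survival_fraction": float(np.mean([r.survived for r in records])),
        })
        if gen == ec.n_generations:
            break
        gen_rng = child_rng(ec.seed, "breed", gen)
        population = next_generation(records, population, ec, gen_rng,
                                     frozen_fields=frozen_fields)
    summary = pd.DataFrame(summary_rows)
    fitness = [r.fitness for r in records]
    best = population[max(range(len(population)), key=lambda i: fitness[i])]
    return EvolutionResult(population=population, summary=summary, best=best,
                           records=records)
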