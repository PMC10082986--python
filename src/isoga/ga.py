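"""Fixed-cardinality genetic algorithm: choose m of p indices minimizing an
arbitrary fitness.

Individuals are sorted tuples of m distinct indices (the binary string with
exactly m ones).  All operators preserve cardinality: crossover keeps the
parents' intersection and fills the remaining slots uniformly from the
symmetric difference; mutation swaps selected indices for unselected ones.
Selection is tournament (lower fitness wins) with elitism, and ties break
lexicographically everywhere so runs are reproducible bit-for-bit given a
seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

Individual = tuple[int, ...]


@dataclass
class GAState:
    population: list[Individual]
    p: int
    m: int
    rng: np.random.Generator
    generation: int = 0
    fitnesses: list[float] | None = None
    best: Individual | None = None
    best_fitness: float = math.inf
    history: list[float] = field(default_factory=list)


def random_subset(rng: np.random.Generator, p: int, m: int) -> Individual:
    return tuple(sorted(int(i) for i in rng.choice(p, size=m, replace=False)))


def init_population(p: int, m: int, pop_size: int, rng: np.random.Generator) -> GAState:
    """Uniform random m-subsets; duplicates across the population allowed."""
    if m > p:
        raise ValueError(f"subset size m={m} exceeds p={p}")
    population = [random_subset(rng, p, m) for _ in range(pop_size)]
    return GAState(population=population, p=p, m=m, rng=rng)


def crossover(a: Individual, b: Individual, rng: np.random.Generator) -> Individual:
    """Intersection-preserving uniform crossover for fixed-size subsets."""
    sa, sb = set(a), set(b)
    core = sa & sb
    pool = sorted(sa ^ sb)
    need = len(a) - len(core)
    if need:
        picks = rng.choice(len(pool), size=need, replace=False)
        core |= {pool[i] for i in picks}
    return tuple(sorted(core))


def mutate(ind: Individual, rate: float, rng: np.random.Generator, p: int) -> Individual:
    """Swap each selected index, with probability ``rate``, for a uniform
    draw from the currently unselected indices."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    current = set(ind)
    for idx in ind:
        if rng.random() >= rate:
            continue
        available = p - len(current)
        if available == 0:
            break
        # uniform draw from the complement without materializing it fully
        pool = np.setdiff1d(np.arange(p), np.fromiter(current, dtype=int))
        new = int(pool[rng.integers(pool.size)])
        current.remove(idx)
        current.add(new)
    return tuple(sorted(current))


def _evaluate(fitness_fn, ind: Individual) -> float:
    value = float(fitness_fn(ind))
    if math.isnan(value):
        log.warning("fitness returned NaN for %s; treating as +inf", ind)
        return math.inf
    return value


def _tournament(state: GAState, scored: list[tuple[float, Individual]],
                size: int) -> Individual:
    picks = state.rng.integers(len(scored), size=size)
    best = min((scored[i] for i in picks), key=lambda t: (t[0], t[1]))
    return best[1]


def evolve(
    state: GAState,
    fitness_fn,
    generations: int,
    tournament_size: int = 2,
    elitism: int = 1,
    mutation_rate: float = 0.01,
) -> GAState:
    """Run the generational loop; returns the final state with the
    population sorted ascending by fitness.

    Each generation copies the best ``elitism`` individuals unchanged, then
    fills the remaining slots with tournament selection → crossover →
    mutation.  With elitism >= 1 the best fitness is monotone
    non-increasing.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    pop = list(state.population)
    fits = [_evaluate(fitness_fn, ind) for ind in pop]
    for _ in range(generations):
        scored = sorted(zip(fits, pop), key=lambda t: (t[0], t[1]))
        if scored[0][0] < state.best_fitness:
            state.best_fitness, state.best = scored[0][0], scored[0][1]
        state.history.append(state.best_fitness)
        next_pop: list[Individual] = [ind for _, ind in scored[:elitism]]
        while len(next_pop) < len(pop):
            pa = _tournament(state, scored, tournament_size)
            pb = _tournament(state, scored, tournament_size)
            child = crossover(pa, pb, state.rng)
            child = mutate(child, mutation_rate, state.rng, state.p)
            next_pop.append(child)
        pop = next_pop
        fits = [_evaluate(fitness_fn, ind) for ind in pop]
        state.generation += 1
    order = sorted(range(len(pop)), key=lambda i: (fits[i], pop[i]))
    state.population = [pop[i] for i in order]
    state.fitnesses = [fits[i] for i in order]
    if state.fitnesses[0] < state.best_fitness:
        state.best_fitness, state.best = state.fitnesses[0], state.population[0]
    return state


def top_k(state: GAState, count: int) -> list[tuple[Individual, float]]:
    """The ``count`` lowest-fitness *distinct* subsets of the final
    generation, ties broken lexicographically.

    When the population holds fewer distinct subsets than requested, the
    shorter list is returned (length reported honestly, no padding).
    """
    if state.fitnesses is None:
        raise ValueError("population not evaluated; run evolve first")
    if count > len(state.population):
        raise ValueError("count exceeds population size")
    seen: set[Individual] = set()
    out: list[tuple[Individual, float]] = []
    for fit, ind in sorted(
        zip(state.fitnesses, state.population), key=lambda t: (t[0], t[1])
    ):
        if ind in seen:
            continue
        seen.add(ind)
        out.append((ind, fit))
        if len(out) == count:
            break
    return out
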