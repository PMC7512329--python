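"""Genetic-algorithm temperature minimization (BINMATNEST-style).

Chromosomes are candidate rankings (a permutation pair, one per matrix side);
the objective is the nestedness temperature of the reordered matrix, so
fitness is -T.  Each generation a well-performing chromosome ``w`` is chosen
by linear rank weighting, a partner ``p`` uniformly at random, and a single
offspring is produced by an order-preserving crossover applied independently
to the row and column permutations:

1. with probability 1/2 the offspring side is a copy of ``w``; otherwise
2. draw ``k`` uniformly in {1..N} and copy ``o_i = w_i`` for i <= k;
3. for i > k set ``o_i = p_i`` iff ``p_i`` has not appeared in {w_1..w_k};
4. positions left open receive the not-yet-used rank values, assigned in
   increasing position order with unused values taken in increasing order.

The offspring then mutates with probability 0.1 per side: a random contiguous
slice ``o_k1..o_k2`` is cyclically rotated by one position.  Steady-state,
elitist replacement: the offspring replaces the current worst chromosome only
if strictly better, so the best temperature found is non-increasing.  One
generation comprises ``population_size`` such births, and the search stops
after ``max_generations`` generations or once ``stagnation_limit``
generations pass without the best temperature improving.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .fca import fca_converge, fca_ranking
from .isocline import calibrated_isocline
from .matrix import IncidenceMatrix, Ranking, degree_ranking
from .temperature import TemperatureResult, temperature, unexpectedness, UMAX

__all__ = [
    "GAConfig",
    "Chromosome",
    "GAResult",
    "ga_crossover",
    "ga_mutate",
    "ga_minimize",
    "brute_force_min_temperature",
]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 30
    max_generations: int = 500
    stagnation_limit: int = 100  # generations without improvement of the best
    mutation_probability: float = 0.1
    copy_probability: float = 0.5  # probability that a side is copied from w
    seed: int | None = None
    seeding: tuple = ("degree", "fca", "random")
    fca_delta_n: int = 10

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("mutation_probability", "copy_probability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        unknown = set(self.seeding) - {"degree", "fca", "random"}
        if unknown:
            raise ValueError(f"unknown seeding policies: {sorted(unknown)}")


@dataclass
class Chromosome:
    """One candidate ranking with its (cached) temperature."""

    candidate: Ranking
    temperature: float

    @property
    def fitness_value(self) -> float:
        return -self.temperature


@dataclass(frozen=True)
class GAResult:
    ranking: Ranking
    temperature: TemperatureResult
    history: tuple  # best temperature after each generation (non-increasing)
    generations: int
    evaluations: int


def ga_crossover(w: np.ndarray, p: np.ndarray, rng: np.random.Generator,
                 copy_probability: float = 0.5) -> np.ndarray:
    """Offspring permutation side from well-performing *w* and partner *p*."""
    w = np.asarray(w, dtype=np.int64)
    p = np.asarray(p, dtype=np.int64)
    n = w.shape[0]
    if p.shape[0] != n:
        raise ValueError("parent permutations must have equal length")
    if rng.random() < copy_probability:
        return w.copy()
    k = int(rng.integers(1, n + 1))
    child = np.zeros(n, dtype=np.int64)
    used = np.zeros(n + 2, dtype=bool)
    child[:k] = w[:k]
    used[w[:k]] = True
    in_prefix = used.copy()  # membership in {w_1..w_k}
    open_positions = []
    for i in range(k, n):
        if not in_prefix[p[i]]:
            child[i] = p[i]
            used[p[i]] = True
        else:
            open_positions.append(i)
    if open_positions:
        unused = np.flatnonzero(~used[1 : n + 1]) + 1  # increasing value order
        for pos, val in zip(open_positions, unused):
            child[pos] = val
    return child


def ga_mutate(o: np.ndarray, probability: float, rng: np.random.Generator) -> np.ndarray:
    """With the given probability, rotate a random slice o[k1..k2] by one position."""
    o = np.asarray(o, dtype=np.int64).copy()
    n = o.shape[0]
    if n >= 2 and rng.random() < probability:
        k1, k2 = np.sort(rng.choice(n, size=2, replace=False)) + 1
        o[k1 - 1 : k2] = np.roll(o[k1 - 1 : k2], 1)
    return o


def _seed_population(m: IncidenceMatrix, config: GAConfig, rng: np.random.Generator):
    rankings = []
    if "degree" in config.seeding:
        rankings.append(degree_ranking(m))
    if "fca" in config.seeding:
        state = fca_converge(m, delta_n=config.fca_delta_n)
        rankings.append(fca_ranking(state, m))
    while len(rankings) < config.population_size:
        rankings.append(
            Ranking(rng.permutation(m.n_rows) + 1, rng.permutation(m.n_cols) + 1)
        )
    return rankings[: config.population_size]


def _chromosome_key(c: Chromosome):
    return (c.candidate.row_order.tobytes(), c.candidate.col_order.tobytes())


class _Evaluator:
    """Memoized temperature of a ranking pair (orderings recur heavily)."""

    def __init__(self, m: IncidenceMatrix, iso):
        self._entries = m.entries.astype(bool)
        self._expected = iso.expected_mask
        self._contrib = iso.unexpectedness_grid
        self._scale = 100.0 / (UMAX * iso.n_rows * iso.n_cols)
        self._memo: dict = {}
        self.evaluations = 0

    def __call__(self, row_order: np.ndarray, col_order: np.ndarray) -> float:
        key = (row_order.tobytes(), col_order.tobytes())
        t = self._memo.get(key)
        if t is None:
            inv_r = np.argsort(row_order, kind="stable")
            inv_c = np.argsort(col_order, kind="stable")
            mismatch = self._expected != self._entries[np.ix_(inv_r, inv_c)]
            t = self._contrib[mismatch].sum() * self._scale
            self._memo[key] = t
            self.evaluations += 1
        return t


def ga_minimize(m: IncidenceMatrix, config: GAConfig | None = None) -> GAResult:
    """Minimize nestedness temperature over row/column rankings."""
    config = config or GAConfig()
    if (m.row_degrees == 0).any() or (m.col_degrees == 0).any():
        raise ValueError("matrix has empty rows or columns; clean it with drop_empty() first")
    rng = np.random.default_rng(config.seed)
    iso = calibrated_isocline(m.n_rows, m.n_cols, m.n_links)
    evaluate = _Evaluator(m, iso)

    population = [
        Chromosome(r, evaluate(r.row_order, r.col_order))
        for r in _seed_population(m, config, rng)
    ]
    member_keys = {_chromosome_key(c) for c in population}
    best = min(population, key=lambda c: c.temperature)
    best = Chromosome(best.candidate, best.temperature)
    history = [best.temperature]
    since_improvement = 0
    pop = config.population_size
    # linear rank weights: best member gets weight pop, worst gets 1
    weights = np.arange(pop, 0, -1, dtype=float)
    weights /= weights.sum()

    generation = 0
    for generation in range(1, config.max_generations + 1):
        improved = False
        for _ in range(pop):  # one generation = population_size births
            temps = [c.temperature for c in population]
            order = np.argsort(temps, kind="stable")
            w_idx = order[rng.choice(pop, p=weights)]
            p_idx = int(rng.integers(pop))
            w, partner = population[w_idx], population[p_idx]

            row_child = ga_crossover(w.candidate.row_order, partner.candidate.row_order,
                                     rng, config.copy_probability)
            col_child = ga_crossover(w.candidate.col_order, partner.candidate.col_order,
                                     rng, config.copy_probability)
            row_child = ga_mutate(row_child, config.mutation_probability, rng)
            col_child = ga_mutate(col_child, config.mutation_probability, rng)
            t_child = evaluate(row_child, col_child)

            # steady-state elitist replacement; duplicates are kept out so the
            # population stays a set of distinct candidate rankings
            worst_idx = int(np.argmax(temps))
            child_key = (row_child.tobytes(), col_child.tobytes())
            if t_child < temps[worst_idx] and child_key not in member_keys:
                member_keys.discard(_chromosome_key(population[worst_idx]))
                member_keys.add(child_key)
                population[worst_idx] = Chromosome(Ranking(row_child, col_child), t_child)
            if t_child < best.temperature:
                best = Chromosome(Ranking(row_child, col_child), t_child)
                since_improvement = 0
                improved = True
        if not improved:
            since_improvement += 1
        history.append(best.temperature)
        if since_improvement >= config.stagnation_limit:
            break

    result = temperature(m, best.candidate)
    return GAResult(
        ranking=best.candidate,
        temperature=result,
        history=tuple(history),
        generations=generation,
        evaluations=evaluate.evaluations,
    )


def brute_force_min_temperature(m: IncidenceMatrix, guard: int = 10**6):
    """Exact minimum temperature over all N! * M! ranking pairs.

    Deliberately exhaustive, for tiny test instances only; ties broken by
    lexicographic order of the (row, column) rank vectors.
    """
    n, mm = m.n_rows, m.n_cols
    if math.factorial(n) * math.factorial(mm) > guard:
        raise ValueError(f"search space {n}! * {mm}! exceeds the guard of {guard}")
    if (m.row_degrees == 0).any() or (m.col_degrees == 0).any():
        raise ValueError("matrix has empty rows or columns; clean it with drop_empty() first")
    iso = calibrated_isocline(n, mm, m.n_links)
    nm = n * mm
    contrib = iso.unexpectedness_grid
    expected = iso.expected_mask
    entries = m.entries.astype(bool)
    best_u = math.inf
    best_pair = None
    for row_order in itertools.permutations(range(1, n + 1)):
        inv_r = np.argsort(np.asarray(row_order))
        rows = entries[inv_r]
        for col_order in itertools.permutations(range(1, mm + 1)):
            inv_c = np.argsort(np.asarray(col_order))
            u = contrib[expected != rows[:, inv_c]].sum()
            if u < best_u - 1e-15:
                best_u = u
                best_pair = (row_order, col_order)
    ranking = Ranking(np.asarray(best_pair[0]), np.asarray(best_pair[1]))
    return ranking, 100.0 * (best_u / nm) / UMAX
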