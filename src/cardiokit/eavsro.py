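"""Ship-rescue population metaheuristic with a fitness-adaptive step coefficient.

The base algorithm (ship rescue optimization, SRO) moves each candidate toward
or away from the current "prey" (population-best) position, scaled by a random
coefficient r in [0, 1].  The enhanced variant implemented here (EAVSRO)
replaces that uniform coefficient with a ratio computed once per generation
from the population's fitness statistics,

    v = worst / (center + worst + best),

where ``center`` is the population mean fitness.  When the population is
spread out (worst >> best) the coefficient approaches 1 and the search takes
large exploratory steps; as the population converges the coefficient shrinks
and the search focuses.  All objectives are minimized, acceptance is greedy
(a moved candidate replaces its parent only on improvement), so the best
fitness trace is monotonically non-increasing.

The per-gene move is

    x_new = x + v * (q - I * x)   if  F(prey) <  F(candidate)
    x_new = x + v * (x - q)       otherwise,

with q the prey position and I an intensity coefficient drawn uniformly from
{1, 2} per gene.  Positions are clamped to the search bounds after every move.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, EvaluationError, ShapeError, StateError

__all__ = [
    "Bounds",
    "Candidate",
    "FitnessStats",
    "OptimizerConfig",
    "OptimizationTrace",
    "initialize_population",
    "compute_adaptive_v",
    "sro_update",
    "clamp_to_bounds",
    "optimize",
]


@dataclass(frozen=True)
class Bounds:
    """Per-gene box constraints of the search space."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ConfigurationError("bounds must be 1-D vectors of equal length")
        if not np.all(self.lower < self.upper):
            raise ConfigurationError("every lower bound must be strictly below its upper bound")

    @property
    def n_genes(self) -> int:
        return self.lower.size

    def contains(self, genes: np.ndarray) -> bool:
        return bool(np.all(genes >= self.lower) and np.all(genes <= self.upper))


@dataclass
class Candidate:
    """One solution: a bounded real gene vector plus its objective value."""

    genes: np.ndarray
    fitness: float | None = None

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=float)

    @property
    def evaluated(self) -> bool:
        return self.fitness is not None


@dataclass(frozen=True)
class FitnessStats:
    """Best / worst / mean fitness of one generation (all minimized, >= 0)."""

    best: float
    worst: float
    center: float

    @classmethod
    def from_population(cls, population: list[Candidate]) -> "FitnessStats":
        values = np.array([c.fitness for c in population], dtype=float)
        return cls(best=float(values.min()), worst=float(values.max()),
                   center=float(values.mean()))


@dataclass(frozen=True)
class OptimizerConfig:
    """Run settings.  Defaults: population 10, 50 iterations."""

    population_size: int = 10
    max_iterations: int = 50
    chromosome_length: int = 3
    seed: int = 0
    v_mode: str = "adaptive"  # "adaptive" (EAVSRO) or "random" (baseline SRO)

    def __post_init__(self):
        if self.population_size < 2:
            raise ConfigurationError("population_size must be at least 2")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be positive")
        if self.chromosome_length < 1:
            raise ConfigurationError("chromosome_length must be positive")
        if self.v_mode not in ("adaptive", "random"):
            raise ConfigurationError(f"unknown v_mode {self.v_mode!r}")


@dataclass
class OptimizationTrace:
    """Convergence record of one run.

    ``best_fitness_per_iteration`` holds the incumbent best after the initial
    evaluation (entry 0) and after each generation; with greedy acceptance it
    is non-increasing.
    """

    best_fitness_per_iteration: np.ndarray
    best_candidate: Candidate
    evaluations: int

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["iteration", "best_fitness"])
            for i, value in enumerate(self.best_fitness_per_iteration):
                writer.writerow([i, repr(float(value))])


def initialize_population(bounds: Bounds, config: OptimizerConfig,
                          rng_seed=None) -> list[Candidate]:
    """Draw ``population_size`` candidates uniformly within the bounds.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``;
    when omitted, ``config.seed`` is used.
    """
    if isinstance(rng_seed, np.random.Generator):
        rng = rng_seed
    else:
        rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    genes = rng.uniform(bounds.lower, bounds.upper,
                        size=(config.population_size, bounds.n_genes))
    return [Candidate(genes=row) for row in genes]


def compute_adaptive_v(stats: FitnessStats) -> float:
    """Fitness-adaptive step coefficient v = worst / (center + worst + best).

    Lies in [0, 1] for non-negative statistics because the denominator always
    dominates the numerator.  A fully degenerate population (all statistics
    zero) yields 0 with a warning.
    """
    denominator = stats.center + stats.worst + stats.best
    if denominator <= 0.0:
        warnings.warn("degenerate population: all fitness statistics are zero; v set to 0",
                      stacklevel=2)
        return 0.0
    return stats.worst / denominator


def clamp_to_bounds(genes: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Project each gene onto its [lower, upper] interval."""
    genes = np.asarray(genes, dtype=float)
    if genes.shape != bounds.lower.shape:
        raise ShapeError(f"gene vector of length {genes.size} does not match "
                         f"bounds of length {bounds.n_genes}")
    return np.clip(genes, bounds.lower, bounds.upper)


def sro_update(candidate: Candidate, prey: Candidate, v: float,
               intensity_rng=None, intensity=None) -> np.ndarray:
    """One rescue move of ``candidate`` relative to ``prey``.

    If the prey is strictly fitter, the candidate moves toward it with a
    per-gene intensity I in {1, 2}; otherwise it moves away.  ``intensity``
    may be forced (scalar or per-gene array) for testing; otherwise it is
    drawn from ``intensity_rng``.
    """
    if not candidate.evaluated or not prey.evaluated:
        raise StateError("both candidate and prey must be evaluated before an update")
    x = candidate.genes
    q = prey.genes
    if prey.fitness < candidate.fitness:
        if intensity is None:
            if intensity_rng is None:
                raise StateError("intensity_rng required when intensity is not forced")
            intensity = intensity_rng.integers(1, 3, size=x.shape)
        return x + v * (q - np.asarray(intensity) * x)
    return x + v * (x - q)


def _evaluate(objective, genes: np.ndarray) -> float:
    value = float(objective(genes))
    if not np.isfinite(value):
        raise EvaluationError(f"objective returned non-finite value {value!r} "
                              f"for candidate {np.array2string(genes, precision=6)}")
    return value


def optimize(objective, bounds: Bounds, config: OptimizerConfig) -> OptimizationTrace:
    """Minimize ``objective`` over ``bounds``.

    Each generation recomputes the fitness statistics, derives the shared step
    coefficient v (or draws it uniformly in baseline mode), moves every
    candidate relative to the current population best, clamps to bounds and
    accepts greedily.  The total number of objective evaluations is exactly
    ``population_size * (max_iterations + 1)``.
    """
    rng = np.random.default_rng(config.seed)
    population = initialize_population(bounds, config, rng)
    for candidate in population:
        candidate.fitness = _evaluate(objective, candidate.genes)
    evaluations = len(population)

    incumbent = min(population, key=lambda c: c.fitness)
    best = Candidate(genes=incumbent.genes.copy(), fitness=incumbent.fitness)
    history = [best.fitness]

    for _ in range(config.max_iterations):
        stats = FitnessStats.from_population(population)
        if config.v_mode == "adaptive":
            v = compute_adaptive_v(stats)
        else:
            v = float(rng.uniform())
        prey = min(population, key=lambda c: c.fitness)
        prey = Candidate(genes=prey.genes.copy(), fitness=prey.fitness)
        for j, candidate in enumerate(population):
            trial = clamp_to_bounds(sro_update(candidate, prey, v, rng), bounds)
            fitness = _evaluate(objective, trial)
            evaluations += 1
            if fitness < candidate.fitness:
                population[j] = Candidate(genes=trial, fitness=fitness)
        generation_best = min(population, key=lambda c: c.fitness)
        if generation_best.fitness < best.fitness:
            best = Candidate(genes=generation_best.genes.copy(),
                             fitness=generation_best.fitness)
        history.append(best.fitness)

    return OptimizationTrace(best_fitness_per_iteration=np.array(history),
                             best_candidate=best, evaluations=evaluations)
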