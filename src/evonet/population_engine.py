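"""Wright-Fisher-style forward simulation of a population of regulatory networks.

The population holds ``N`` haploid individuals with non-overlapping
generations and constant size.  Each generation, every offspring draws its
parent(s) with probability proportional to fitness, inherits the regulatory
regions (optionally recombined), acquires Poisson-distributed bit-flip
mutations, matures its expression dynamics and is assigned a fitness.

The reproduction loop is generic over a *model* object that maps genotypes
to fitness, so the full regulatory-network model and the GRN-less baseline
(see :mod:`evonet.experiments`) share the identical selection and
reproduction code path and differ only in the genotype-to-fitness map.

Default parameters: N=100 haploids, n=10 genes with 30-bit regions,
mu=0.005 mutations per genome per generation, selection intensity
1/sigma^2 = 1/5 toward the all-ones optimum, 15,000 generations, maturation
step cap 10,000.  Newborns start maturation from the constant all-ones
expression vector; because generation-0 cis regions accept no regulation,
every generation-0 individual nevertheless matures to the all-off
phenotype.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .cli_io import RngStreams
from .maturation_fitness import (
    DEFAULT_STEP_CAP,
    MaturationResult,
    OptimumSpec,
    Outcome,
    evaluate_individual,
)
from .regulatory_genome import Genome, build_interaction_matrix
from .variation import (
    TYPE_BIT_PROB,
    apply_mutations,
    draw_events,
    recombine_breakpoint,
    recombine_wagner,
)

__all__ = [
    "SimulationConfig",
    "Individual",
    "GenerationStats",
    "RunResult",
    "GrnModel",
    "initialize_population",
    "select_parents",
    "next_generation",
    "run",
]

_RECOMBINATION_MODELS = ("none", "wagner", "r1r2")


@dataclass
class SimulationConfig:
    """Run parameters; defaults mirror the standard study conditions."""

    N: int = 100
    n: int = 10
    L: int = 30
    mu: float = 0.005
    sigma2: float = 5.0
    optimum: Optional[str] = None  # '0'/'1' string; default all-ones
    neutral_mask: Optional[str] = None  # '1' marks a neutrally evolving gene
    recombination_model: str = "none"
    recombination_prob: Optional[float] = None  # default 0.5 when a model is enabled
    generations: int = 15_000
    step_cap: int = DEFAULT_STEP_CAP
    initial_expression: Optional[str] = None  # birth state; default all-ones
    init_strength_bits: str = "zeros"  # zeros | random | ones
    seed: int = 0
    genotype_identity: str = "genome"  # genome | matrix_sign
    zero_fitness_policy: str = "abort"  # abort | uniform
    type_bit_prob: float = TYPE_BIT_PROB

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("population size N must be >= 1")
        if self.n < 1 or self.L < 2:
            raise ValueError("need n >= 1 genes of region length L >= 2")
        if self.mu < 0:
            raise ValueError("mutation rate mu must be non-negative")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.recombination_model not in _RECOMBINATION_MODELS:
            raise ValueError(f"recombination_model must be one of {_RECOMBINATION_MODELS}")
        if self.recombination_prob is None:
            self.recombination_prob = 0.5 if self.recombination_model != "none" else 0.0
        if not 0.0 <= self.recombination_prob <= 1.0:
            raise ValueError("recombination_prob must lie in [0, 1]")
        if self.init_strength_bits not in ("random", "zeros", "ones"):
            raise ValueError("init_strength_bits must be random, zeros or ones")
        if self.genotype_identity not in ("genome", "matrix_sign"):
            raise ValueError("genotype_identity must be genome or matrix_sign")
        if self.zero_fitness_policy not in ("abort", "uniform"):
            raise ValueError("zero_fitness_policy must be abort or uniform")
        for name in ("optimum", "neutral_mask", "initial_expression"):
            val = getattr(self, name)
            if val is not None and (len(val) != self.n or set(val) - {"0", "1"}):
                raise ValueError(f"{name} must be a length-{self.n} string of 0/1")

    def optimum_spec(self) -> OptimumSpec:
        opt = self.optimum if self.optimum is not None else "1" * self.n
        return OptimumSpec.from_strings(opt, self.neutral_mask, self.sigma2)

    def initial_state(self) -> np.ndarray:
        """Constant expression vector newborns start maturation from.

        Defaults to all-ones: under the strict-positive threshold the
        all-zero state is absorbing, so a nonzero constant start is needed
        for regulation to act at all.
        """
        if self.initial_expression is None:
            return np.ones(self.n, dtype=np.int8)
        return np.array([int(c) for c in self.initial_expression], dtype=np.int8)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Individual:
    """One haploid: genome, its interaction matrix, and the cached
    maturation/fitness evaluation (all consistent with each other)."""

    genome: Genome
    matrix: np.ndarray
    fitness: float
    maturation: MaturationResult
    _genome_key: Optional[bytes] = field(default=None, repr=False)

    def genotype_key(self, identity: str = "genome") -> bytes:
        if identity == "matrix_sign":
            return np.sign(self.matrix).astype(np.int8).tobytes()
        if self._genome_key is None:
            self._genome_key = self.genome.key()
        return self._genome_key


@dataclass
class GenerationStats:
    generation: int
    mean_fitness: float
    max_fitness: float
    viable_count: int
    distinct_genotypes: int
    cumulative_distinct: int
    cross_partition_mean: Optional[float] = None


@dataclass
class RunResult:
    stats: list
    population: list


# ---------------------------------------------------------------------------
# The full regulatory-network model

class GrnModel:
    """Genotype = regulatory genome; phenotype via maturation of the
    interaction matrix; fitness via distance of the matured expression
    vector from the optimum."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.optimum = config.optimum_spec()
        self.initial_state = config.initial_state()
        neutral = ~self.optimum.selected
        self.neutral_mask = neutral if neutral.any() and not neutral.all() else None

    # -- construction -------------------------------------------------
    def founder(self, rng: np.random.Generator) -> Individual:
        """Generation-0 genotype: cis regions accept no regulation (type bit
        0), trans regions are activators (type bit 1); strength bits follow
        the configured policy.  The population starts clonal."""
        cfg = self.config
        n, L = cfg.n, cfg.L
        if cfg.init_strength_bits == "random":
            cis_s = rng.integers(0, 2, size=(n, L - 1), dtype=np.uint8)
            trans_s = rng.integers(0, 2, size=(n, L - 1), dtype=np.uint8)
        else:
            fill = 0 if cfg.init_strength_bits == "zeros" else 1
            cis_s = np.full((n, L - 1), fill, dtype=np.uint8)
            trans_s = np.full((n, L - 1), fill, dtype=np.uint8)
        cis = np.hstack([cis_s, np.zeros((n, 1), dtype=np.uint8)])
        trans = np.hstack([trans_s, np.ones((n, 1), dtype=np.uint8)])
        genome = Genome(cis, trans)
        return self._evaluate(genome, build_interaction_matrix(genome))

    def initialize(self, rng: np.random.Generator) -> list:
        founder = self.founder(rng)
        return [founder] * self.config.N

    def _evaluate(self, genome: Genome, matrix: np.ndarray) -> Individual:
        fit, mat = evaluate_individual(
            matrix, self.initial_state, self.optimum, self.config.step_cap
        )
        return Individual(genome, matrix, fit, mat)

    # -- reproduction hooks -------------------------------------------
    def mutate(self, genome: Genome, matrix: np.ndarray, count: int, rng: np.random.Generator):
        events = self._draw_events(count, rng)
        return apply_mutations(genome, matrix, events)

    def _draw_events(self, count: int, rng: np.random.Generator) -> list[MutationEvent]:
        cfg = self.config
        return draw_events(count, cfg.n, cfg.L, rng, cfg.type_bit_prob)

    def offspring(self, parents: list, two_parents: bool, mutation_count: int,
                  rec_rng: np.random.Generator, mut_rng: np.random.Generator) -> Individual:
        if two_parents:
            if self.config.recombination_model == "wagner":
                genome = recombine_wagner(parents[0].genome, parents[1].genome, rec_rng)
            else:
                genome = recombine_breakpoint(parents[0].genome, parents[1].genome, rec_rng)
            matrix = None
            # a recombinant identical to a parent inherits its evaluation
            key = genome.key()
            for p in parents[:2]:
                if p.genotype_key("genome") == key:
                    if mutation_count == 0:
                        return p
                    genome, matrix = p.genome, p.matrix
                    break
            if matrix is None:
                matrix = build_interaction_matrix(genome)
        elif mutation_count == 0:
            return parents[0]  # faithful copy: shares the parent's evaluation
        else:
            genome, matrix = parents[0].genome, parents[0].matrix
        if mutation_count:
            genome, matrix = self.mutate(genome, matrix, mutation_count, mut_rng)
        return self._evaluate(genome, matrix)

    # -- bookkeeping ---------------------------------------------------
    def genotype_key(self, ind: Individual) -> bytes:
        return ind.genotype_key(self.config.genotype_identity)

    def is_viable(self, ind: Individual) -> bool:
        return ind.maturation.outcome is not Outcome.NON_VIABLE

    def extra_stat(self, population: list) -> Optional[float]:
        if self.neutral_mask is None:
            return None
        from .experiments import cross_partition_interactions

        return float(
            np.mean([cross_partition_interactions(ind.matrix, self.neutral_mask)
                     for ind in population])
        )


# ---------------------------------------------------------------------------
# Engine operations

def initialize_population(config: SimulationConfig, rng: np.random.Generator) -> list:
    """N clonal generation-0 individuals (matrices all zero, so every
    individual matures to the all-off phenotype)."""
    return GrnModel(config).initialize(rng)


def select_parents(
    population: list,
    count: int,
    rng: np.random.Generator,
    zero_fitness_policy: str = "abort",
) -> np.ndarray:
    """Fitness-proportional i.i.d. parent draws (indices into the population).

    Individuals of fitness 0 are never chosen.  If every individual has
    fitness 0 the configured policy applies: 'abort' raises, 'uniform'
    falls back to pure drift.
    """
    fits = np.array([ind.fitness for ind in population], dtype=np.float64)
    total = fits.sum()
    if total <= 0:
        if zero_fitness_policy == "abort":
            raise RuntimeError(
                "all individuals have fitness 0; no parent can be selected "
                "(set zero_fitness_policy='uniform' for pure drift)"
            )
        weights = np.full(len(population), 1.0 / len(population))
    else:
        weights = fits / total
    return rng.choice(len(population), size=count, p=weights)


def _generation_stats(
    population: list, generation: int, cumulative: set, model
) -> GenerationStats:
    keys = {model.genotype_key(ind) for ind in population}
    cumulative.update(keys)
    fits = np.array([ind.fitness for ind in population])
    return GenerationStats(
        generation=generation,
        mean_fitness=float(fits.mean()),
        max_fitness=float(fits.max()),
        viable_count=int(sum(model.is_viable(ind) for ind in population)),
        distinct_genotypes=len(keys),
        cumulative_distinct=len(cumulative),
        cross_partition_mean=model.extra_stat(population),
    )


def next_generation(
    population: list,
    config: SimulationConfig,
    streams: RngStreams,
    model=None,
) -> list:
    """Produce the next (non-overlapping, equal-size) generation."""
    if model is None:
        model = GrnModel(config)
    N = config.N
    first = select_parents(population, N, streams.selection, config.zero_fitness_policy)
    if config.recombination_model != "none" and config.recombination_prob > 0:
        two = streams.recombination.random(N) < config.recombination_prob
        second = select_parents(population, N, streams.selection, config.zero_fitness_policy)
    else:
        two = np.zeros(N, dtype=bool)
        second = first
    counts = streams.mutation.poisson(config.mu, N) if config.mu > 0 else np.zeros(N, dtype=np.int64)
    offspring = []
    for k in range(N):
        parents = [population[first[k]], population[second[k]]]
        offspring.append(
            model.offspring(parents, bool(two[k]), int(counts[k]),
                            streams.recombination, streams.mutation)
        )
    return offspring


def run(
    config: SimulationConfig,
    model=None,
    callback: Optional[Callable] = None,
) -> RunResult:
    """Execute the full forward simulation.

    Emits one :class:`GenerationStats` record per generation including
    generation 0; the cumulative distinct-genotype counter treats the full
    genome bit-string as genotype identity (configurable).  Fully
    reproducible from ``config.seed``.  An optional ``callback(generation,
    population, streams)`` runs after each generation's stats are recorded
    (used by the experiment probes; it draws only from the experiment
    stream, leaving the trajectory unchanged).
    """
    streams = RngStreams(config.seed)
    if model is None:
        model = GrnModel(config)
    population = model.initialize(streams.initialization)
    cumulative: set = set()
    stats = [_generation_stats(population, 0, cumulative, model)]
    if callback is not None:
        callback(0, population, streams)
    for g in range(1, config.generations + 1):
        population = next_generation(population, config, streams, model)
        stats.append(_generation_stats(population, g, cumulative, model))
        if callback is not None:
            callback(g, population, streams)
    return RunResult(stats=stats, population=population)
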