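"""Experiment harnesses: robustness probing, neutral-gene accounting, and
the GRN-less mutational-buffering baseline.

*Robustness probing* clones the evolving ("core") population at discrete
time points into a "branch" population, injects a fixed number of random
mutations into every branch individual, matures both copies and measures

* expression robustness -- the mean fraction of genes whose binary
  post-maturation expression agrees between core and branch, and
* topology robustness -- the mean fraction of entries of the sign-
  discretized interaction matrices that agree.

The core population is untouched, and the probe draws from a dedicated
random stream, so probing never perturbs the evolutionary trajectory.

*Neutral-gene accounting* counts regulatory interactions that cross the
partition between genes under selection and neutrally evolving genes.

*The GRN-less baseline* strips away the regulatory layer entirely: gene
on/off states are the genotype, mutations flip them directly, and fitness
is the same exponential distance function with no maturation.  It shares
the reproduction loop of :mod:`evonet.population_engine` by dependency
injection, so comparisons with the full model differ only in the
genotype-to-fitness map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .cli_io import RngStreams
from .maturation_fitness import fitness, mature
from .population_engine import (
    GrnModel,
    RunResult,
    SimulationConfig,
    run,
)
from .variation import apply_mutations

__all__ = [
    "RobustnessRecord",
    "GrnlessIndividual",
    "GrnlessModel",
    "NOT_REACHED",
    "discretize_matrix",
    "branch_and_probe",
    "cross_partition_interactions",
    "run_grnless",
    "run_with_probes",
    "time_to_optimum",
    "time_to_population_optimum",
    "buffering_experiment",
    "exploration_experiment",
    "neutral_gene_experiment",
    "find_plateaus",
    "ladder_levels",
]

#: Sentinel for runs that never attain maximum fitness (compares greater
#: than every generation index, convenient for medians).
NOT_REACHED = math.inf


@dataclass
class RobustnessRecord:
    generation: int
    expression_robustness: float
    topology_robustness: float
    branch_mutation_count: int


def discretize_matrix(matrix: np.ndarray) -> np.ndarray:
    """Element-wise sign: positive -> 1, negative -> -1, zero stays 0."""
    return np.sign(np.asarray(matrix)).astype(np.int8)


def cross_partition_interactions(
    matrix: np.ndarray,
    neutral_mask: np.ndarray,
    expressed: Optional[np.ndarray] = None,
) -> int:
    """Number of nonzero (discretized) interactions linking a neutral gene
    with a selected gene, both directions counted separately.

    With ``expressed`` given (a binary expression vector), only interactions
    whose source gene is currently expressed are counted — an interaction
    from a silent gene contributes nothing to the dynamics.
    """
    neutral_mask = np.asarray(neutral_mask, dtype=bool)
    n = neutral_mask.size
    if not neutral_mask.any() or neutral_mask.all():
        raise ValueError("mask must contain at least one neutral and one selected gene")
    if np.asarray(matrix).shape != (n, n):
        raise ValueError("mask length must match matrix size")
    crosses = neutral_mask[:, None] != neutral_mask[None, :]
    present = discretize_matrix(matrix) != 0
    if expressed is not None:
        present &= np.asarray(expressed, dtype=bool)[None, :]
    return int(np.count_nonzero(present & crosses))


def _phenotype_identity(a: Optional[np.ndarray], b: Optional[np.ndarray], n: int) -> float:
    if a is None or b is None:
        return 0.0 if (a is None) != (b is None) else 1.0
    return float(np.count_nonzero(a == b)) / n


def branch_and_probe(
    population: list,
    branch_mutations: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    generation: int = 0,
) -> RobustnessRecord:
    """Clone the population, hit every clone with exactly ``branch_mutations``
    random bit flips, mature both copies and score their agreement.

    Mutation placement follows the standard mutation model (uniform region,
    1% type-bit chance).  Expression robustness compares the representative
    post-maturation phenotypes gene by gene; topology robustness compares
    the sign-discretized interaction matrices entry by entry.  The core
    individuals are only read, never modified.
    """
    if branch_mutations < 0:
        raise ValueError("branch_mutations must be >= 0")
    model = GrnModel(config)
    init = config.initial_state()
    n = config.n
    expr_scores, topo_scores = [], []
    for ind in population:
        events = model._draw_events(branch_mutations, rng)
        branch_genome, branch_matrix = apply_mutations(ind.genome, ind.matrix, events)
        core_res = mature(ind.matrix, init, config.step_cap)
        branch_res = mature(branch_matrix, init, config.step_cap)
        expr_scores.append(_phenotype_identity(core_res.phenotype, branch_res.phenotype, n))
        topo_scores.append(
            float(np.count_nonzero(discretize_matrix(ind.matrix) == discretize_matrix(branch_matrix)))
            / (n * n)
        )
    return RobustnessRecord(
        generation=generation,
        expression_robustness=float(np.mean(expr_scores)),
        topology_robustness=float(np.mean(topo_scores)),
        branch_mutation_count=branch_mutations,
    )


def run_with_probes(
    config: SimulationConfig,
    interval: int,
    branch_mutations: int = 15,
) -> tuple[RunResult, list]:
    """Full simulation with a robustness probe every ``interval``
    generations (generation 0 included).  Probes draw exclusively from the
    experiment stream, so the evolutionary trajectory is identical to a run
    without probes."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    records: list[RobustnessRecord] = []

    def probe(generation: int, population: list, streams: RngStreams) -> None:
        if generation % interval == 0:
            records.append(
                branch_and_probe(population, branch_mutations, config,
                                 streams.experiment, generation)
            )

    result = run(config, callback=probe)
    return result, records


# ---------------------------------------------------------------------------
# GRN-less baseline

@dataclass
class GrnlessIndividual:
    """Baseline genotype: the on/off states themselves, no regulatory layer."""

    states: np.ndarray
    fitness: float
    _key: Optional[bytes] = field(default=None, repr=False)


class GrnlessModel:
    """Drop-in model for the shared reproduction loop: mutations flip gene
    states directly (Poisson(mu) flips per genome, uniform over genes) and
    fitness is the exponential distance of the states from the optimum,
    with no maturation step."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.optimum = config.optimum_spec()
        # start from the all-off phenotype, matching the matured state of a
        # generation-0 regulatory genome
        self.initial_state = np.zeros(config.n, dtype=np.int8)

    def initialize(self, rng: np.random.Generator) -> list:
        founder = self._evaluate(self.initial_state.copy())
        return [founder] * self.config.N

    def _evaluate(self, states: np.ndarray) -> GrnlessIndividual:
        return GrnlessIndividual(states, fitness(states, self.optimum))

    def offspring(self, parents: list, two_parents: bool, mutation_count: int,
                  rec_rng: np.random.Generator, mut_rng: np.random.Generator) -> GrnlessIndividual:
        n = self.config.n
        if two_parents:
            j = int(rec_rng.integers(1, n))
            states = np.concatenate([parents[0].states[:j], parents[1].states[j:]])
        elif mutation_count == 0:
            return parents[0]
        else:
            states = parents[0].states
        if mutation_count:
            states = states.copy()
            for g in mut_rng.integers(0, n, size=mutation_count):
                states[g] ^= 1
        return self._evaluate(states)

    def genotype_key(self, ind: GrnlessIndividual) -> bytes:
        if ind._key is None:
            ind._key = ind.states.tobytes()
        return ind._key

    def is_viable(self, ind: GrnlessIndividual) -> bool:
        return True

    def extra_stat(self, population: list) -> Optional[float]:
        return None


def run_grnless(config: SimulationConfig) -> RunResult:
    """Run the baseline model through the identical engine loop."""
    return run(config, model=GrnlessModel(config))


# ---------------------------------------------------------------------------
# Analysis helpers

def time_to_optimum(stats: list) -> float:
    """First generation at which some individual attains fitness 1 (matches
    the optimum at every selected gene); :data:`NOT_REACHED` otherwise."""
    for rec in stats:
        if rec.max_fitness >= 1.0:
            return rec.generation
    return NOT_REACHED


def time_to_population_optimum(stats: list, threshold: float = 0.95) -> float:
    """First generation at which the population *mean* fitness reaches
    ``threshold``; :data:`NOT_REACHED` otherwise.

    A single lucky offspring can touch the optimum even under crushing
    mutational load, so mutation-selection-balance effects are only visible
    at the population level.
    """
    for rec in stats:
        if rec.mean_fitness >= threshold:
            return rec.generation
    return NOT_REACHED


def buffering_experiment(
    mu_grid: list,
    replicates: int,
    base_config: SimulationConfig,
    seed: int = 0,
    attainment: str = "population",
) -> list:
    """Time-to-optimum of the full model vs the GRN-less baseline across a
    mutation-rate grid.

    ``attainment`` selects the statistic: ``"population"`` (mean fitness
    reaches 0.95; default, sensitive to mutational load) or
    ``"individual"`` (first touch by any individual).  Returns records
    ``(model, mu, replicate, time)``; each replicate runs both models at
    the same mu with its own seed.
    """
    measure = time_to_population_optimum if attainment == "population" else time_to_optimum
    records = []
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(len(mu_grid) * replicates, dtype=np.uint32)
    k = 0
    for mu in mu_grid:
        for rep in range(replicates):
            cfg = replace(base_config, mu=float(mu), seed=int(seeds[k]))
            k += 1
            records.append(("grn", mu, rep, measure(run(cfg).stats)))
            records.append(("grnless", mu, rep, measure(run_grnless(cfg).stats)))
    return records


def neutral_gene_experiment(
    base_config: SimulationConfig,
    replicates: int,
    seed: int = 0,
) -> list:
    """Cross-partition interaction counts while climbing vs at the optimum.

    Each replicate evolves a population whose optimum constrains only the
    selected genes (the configured neutral mask marks the rest), then
    splits the per-generation mean cross-partition count into an ascent
    phase (mean fitness first above its initial level by more than 1/N,
    until the optimum is first touched) and a post-optimum phase.  Returns
    per-replicate ``(ascent_mean, post_mean, t_optimum)`` tuples; replicates
    that never reach the optimum report ``NOT_REACHED`` and NaN means.
    """
    if base_config.neutral_mask is None:
        raise ValueError("base_config must set a neutral_mask")
    seeds = np.random.SeedSequence(seed).generate_state(replicates, dtype=np.uint32)
    out = []
    for r in range(replicates):
        cfg = replace(base_config, seed=int(seeds[r]))
        stats = run(cfg).stats
        f0 = stats[0].mean_fitness
        tto = time_to_optimum(stats)
        rise = next(
            (s.generation for s in stats if s.mean_fitness > f0 + 1.0 / cfg.N), None
        )
        if tto == NOT_REACHED or rise is None or rise >= tto:
            out.append((math.nan, math.nan, NOT_REACHED))
            continue
        x = [s.cross_partition_mean for s in stats]
        t = int(tto)
        out.append((float(np.mean(x[rise:t])), float(np.mean(x[t:])), t))
    return out


def exploration_experiment(
    base_config: SimulationConfig,
    replicates: int,
    seed: int = 0,
) -> dict:
    """Cumulative distinct-genotype counts under selection vs neutrality.

    The selection scenario evolves toward the configured optimum with R1R2
    recombination (two-parent probability 0.5), so novel genotypes arise
    from both mutation and recombination of the co-segregating networks
    that selection maintains.  The neutral scenario leaves genotype
    frequencies to mutation and genetic drift alone (all genes free of
    selection, no recombination).  Returns per-replicate final cumulative
    counts under ``{"selection": [...], "neutral": [...]}``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * replicates, dtype=np.uint32)
    out: dict = {"selection": [], "neutral": []}
    for r in range(replicates):
        sel_cfg = replace(base_config, neutral_mask=None,
                          recombination_model="r1r2", recombination_prob=0.5,
                          seed=int(seeds[2 * r]))
        neu_cfg = replace(base_config, neutral_mask="1" * base_config.n,
                          recombination_model="none", recombination_prob=0.0,
                          seed=int(seeds[2 * r + 1]))
        out["selection"].append(run(sel_cfg).stats[-1].cumulative_distinct)
        out["neutral"].append(run(neu_cfg).stats[-1].cumulative_distinct)
    return out


def ladder_levels(n_selected: int, sigma2: float) -> np.ndarray:
    """The discrete set of attainable fixed-point fitness values
    exp(-sqrt(k)/sigma2), k = 0..n_selected."""
    return np.exp(-np.sqrt(np.arange(n_selected + 1)) / sigma2)


def find_plateaus(
    mean_fitness: np.ndarray,
    min_length: int = 200,
    tolerance: float = 0.01,
) -> list:
    """Maximal runs of consecutive generations whose mean fitness stays
    within ``tolerance`` (peak-to-peak) for at least ``min_length``
    generations.  Returns (start, end_exclusive, level) with level = the
    segment mean."""
    f = np.asarray(mean_fitness, dtype=float)
    plateaus = []
    start = 0
    lo = hi = f[0] if f.size else 0.0
    for t in range(1, f.size + 1):
        if t < f.size:
            new_lo, new_hi = min(lo, f[t]), max(hi, f[t])
        if t == f.size or new_hi - new_lo > tolerance:
            if t - start >= min_length:
                plateaus.append((start, t, float(f[start:t].mean())))
            if t < f.size:
                start = t  # greedy restart; transition segments are short and get dropped
                lo = hi = f[t]
        else:
            lo, hi = new_lo, new_hi
    return plateaus
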