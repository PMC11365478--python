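"""Heritable variation: Poisson bit-flip mutations and two recombination models.

Mutation: the number of bit flips per offspring genome is Poisson(mu).
Each flip lands on one of the 2n regulatory regions uniformly.  Within a
*trans* region it hits the type bit with probability 1% and otherwise a
uniformly chosen strength bit: mutations that switch an established
regulator between activator and repressor are rare compared with mutations
that tune interaction strength.  Within a *cis* region all L positions are
hit uniformly — gaining or losing the ability to accept regulation is an
ordinary promoter-scale mutation, not a rare qualitative switch.

Recombination:

* ``wagner`` -- the classical row-swap model: the child keeps one parent's
  trans regions while each cis region independently comes from either
  parent (p = 1/2).  Interactions are re-estimated from the resulting
  regions, not copied from the parents.
* ``r1r2`` -- a single crossover breakpoint j (0 < j < n): the first j
  genes inherit both regions from one parent, the rest from the other, and
  cross-block interactions are recomputed from the child's regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regulatory_genome import Genome, refresh_after_mutation

__all__ = [
    "MutationEvent",
    "TYPE_BIT_PROB",
    "draw_events",
    "draw_mutations",
    "apply_mutations",
    "recombine_wagner",
    "recombine_breakpoint",
]

#: Probability that a trans-region mutation hits the type bit.
TYPE_BIT_PROB = 0.01


@dataclass(frozen=True)
class MutationEvent:
    """A single bit flip.  ``bit_position`` is 1-based: 1..L-1 are strength
    bits, L is the type bit (matching the on-disk genome format)."""

    gene_index: int
    region_kind: str  # "cis" | "trans"
    bit_position: int


def draw_events(
    count: int,
    n: int,
    L: int,
    rng: np.random.Generator,
    type_bit_prob: float = TYPE_BIT_PROB,
) -> list[MutationEvent]:
    """Place ``count`` mutation events: region uniform among the 2n regions;
    cis positions uniform over all L bits, trans positions type bit with
    probability ``type_bit_prob`` else uniform over the L-1 strength bits."""
    events = []
    for _ in range(count):
        region = int(rng.integers(2 * n))
        gene_index, kind = region // 2, ("cis", "trans")[region % 2]
        if kind == "cis":
            pos = int(rng.integers(1, L + 1))
        elif rng.random() < type_bit_prob:
            pos = L
        else:
            pos = int(rng.integers(1, L))
        events.append(MutationEvent(gene_index, kind, pos))
    return events


def draw_mutations(
    n: int,
    L: int,
    mu: float,
    rng: np.random.Generator,
    type_bit_prob: float = TYPE_BIT_PROB,
) -> list[MutationEvent]:
    """Draw Poisson(mu) mutation events for one offspring genome."""
    if mu < 0:
        raise ValueError("mutation rate mu must be non-negative")
    return draw_events(int(rng.poisson(mu)), n, L, rng, type_bit_prob)


def apply_mutations(
    genome: Genome,
    matrix: np.ndarray,
    events: list[MutationEvent],
) -> tuple[Genome, np.ndarray]:
    """Flip the named bits and refresh the interaction matrix incrementally.

    The inputs are never modified; with an empty event list they are
    returned as-is.  A cis flip triggers a row refresh, a trans flip a
    column refresh, so the returned matrix stays consistent with the
    returned genome.
    """
    if not events:
        return genome, matrix
    genome = genome.copy()
    matrix = np.array(matrix, dtype=np.float64, copy=True)
    for ev in events:
        if not 0 <= ev.gene_index < genome.n:
            raise IndexError(f"gene index {ev.gene_index} out of range")
        if not 1 <= ev.bit_position <= genome.L:
            raise IndexError(f"bit position {ev.bit_position} outside 1..L")
        regions = genome.cis if ev.region_kind == "cis" else genome.trans
        regions[ev.gene_index, ev.bit_position - 1] ^= 1
        refresh_after_mutation(matrix, genome, ev.gene_index, ev.region_kind)
    return genome, matrix


def _check_parents(parent1: Genome, parent2: Genome) -> None:
    if parent1.cis.shape != parent2.cis.shape:
        raise ValueError("parents must share gene count and region length")


def recombine_wagner(parent1: Genome, parent2: Genome, rng: np.random.Generator) -> Genome:
    """Row-swap recombination: all trans regions from parent1; each cis
    region independently from parent2 with probability 1/2."""
    _check_parents(parent1, parent2)
    take_p2 = rng.random(parent1.n) < 0.5
    cis = np.where(take_p2[:, None], parent2.cis, parent1.cis)
    return Genome(cis, parent1.trans.copy())


def recombine_breakpoint(parent1: Genome, parent2: Genome, rng: np.random.Generator) -> Genome:
    """Single-breakpoint crossover: genes before the breakpoint take both
    regions from parent1, the rest from parent2.  The breakpoint is uniform
    on {1, ..., n-1}, so the child always mixes both parents."""
    _check_parents(parent1, parent2)
    n = parent1.n
    if n < 2:
        raise ValueError("breakpoint recombination needs at least two genes")
    j = int(rng.integers(1, n))
    cis = np.concatenate([parent1.cis[:j], parent2.cis[j:]])
    trans = np.concatenate([parent1.trans[:j], parent2.trans[j:]])
    return Genome(cis, trans)
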