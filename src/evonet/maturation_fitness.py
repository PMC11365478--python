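"""Expression dynamics ("maturation"), attractor classification and fitness.

A newborn individual starts from a constant binary expression vector (all
genes on) and iterates the map ``E(t+1) = M E(t)`` until the trajectory
revisits a state.  Expression is binary (a gene is on or off): at each
step the product ``M E(t)`` sums the interaction weights a gene receives
from the currently expressed genes, and the new expression value is 1 if
that input is strictly positive and 0 otherwise.  The all-off state is
therefore absorbing for a zero interaction matrix, which pins generation-0
populations (whose cis regions accept no regulation) at the all-off
phenotype.  Because the state space is finite and the map deterministic,
the trajectory always falls onto either a fixed point or a cycle; a cycle
whose detection would require more steps than the cap (default 10,000)
marks the individual as non-viable.

Fitness is stabilizing/directional selection toward an optimum expression
vector: ``F = exp(-d / sigma2)`` with ``d`` the Euclidean distance between
the (binary) phenotype and the optimum, restricted to the genes under
selection.  Genes marked FREE in the optimum evolve neutrally: their state
never enters ``d``.  Cyclic individuals score the minimum fitness over one
full period; non-viable individuals score 0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "FREE",
    "Outcome",
    "OptimumSpec",
    "MaturationResult",
    "step_expression",
    "mature",
    "fitness",
    "evaluate_individual",
    "DEFAULT_STEP_CAP",
]

#: Sentinel marking a neutrally evolving gene in an optimum vector.
FREE = -1

DEFAULT_STEP_CAP = 10_000


class Outcome(enum.Enum):
    FIXED_POINT = "fixed_point"
    CYCLE = "cycle"
    NON_VIABLE = "non_viable"


@dataclass(frozen=True)
class OptimumSpec:
    """Optimum expression vector plus selection strength.

    ``target`` holds 0/1 for genes under selection and :data:`FREE` (-1)
    for neutral genes; ``sigma2`` is the denominator of the exponential
    fitness function (larger = weaker selection).
    """

    target: np.ndarray
    sigma2: float = 5.0

    def __post_init__(self) -> None:
        target = np.ascontiguousarray(self.target, dtype=np.int8)
        object.__setattr__(self, "target", target)
        if not np.isin(target, (0, 1, FREE)).all():
            raise ValueError("optimum entries must be 0, 1 or FREE")
        if not (target != FREE).any():
            raise ValueError("at least one gene must be under selection")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")

    @property
    def selected(self) -> np.ndarray:
        """Boolean mask of genes under selection."""
        return self.target != FREE

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @classmethod
    def all_ones(cls, n: int, sigma2: float = 5.0) -> "OptimumSpec":
        return cls(np.ones(n, dtype=np.int8), sigma2)

    @classmethod
    def all_free(cls, n: int, sigma2: float = 5.0) -> "OptimumSpec":
        """Fully neutral optimum: every gene FREE except that fitness must
        remain well defined, so distance is taken over an empty set and every
        viable individual has fitness 1 (pure drift)."""
        spec = cls.__new__(cls)
        object.__setattr__(spec, "target", np.full(n, FREE, dtype=np.int8))
        object.__setattr__(spec, "sigma2", float(sigma2))
        return spec

    @classmethod
    def from_strings(
        cls, optimum: str, neutral_mask: Optional[str] = None, sigma2: float = 5.0
    ) -> "OptimumSpec":
        """Parse '1111100000'-style optimum and optional neutral mask
        (a '1' in the mask marks a neutral gene)."""
        target = np.array([int(c) for c in optimum], dtype=np.int8)
        if neutral_mask is not None:
            mask = np.array([int(c) for c in neutral_mask], dtype=bool)
            if mask.size != target.size:
                raise ValueError("neutral mask length must match optimum length")
            target[mask] = FREE
            if mask.all():
                return cls.all_free(target.size, sigma2)
        return cls(target, sigma2)


@dataclass
class MaturationResult:
    """Outcome of iterating the expression map from a given start state."""

    outcome: Outcome
    steps_taken: int
    final_state: Optional[np.ndarray] = None
    cycle_states: list = field(default_factory=list)
    period: int = 0

    @property
    def phenotype(self) -> Optional[np.ndarray]:
        """Representative post-maturation expression vector: the fixed point,
        or for cycles the recurring state that was reached first.  None for
        non-viable individuals."""
        if self.outcome is Outcome.FIXED_POINT:
            return self.final_state
        if self.outcome is Outcome.CYCLE:
            return self.cycle_states[0]
        return None


def step_expression(matrix: np.ndarray, state: np.ndarray) -> np.ndarray:
    """One synchronous update of the expression vector.

    Gene i receives input sum_j M[i, j] * state[j] — the summed interaction
    weights from the genes currently expressed — and is expressed at the
    next step iff that input is strictly positive.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    state = np.asarray(state, dtype=np.int8)
    n = state.size
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} incompatible with state length {n}")
    inp = matrix @ state.astype(np.float64)
    return (inp > 0).astype(np.int8)


def mature(
    matrix: np.ndarray,
    initial: np.ndarray,
    step_cap: int = DEFAULT_STEP_CAP,
) -> MaturationResult:
    """Iterate :func:`step_expression` until a previously visited state
    recurs, classifying the attractor.

    Every visited state is recorded with its first-visit time; on the first
    revisit with period 1 the state is a fixed point, with period k >= 2 the
    k states of one full period (in visit order) form a cycle.  If no state
    recurs within ``step_cap`` steps the individual is non-viable.
    """
    if step_cap < 1:
        raise ValueError("step_cap must be >= 1")
    state = np.asarray(initial, dtype=np.int8).copy()
    seen = {state.tobytes(): 0}
    trajectory = [state]
    for t in range(1, step_cap + 1):
        state = step_expression(matrix, state)
        first = seen.get(state.tobytes())
        if first is not None:
            period = t - first
            if period == 1:
                return MaturationResult(Outcome.FIXED_POINT, steps_taken=t, final_state=state, period=1)
            return MaturationResult(
                Outcome.CYCLE,
                steps_taken=t,
                cycle_states=trajectory[first:t],
                period=period,
            )
        seen[state.tobytes()] = t
        trajectory.append(state)
    return MaturationResult(Outcome.NON_VIABLE, steps_taken=step_cap)


def fitness(expression: Union[np.ndarray, Sequence[int]], optimum: OptimumSpec) -> float:
    """Exponential stabilizing-selection fitness exp(-d / sigma2).

    ``d`` is the Euclidean distance between expression and optimum over the
    genes under selection only; with binary states it equals the square root
    of the number of mismatched selected genes.
    """
    expression = np.asarray(expression, dtype=np.int8)
    if expression.size != optimum.target.size:
        raise ValueError("expression and optimum lengths differ")
    sel = optimum.selected
    mismatches = int(np.count_nonzero(expression[sel] != optimum.target[sel]))
    return math.exp(-math.sqrt(mismatches) / optimum.sigma2)


def evaluate_individual(
    matrix: np.ndarray,
    initial: np.ndarray,
    optimum: OptimumSpec,
    step_cap: int = DEFAULT_STEP_CAP,
) -> tuple[float, MaturationResult]:
    """Mature an individual and score it.

    Fixed points score the fitness of the equilibrium state; cycles score
    the minimum fitness over the states of one period (transient states do
    not contribute); non-viable individuals score 0.
    """
    result = mature(matrix, initial, step_cap)
    if result.outcome is Outcome.FIXED_POINT:
        return fitness(result.final_state, optimum), result
    if result.outcome is Outcome.CYCLE:
        return min(fitness(s, optimum) for s in result.cycle_states), result
    return 0.0, result
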