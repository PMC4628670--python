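"""One-dimensional cellular automaton over a periodic lattice of reads.

The lattice holds one read per cell on a circle (cell N+1 is cell 1).  A
range-r transition rule applied at cell i compares the distance from the
read at cell i to its immediate successor against the distance to the read
r-1 cells ahead, and swaps the two candidates when the farther one is
strictly closer.  Sweeping all rules over all cells until no swap fires
sorts compositionally similar reads into contiguous stretches.

Update discipline is a sequential in-place sweep: cells are visited in
order, every rule r = 3..R (ascending) is applied at the current cell, and
each swap takes effect immediately.  This is deterministic, applies every
rule at every cell once per iteration, and empirically converges in a few
dozen iterations; a synchronous update would let two rules claim the same
cell, and sweeping ranges in the outer loop instead often fails to settle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .kmer_features import DistanceOracle, PairwiseDistanceProvider

__all__ = [
    "Lattice",
    "RuleSchedule",
    "ConvergenceReport",
    "init_lattice",
    "compute_R",
    "apply_rule",
    "run_iteration",
    "run_to_convergence",
    "is_fixpoint",
]

MIN_RULE_RANGE = 3  # a rule touches three cells, so ranges start at 3


@dataclass
class Lattice:
    """Periodic arrangement of read indices: ``order[i]`` is the read at cell i.

    ``order`` is always a permutation of 0..N-1; cells are indexed 0-based
    with periodic wrap-around.
    """

    order: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        if self.order.ndim != 1 or self.order.size < 1:
            raise ValueError("lattice order must be a non-empty 1-D index array")

    @property
    def n(self) -> int:
        return self.order.size

    def copy(self) -> "Lattice":
        return Lattice(self.order.copy())


@dataclass(frozen=True)
class RuleSchedule:
    """Sweep plan for one iteration: ranges r = 3..R at cells i = 0..N-1.

    Cells are the outer loop, ranges the inner one; both ascend.  ``R``
    must allow at least the minimum range 3 and stay below N so a rule
    never wraps onto itself.
    """

    R: int

    def __post_init__(self) -> None:
        if self.R < MIN_RULE_RANGE:
            raise ValueError(f"R must be >= {MIN_RULE_RANGE}, got {self.R}")

    @property
    def ranges(self) -> range:
        return range(MIN_RULE_RANGE, self.R + 1)


@dataclass
class ConvergenceReport:
    """Outcome of iterating the automaton to a fixpoint."""

    iterations_run: int
    converged: bool
    swaps_per_iteration: list[int]
    state_trace: list[np.ndarray] | None = field(default=None, repr=False)


def init_lattice(n_reads: int, seed: int) -> Lattice:
    """Place reads on cells uniformly at random, reproducibly per seed."""
    if n_reads < 1:
        raise ValueError(f"need at least one read, got {n_reads}")
    rng = np.random.default_rng(seed)
    return Lattice(rng.permutation(n_reads).astype(np.int64))


def compute_R(n_cells: int) -> int:
    """Default maximum rule range for an N-cell lattice.

    R = max(3, floor(sqrt(N))), capped at N-1.  Square-root ranges let
    clusters of roughly sqrt(N) cells merge while keeping one iteration at
    O(N * R) rule applications.
    """
    if n_cells < 4:
        raise ValueError(
            f"need at least 4 cells to apply a range-3 rule, got {n_cells}"
        )
    return max(MIN_RULE_RANGE, min(n_cells - 1, math.isqrt(n_cells)))


def apply_rule(lattice: Lattice, i: int, r: int, d: DistanceOracle) -> bool:
    """Apply the range-r swap rule at cell i; return whether a swap fired.

    Compares d(x_i, x_{i+1}) with d(x_i, x_{i+r-1}) (cell indices mod N) and
    swaps the reads at cells i+1 and i+r-1 iff the first distance is
    strictly larger.  Equal distances never swap.
    """
    n = lattice.n
    if not (MIN_RULE_RANGE <= r < n):
        raise ValueError(f"rule range r = {r} outside [{MIN_RULE_RANGE}, N-1] for N = {n}")
    if not (0 <= i < n):
        raise ValueError(f"cell index {i} outside 0..{n - 1}")
    order = lattice.order
    a = order[i]
    j_near = (i + 1) % n
    j_far = (i + r - 1) % n
    if d(a, order[j_near]) > d(a, order[j_far]):
        order[j_near], order[j_far] = order[j_far], order[j_near]
        return True
    return False


@njit(cache=True)
def _sweep_dense(order: np.ndarray, dist: np.ndarray, R: int) -> int:
    n = order.shape[0]
    swaps = 0
    for i in range(n):
        a = order[i]
        j_near = i + 1
        if j_near >= n:
            j_near -= n
        for r in range(3, R + 1):
            j_far = i + r - 1
            if j_far >= n:
                j_far -= n
            if dist[a, order[j_near]] > dist[a, order[j_far]]:
                tmp = order[j_near]
                order[j_near] = order[j_far]
                order[j_far] = tmp
                swaps += 1
    return swaps


def run_iteration(
    lattice: Lattice, schedule: RuleSchedule, d: DistanceOracle
) -> int:
    """Sweep every (r, i) pair once, swaps taking effect immediately.

    Returns the number of swaps performed.  When the oracle exposes a dense
    distance matrix the sweep runs through a compiled kernel; the generic
    path executes the identical loop in Python.
    """
    n = lattice.n
    if n < 4:
        raise ValueError(f"need at least 4 cells to iterate, got {n}")
    if schedule.R >= n:
        raise ValueError(f"R = {schedule.R} must be < N = {n}")
    if isinstance(d, PairwiseDistanceProvider):
        return int(_sweep_dense(lattice.order, d.matrix, schedule.R))
    swaps = 0
    for i in range(n):
        for r in schedule.ranges:
            if apply_rule(lattice, i, r, d):
                swaps += 1
    return swaps


def run_to_convergence(
    lattice: Lattice,
    schedule: RuleSchedule,
    d: DistanceOracle,
    max_iterations: int = 1000,
    *,
    trace: bool = False,
) -> ConvergenceReport:
    """Iterate the automaton until an iteration performs zero swaps.

    The lattice is modified in place.  Hitting ``max_iterations`` without a
    zero-swap iteration is reported (``converged=False``) with a warning,
    not raised.  With ``trace=True`` the cell order after every iteration
    (including the initial state) is recorded for diagnostic export.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    swaps_history: list[int] = []
    trace_states: list[np.ndarray] | None = [lattice.order.copy()] if trace else None
    converged = False
    iterations = 0
    for _ in range(max_iterations):
        swaps = run_iteration(lattice, schedule, d)
        iterations += 1
        swaps_history.append(swaps)
        if trace_states is not None:
            trace_states.append(lattice.order.copy())
        if swaps == 0:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"lattice did not converge within {max_iterations} iterations "
            f"(last iteration performed {swaps_history[-1]} swaps)",
            stacklevel=2,
        )
    return ConvergenceReport(
        iterations_run=iterations,
        converged=converged,
        swaps_per_iteration=swaps_history,
        state_trace=trace_states,
    )


def is_fixpoint(lattice: Lattice, schedule: RuleSchedule, d: DistanceOracle) -> bool:
    """Exhaustively check that no (r, i) rule would fire on the lattice.

    Pure inspection (no mutation); used as the convergence oracle.
    """
    n = lattice.n
    order = lattice.order
    for r in schedule.ranges:
        for i in range(n):
            a = order[i]
            if d(a, order[(i + 1) % n]) > d(a, order[(i + r - 1) % n]):
                return False
    return True
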