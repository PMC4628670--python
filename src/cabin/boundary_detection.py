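"""Cut the converged chain of reads into clusters.

After the automaton converges, reads from one species sit in contiguous
stretches of the circular lattice.  The chainmap — the sequence of
distances between reads at consecutive cells — shows valleys inside
clusters and spikes at their edges.  A single left-to-right scan declares
read x_i the start of a new cluster when all of the following hold
(distances d, global chainmap mean avg, running within-cluster mean/sd
avg_k and sd_k up to the previous read):

1. d(x_i, x_{i+1}) < avg                      — the new start sits in a valley;
2. d(x_{i-1}, x_i) > max(avg, avg_k + sd_k)   — the gap behind it is tall;
3. d(x_{i-1}, x_i) > d(x_i, x_{i+1}) > d(x_{i+1}, x_{i+2})
                                              — distances fall away from the
                                                gap, filtering lone spikes;
and x_i lies at least ``min_cluster_size`` cells past the current cluster's
start.  When x_i opens a new cluster, x_{i-1} closes the previous one and
the running statistics reset.

Because the lattice is circular but the scan is linear, the lattice is
first rotated so that the globally largest consecutive distance — the most
plausible inter-cluster gap — becomes the seam between the last and first
cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .ca_lattice import Lattice
from .kmer_features import DistanceOracle, PairwiseDistanceProvider

__all__ = [
    "Chainmap",
    "ClusterAssignment",
    "compute_chainmap",
    "rotate_to_seam",
    "detect_boundaries",
    "verify_boundaries",
]

DEFAULT_MIN_CLUSTER_SIZE = 30  # rule-of-thumb floor on cluster size


@dataclass
class Chainmap:
    """Consecutive-cell distances of a (converged) lattice.

    ``distances[i] = d(x_i, x_{i+1})`` with the index taken mod N, so the
    last entry closes the circle: ``distances[N-1] = d(x_{N-1}, x_0)``.
    """

    distances: np.ndarray
    global_average: float

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)

    @property
    def n(self) -> int:
        return self.distances.size


@dataclass
class ClusterAssignment:
    """Cluster ids aligned to lattice cells, in scan order.

    ``labels[i]`` is the 0-based cluster id of the read at cell i; labels
    form contiguous runs.  ``boundaries`` holds the starting cell of each
    cluster (the first is always 0).
    """

    labels: np.ndarray
    boundaries: list[int]

    @property
    def k(self) -> int:
        return len(self.boundaries)


def compute_chainmap(lattice: Lattice, d: DistanceOracle) -> Chainmap:
    """Distances between reads at consecutive cells, plus their mean."""
    n = lattice.n
    if n < 2:
        raise ValueError(f"chainmap needs at least 2 cells, got {n}")
    order = lattice.order
    if isinstance(d, PairwiseDistanceProvider):
        dist = d.matrix[order, np.roll(order, -1)]
    else:
        dist = np.array(
            [d(order[i], order[(i + 1) % n]) for i in range(n)], dtype=np.float64
        )
    return Chainmap(dist, float(dist.mean()))


def rotate_to_seam(lattice: Lattice, chainmap: Chainmap) -> tuple[Lattice, Chainmap]:
    """Rotate so the largest consecutive distance spans cells N-1 and 0.

    The linear scan then starts just after the most plausible inter-cluster
    gap instead of possibly splitting a true cluster across the wrap.  Ties
    are broken by the smallest original cell index.  Returns a rotated copy;
    the inputs are untouched.
    """
    n = lattice.n
    seam = int(np.argmax(chainmap.distances))  # first maximum wins ties
    shift = (seam + 1) % n
    order = np.roll(lattice.order, -shift)
    dist = np.roll(chainmap.distances, -shift)
    return Lattice(order), Chainmap(dist, chainmap.global_average)


class _RunningStats:
    """Streaming mean / population standard deviation (Welford)."""

    def __init__(self) -> None:
        self.count = 0
        self.mean = 0.0
        self._m2 = 0.0

    def push(self, x: float) -> None:
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self._m2 += delta * (x - self.mean)

    @property
    def sd(self) -> float:
        if self.count < 2:
            return 0.0
        return sqrt(self._m2 / self.count)


def detect_boundaries(
    chainmap: Chainmap,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    reference_average: float | None = None,
) -> ClusterAssignment:
    """Scan the chainmap and assign a contiguous cluster id to every cell.

    Expects a chainmap from a seam-rotated lattice.  A scan that never
    fires yields a single cluster (K = 1).  The running within-cluster
    statistics cover only distances between consecutive members of the
    current cluster; the gap that opened the cluster is excluded.

    ``reference_average`` is the dataset-level average distance the first
    two criteria compare against; it defaults to the chainmap's own mean.
    The pipeline passes the mean over *all* read pairs instead, which sits
    clearly above within-cluster distances and makes both criteria
    discriminative (the chain mean is dominated by within-cluster values
    once the lattice has converged).
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    dist = chainmap.distances
    n = chainmap.n
    avg = (
        chainmap.global_average if reference_average is None else reference_average
    )

    labels = np.zeros(n, dtype=np.int64)
    boundaries = [0]
    stats = _RunningStats()
    cluster_start = 0
    current = 0

    for i in range(1, n):
        d_prev = dist[i - 1]  # d(x_{i-1}, x_i)
        d_next = dist[i]  # d(x_i, x_{i+1}); wraps at i = n-1
        d_next2 = dist[(i + 1) % n]  # d(x_{i+1}, x_{i+2})
        is_start = (
            i >= cluster_start + min_cluster_size
            and d_next < avg
            and d_prev > max(avg, stats.mean + stats.sd)
            and d_prev > d_next > d_next2
        )
        if is_start:
            current += 1
            boundaries.append(i)
            cluster_start = i
            stats = _RunningStats()
        else:
            stats.push(d_prev)
        labels[i] = current

    return ClusterAssignment(labels, boundaries)


def verify_boundaries(
    chainmap: Chainmap,
    assignment: ClusterAssignment,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    reference_average: float | None = None,
) -> bool:
    """Re-check every declared cluster start against the three criteria.

    Recomputes the within-cluster statistics from scratch at each declared
    start (independent of the streaming pass) and confirms the size rule.
    Used as a post-hoc oracle in tests.
    """
    dist = chainmap.distances
    n = chainmap.n
    avg = (
        chainmap.global_average if reference_average is None else reference_average
    )
    starts = assignment.boundaries
    for b_idx, i in enumerate(starts[1:], start=1):
        prev_start = starts[b_idx - 1]
        if i < prev_start + min_cluster_size:
            return False
        # within-cluster consecutive distances of the preceding cluster:
        # d(x_{prev_start}, ...) .. d(x_{i-2}, x_{i-1})
        within = dist[prev_start : i - 1]
        mean = float(within.mean()) if within.size else 0.0
        sd = float(within.std()) if within.size >= 2 else 0.0
        d_prev, d_next, d_next2 = dist[i - 1], dist[i], dist[(i + 1) % n]
        if not (d_next < avg):
            return False
        if not (d_prev > max(avg, mean + sd)):
            return False
        if not (d_prev > d_next > d_next2):
            return False
    return True
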