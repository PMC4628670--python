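"""Binning evaluation: precision and per-species false-positive rate.

With K clusters C_1..C_K and N_s species, let R_ij be the number of reads
in cluster C_i coming from species j.  Cluster C_i is called as the species
with the largest R_ij (its majority species).  Then

    precision = sum_i max_j R_ij / sum_ij R_ij

is the fraction of reads lying in the majority species of their cluster,
and for a species s with called cluster set C_s,

    FP_r(s) = (reads in C_s from species != s) / (all reads in C_s)

measures contamination of the bins called s.  Every read is always
assigned to some cluster here, so sensitivity and F-measure coincide with
precision and are exposed only as aliases.

Counts are kept as plain Python integers: matrices are tiny (K x N_s) and
the arithmetic stays exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .boundary_detection import ClusterAssignment

__all__ = [
    "ConfusionMatrix",
    "SpeciesCall",
    "confusion_matrix",
    "call_species",
    "precision",
    "sensitivity",
    "f_measure",
    "fp_rate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cluster-by-species read counts.

    ``counts[i][j]`` is the number of reads in cluster i from species j.
    ``cluster_ids`` and ``species`` give the row / column identities, each
    ordered by first appearance in the scan.
    """

    counts: tuple[tuple[int, ...], ...]
    cluster_ids: tuple[int, ...]
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.counts or not self.counts[0]:
            raise ValueError("confusion matrix must have at least one row and column")
        if min(map(min, self.counts)) < 0:
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.counts)


@dataclass(frozen=True)
class SpeciesCall:
    """Per-cluster species calls and the induced cluster sets.

    ``calls[i]`` is the species column index called for cluster row i
    (arg max of the row; ties go to the lowest species index).
    ``index_sets[s]`` lists the cluster rows called as species s; the sets
    partition the rows and may be empty for a species never called.
    """

    calls: tuple[int, ...]
    index_sets: tuple[tuple[int, ...], ...]


def confusion_matrix(
    assignment: ClusterAssignment | Sequence[int],
    truth: Mapping[int, str] | Sequence[str],
) -> ConfusionMatrix:
    """Count reads per (cluster, species) pair.

    ``assignment`` gives each cell's cluster id in scan order (a
    :class:`ClusterAssignment` or a plain label sequence); ``truth`` maps
    the cell position to its species.  Rows and columns are ordered by
    first appearance.  A cell without a truth label is an error naming the
    position.
    """
    labels = (
        assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    )
    cluster_ids: list[int] = []
    species: list[str] = []
    cells: list[tuple[int, int]] = []
    for pos, raw in enumerate(labels):
        cid = int(raw)
        try:
            sp = truth[pos]
        except (KeyError, IndexError):
            raise ValueError(f"no truth label for read at cell {pos}") from None
        if sp is None:
            raise ValueError(f"no truth label for read at cell {pos}")
        if cid not in cluster_ids:
            cluster_ids.append(cid)
        if sp not in species:
            species.append(sp)
        cells.append((cluster_ids.index(cid), species.index(sp)))
    counts = [[0] * len(species) for _ in cluster_ids]
    for i, j in cells:
        counts[i][j] += 1
    return ConfusionMatrix(
        tuple(tuple(row) for row in counts), tuple(cluster_ids), tuple(species)
    )


def call_species(cm: ConfusionMatrix) -> SpeciesCall:
    """Call each cluster as its majority species (lowest index wins ties)."""
    sets: list[list[int]] = [[] for _ in cm.counts[0]]
    calls = []
    for i, row in enumerate(cm.counts):
        s = row.index(max(row))
        calls.append(s)
        sets[s].append(i)
    return SpeciesCall(tuple(calls), tuple(tuple(s) for s in sets))


def precision(cm: ConfusionMatrix) -> float:
    """Fraction of reads in the majority species of their cluster."""
    best = total = 0
    for row in cm.counts:
        best += max(row)
        total += sum(row)
    if total == 0:
        raise ValueError("confusion matrix counts no reads")
    return best / total


def sensitivity(cm: ConfusionMatrix) -> float:
    """Alias of :func:`precision`: with no unclassified reads they coincide."""
    return precision(cm)


def f_measure(cm: ConfusionMatrix) -> float:
    """Alias of :func:`precision`: with no unclassified reads they coincide."""
    return precision(cm)


def fp_rate(cm: ConfusionMatrix, calls: SpeciesCall, species: int) -> float:
    """False-positive rate of one species over the clusters called as it.

    Returns NaN when no cluster is called as the species: the rate is
    undefined there, not a vacuous zero.
    """
    n_species = len(cm.counts[0])
    if not (0 <= species < n_species):
        raise ValueError(f"species index {species} outside 0..{n_species - 1}")
    pooled = calls.index_sets[species]
    if not pooled:
        return math.nan
    total = sum(sum(cm.counts[i]) for i in pooled)
    if total == 0:  # only empty clusters called as s: rate undefined
        return math.nan
    foreign = sum(
        c for i in pooled for j, c in enumerate(cm.counts[i]) if j != species
    )
    return foreign / total
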