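"""Synthetic multi-species read sets with ground-truth labels.

Emulates the shape of a MetaSim-style benchmark: a handful of species with
fixed abundance weights, reads drawn uniformly from each genome with
normally distributed lengths and independent per-base substitution errors.
Genomes are either user-supplied sequences or synthesised from a seeded
order-m Markov chain, so different composition seeds give compositionally
distinct species — the property the binning signal rests on.

The default study design mirrors a three-species sample at abundance
1 : 3 : 9 with ~1000 bp reads, the configuration used throughout the test
suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .kmer_features import Read

__all__ = [
    "SpeciesModel",
    "SimulationConfig",
    "synthesize_genome",
    "make_default_species",
    "simulate_reads",
    "write_fasta",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SpeciesModel:
    """One species: a genome sequence and its relative abundance weight."""

    name: str
    genome: str
    abundance_weight: float

    def __post_init__(self) -> None:
        if self.abundance_weight <= 0:
            raise ValueError(f"abundance weight of {self.name!r} must be positive")
        if not self.genome:
            raise ValueError(f"genome of {self.name!r} is empty")


@dataclass(frozen=True)
class SimulationConfig:
    """Read-sampling parameters.

    Lengths are drawn from a normal distribution truncated below at
    ``min_read_length``; substitutions hit each base independently.
    """

    n_reads: int = 5000
    read_length_mean: float = 1000.0
    read_length_sd: float = 100.0
    substitution_rate: float = 0.01
    seed: int = 0
    min_read_length: int = 50

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.read_length_mean < self.min_read_length:
            raise ValueError("read_length_mean must be >= min_read_length")
        if self.read_length_sd < 0:
            raise ValueError("read_length_sd must be >= 0")


def synthesize_genome(
    length: int, markov_order: int = 2, composition_seed: int = 0
) -> str:
    """Generate a random genome with a seeded order-m Markov composition.

    The transition distribution out of each length-m context is drawn once
    from a flat Dirichlet, then the chain is run for ``length`` bases.
    Order 0 reduces to i.i.d. bases from a random distribution.  The same
    seed always yields the same genome; different seeds yield genomes with
    distinct k-mer spectra almost surely.
    """
    if length < 1:
        raise ValueError("genome length must be >= 1")
    if not (0 <= markov_order <= 3):
        raise ValueError("markov_order must be in 0..3")
    rng = np.random.default_rng(composition_seed)
    m = markov_order
    n_contexts = 4**m
    transition = rng.dirichlet(np.ones(4), size=n_contexts)  # (contexts, 4)
    cumulative = np.cumsum(transition, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    context = 0
    mask = n_contexts - 1
    for pos in range(length):
        row = cumulative[context]
        b = int(np.searchsorted(row, u[pos], side="right"))
        if b > 3:  # guard against cumulative rounding at 1.0
            b = 3
        out[pos] = b
        context = ((context << 2) | b) & mask
    return _BASES[out].tobytes().decode("ascii")


def make_default_species(
    n_species: int = 3,
    genome_length: int = 100_000,
    abundance_weights: Sequence[float] = (1.0, 3.0, 9.0),
    markov_order: int = 2,
    seed: int = 0,
) -> list[SpeciesModel]:
    """Build compositionally distinct synthetic species.

    Each species gets its own composition seed derived from ``seed``, so
    the set is reproducible and the genomes differ in k-mer spectrum.
    """
    if len(abundance_weights) != n_species:
        raise ValueError(
            f"got {len(abundance_weights)} abundance weights for {n_species} species"
        )
    rng = np.random.default_rng(seed)
    comp_seeds = rng.integers(0, 2**31 - 1, size=n_species)
    return [
        SpeciesModel(
            name=f"sp{i + 1}",
            genome=synthesize_genome(genome_length, markov_order, int(comp_seeds[i])),
            abundance_weight=float(abundance_weights[i]),
        )
        for i in range(n_species)
    ]


def simulate_reads(
    species: Sequence[SpeciesModel], config: SimulationConfig
) -> list[Read]:
    """Draw labelled reads from the species mixture.

    Per read: species from the normalised abundance weights, start position
    uniform over valid offsets, length from the truncated normal, then
    independent substitutions (to one of the three other bases) at the
    configured rate.  Fully determined by ``config.seed``.
    """
    if not species:
        raise ValueError("need at least one species")
    max_len = int(config.read_length_mean + 6 * config.read_length_sd) + 1
    for sp in species:
        if len(sp.genome) < max_len:
            raise ValueError(
                f"genome of {sp.name!r} ({len(sp.genome)} bp) is shorter than the "
                f"maximum read length {max_len} bp"
            )
    # separate streams: read layout (species, length, start) is invariant
    # to the error rate, so runs differing only in substitution_rate sample
    # the same fragments
    layout_ss, error_ss = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(layout_ss)
    rng_err = np.random.default_rng(error_ss)
    weights = np.array([sp.abundance_weight for sp in species], dtype=np.float64)
    weights /= weights.sum()
    genomes = [
        np.frombuffer(sp.genome.encode("ascii"), dtype=np.uint8) for sp in species
    ]
    base_index = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        base_index[ord(b)] = i

    species_draws = rng.choice(len(species), size=config.n_reads, p=weights)
    lengths = rng.normal(
        config.read_length_mean, config.read_length_sd, size=config.n_reads
    )
    lengths = np.clip(np.rint(lengths), config.min_read_length, max_len).astype(int)

    width = len(str(config.n_reads))
    reads: list[Read] = []
    for idx in range(config.n_reads):
        s = int(species_draws[idx])
        genome = genomes[s]
        length = int(lengths[idx])
        start = int(rng.integers(0, len(genome) - length + 1))
        fragment = genome[start : start + length].copy()
        if config.substitution_rate > 0:
            hits = np.nonzero(rng_err.random(length) < config.substitution_rate)[0]
            if hits.size:
                # replace with one of the three *other* bases
                cur = base_index[fragment[hits]]
                shift = rng_err.integers(1, 4, size=hits.size)
                fragment[hits] = _BASES[(cur + shift) % 4]
        reads.append(
            Read(
                id=f"read_{idx + 1:0{width}d}",
                sequence=fragment.tobytes().decode("ascii"),
                truth_label=species[s].name,
            )
        )
    return reads


def write_fasta(reads: Sequence[Read], path: str | Path) -> None:
    """Write reads as multi-FASTA, truth labels as ``species=`` header tokens."""
    with open(path, "w") as fh:
        for r in reads:
            desc = f" species={r.truth_label}" if r.truth_label is not None else ""
            fh.write(f">{r.id}{desc}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i : i + 80] + "\n")


def write_truth_tsv(reads: Sequence[Read], path: str | Path) -> None:
    """Write the read-id to species table (two tab-separated columns)."""
    with open(path, "w") as fh:
        for r in reads:
            if r.truth_label is None:
                raise ValueError(f"read {r.id!r} has no truth label")
            fh.write(f"{r.id}\t{r.truth_label}\n")
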