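"""Shared fixtures: tiny read sets and synthetic mixtures."""

from __future__ import annotations

import numpy as np
import pytest

from cabin.kmer_features import Read, pairwise_distance_provider
from cabin.read_simulator import (
    SimulationConfig,
    make_default_species,
    simulate_reads,
)


@pytest.fixture(scope="session")
def two_group_reads() -> list[Read]:
    """100 reads from two compositionally distinct synthetic species."""
    species = make_default_species(
        n_species=2,
        genome_length=20_000,
        abundance_weights=(1.0, 1.0),
        seed=11,
    )
    config = SimulationConfig(
        n_reads=100,
        read_length_mean=400.0,
        read_length_sd=20.0,
        substitution_rate=0.0,
        seed=12,
    )
    return simulate_reads(species, config)


@pytest.fixture(scope="session")
def three_species_reads() -> list[Read]:
    """300 reads, three species at 1:3:9, with substitution noise."""
    species = make_default_species(n_species=3, genome_length=50_000, seed=21)
    config = SimulationConfig(
        n_reads=300,
        read_length_mean=500.0,
        read_length_sd=50.0,
        substitution_rate=0.01,
        seed=22,
    )
    return simulate_reads(species, config)


@pytest.fixture(scope="session")
def two_group_provider(two_group_reads):
    return pairwise_distance_provider(two_group_reads, k=4)


@pytest.fixture(scope="session")
def separated_groups() -> list[Read]:
    """Two 50-read groups with disjoint k-mer support (A/C vs G/T genomes).

    The groups are separable by construction: their spectra share no
    k-mers, so between-group distances dwarf within-group ones.
    """
    rng = np.random.default_rng(2024)
    reads = []
    for name, alphabet in (("acrich", "AC"), ("gtrich", "GT")):
        genome = "".join(rng.choice(list(alphabet), size=20_000))
        for i in range(50):
            start = int(rng.integers(0, 20_000 - 300))
            reads.append(Read(f"{name}_{i}", genome[start : start + 300], name))
    return [reads[i] for i in rng.permutation(len(reads))]


def random_spectra_provider(n: int, seed: int, dim: int = 16):
    """Distance provider over random non-negative unit-sum vectors."""
    rng = np.random.default_rng(seed)
    spectra = rng.random((n, dim))
    spectra /= spectra.sum(axis=1, keepdims=True)
    from cabin.kmer_features import PairwiseDistanceProvider

    return PairwiseDistanceProvider(spectra)
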