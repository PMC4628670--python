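"""k-mer composition signatures of sequencing reads.

Each read is summarised by its k-mer spectrum: the vector of occurrence
frequencies of all 4**k length-k nucleotide words, indexed lexicographically
(AA..A first, TT..T last).  The distance between two reads is the Euclidean
norm of the difference of their spectra.  Windows containing ambiguous bases
(anything outside A/C/G/T, case-insensitive) are skipped; counts are
normalised by the number of valid windows so that reads of different length
are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Read",
    "extract_kmer_spectrum",
    "distance",
    "PairwiseDistanceProvider",
    "pairwise_distance_provider",
]

# A,C,G,T -> 0..3; everything else (N, IUPAC codes, gaps) -> -1 (invalid).
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class Read:
    """A single sequencing read.

    Parameters
    ----------
    id
        Non-empty identifier, unique within a dataset.
    sequence
        Nucleotide string over A/C/G/T plus ambiguity codes; case-insensitive.
    truth_label
        Optional ground-truth species identifier (simulation / evaluation only).
    """

    id: str
    sequence: str
    truth_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


def extract_kmer_spectrum(
    read: Read, k: int = 5, *, normalize: bool = True
) -> np.ndarray:
    """Compute the k-mer spectrum of a read.

    Every length-k window whose characters are all plain A/C/G/T is counted
    at its lexicographic index; windows containing ambiguous bases are
    skipped.  With ``normalize=True`` (default) counts are divided by the
    number of valid windows, so an unambiguous read yields a vector summing
    to 1.  A read with zero valid windows yields the all-zero vector.

    Returns a ``float64`` array of length ``4**k``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(read.sequence)
    if n < k:
        raise ValueError(
            f"read {read.id!r} has length {n} < k = {k}; too short to profile"
        )
    codes = _BASE_CODE[np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)]
    n_windows = n - k + 1
    # Horner encoding of each window; a single invalid base poisons the
    # window via the validity mask.
    idx = np.zeros(n_windows, dtype=np.int64)
    valid = np.ones(n_windows, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_windows]
        idx = idx * 4 + np.where(c >= 0, c, 0)
        valid &= c >= 0
    spectrum = np.bincount(idx[valid], minlength=4**k).astype(np.float64)
    if normalize:
        n_valid = int(valid.sum())
        if n_valid > 0:
            spectrum /= n_valid
    return spectrum


def distance(a: np.ndarray, b: np.ndarray, *, norm: str = "euclidean") -> float:
    """Distance ``||a - b||`` between two feature vectors.

    The default norm is Euclidean (L2); ``norm="manhattan"`` selects L1 as
    an experimental alternative.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if norm == "euclidean":
        return float(np.linalg.norm(a - b))
    if norm == "manhattan":
        return float(np.abs(a - b).sum())
    raise ValueError(f"unknown norm {norm!r}; expected 'euclidean' or 'manhattan'")


@dataclass
class PairwiseDistanceProvider:
    """Deterministic distance oracle over read indices.

    Precomputes all spectra once and the full pairwise Euclidean distance
    matrix, so the automaton core never recomputes a spectrum.  Callable as
    ``d(i, j)``; the dense ``matrix`` attribute is used by the fast lattice
    sweep.
    """

    spectra: np.ndarray  # (N, 4**k)
    norm: str = "euclidean"
    matrix: np.ndarray = field(init=False)  # (N, N) float64

    def __post_init__(self) -> None:
        metric = {"euclidean": "euclidean", "manhattan": "cityblock"}.get(self.norm)
        if metric is None:
            raise ValueError(f"unknown norm {self.norm!r}")
        self.matrix = cdist(self.spectra, self.spectra, metric=metric)
        # cdist guarantees symmetry only up to rounding; enforce it exactly
        # so the swap rule is orientation-independent.
        self.matrix = (self.matrix + self.matrix.T) / 2.0
        np.fill_diagonal(self.matrix, 0.0)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def mean_pairwise_distance(self) -> float:
        """Average distance over all unordered read pairs of the dataset."""
        n = self.n
        if n < 2:
            return 0.0
        iu = np.triu_indices(n, k=1)
        return float(self.matrix[iu].mean())

    def __call__(self, i: int, j: int) -> float:
        n = self.n
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"read index out of range: ({i}, {j}), N = {n}")
        return float(self.matrix[i, j])


def pairwise_distance_provider(
    reads: Sequence[Read],
    k: int = 5,
    *,
    normalize: bool = True,
    norm: str = "euclidean",
) -> PairwiseDistanceProvider:
    """Build the cached distance oracle for a dataset of reads."""
    if not reads:
        raise ValueError("cannot build a distance provider over zero reads")
    spectra = np.stack([extract_kmer_spectrum(r, k, normalize=normalize) for r in reads])
    return PairwiseDistanceProvider(spectra, norm=norm)


DistanceOracle = Callable[[int, int], float]
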