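# Methods

`cabin` bins metagenomic sequencing reads without references or training
data. This note records the model, the free choices made where the
procedure is genuinely underdetermined, and what the synthetic testbed
does and does not show.

## Composition signatures

Each read is represented by its k-mer spectrum: the 4^k-vector of
frequencies of all length-k words over {A, C, G, T}, indexed
lexicographically. k = 5 by default (1024 dimensions), following the
common finding that tetra-/pentanucleotide composition carries a
species-level signal in reads of a few hundred bases and up. Counts are
divided by the number of valid windows so reads of different lengths are
comparable; windows containing an ambiguous base are skipped; reverse
complements are *not* merged, keeping the full 4^k dimensionality.
Dissimilarity between reads is the Euclidean norm of the spectrum
difference (L1 available via `norm="manhattan"`). Raw counts
(`normalize=False`) are supported for experimentation; with them,
length variation between reads contaminates the distance, so the
normalized spectrum is the default.

## The lattice automaton

The N reads are placed, uniformly at random (seeded), on a circular
lattice of N cells (cell N+1 = cell 1). For each range r in {3, ..., R},
the transition rule at cell i compares d(x_i, x_{i+1}) with
d(x_i, x_{i+r-1}) and swaps the contents of cells i+1 and i+r-1 when the
first distance is strictly larger — i.e. when the read r-1 cells ahead is
compositionally closer to x_i than its immediate successor is. Equal
distances never swap, so an all-identical dataset is immediately stable.
Iteration stops when a full sweep performs zero swaps; the permutation of
reads is preserved exactly throughout.

Free choices, and what we chose:

* **Sweep order.** The update cannot be synchronous (two rules could
  claim the same cell), so some sequential order is needed. We visit
  cells in ascending order and apply all ranges r = 3..R at the current
  cell before moving on, with swaps taking effect immediately. On
  synthetic mixtures this converges in roughly 5–20 iterations and
  reaches equal or better label contiguity than sweeping ranges in the
  outer loop, which we measured to need hundreds of iterations and to
  stall short of a fixpoint on a substantial fraction of instances.
* **Rule range R.** R bounds how far a rule reaches, and with it the
  scale of cluster that can coalesce: two same-species runs separated by
  a foreign run longer than about R cells cannot merge. The default is
  R = max(3, min(N−1, floor(sqrt(N)))), which keeps one iteration at
  O(N·R) rule applications and converges reliably; larger R (up to
  ~N/10) improves contiguity on well-separated data at the cost of
  convergence robustness, and is available via `R_override`.
* **Safety cap.** `max_iterations` defaults to 1000. Hitting it is
  reported (`converged=False`, with a warning), not raised; unstructured
  data (e.g. i.i.d. random spectra) can cycle indefinitely, and the
  converged flag is the honest signal of whether the fixpoint property
  holds.

A converged lattice satisfies, for every cell i and range r,
d(x_i, x_{i+1}) <= d(x_i, x_{i+r-1}) — each read's successor is its
nearest neighbour among the next R−1 reads. `is_fixpoint` re-checks this
exhaustively and is used as the convergence oracle in the tests.

## Boundary detection

The chainmap is the sequence of distances between reads at consecutive
cells of the converged lattice; valleys mark clusters, spikes mark
boundaries. Because the lattice is circular but the scan is linear, the
lattice is first rotated so the globally largest consecutive distance —
the most plausible inter-cluster gap — becomes the seam between the last
and first cells (ties go to the smallest original index).

A single left-to-right scan then opens a new cluster at read x_i when
all of the following hold, where avg is the reference average distance,
and avg_k/sd_k are the running mean and population standard deviation of
the consecutive distances inside the current cluster (the gap that opened
the cluster excluded):

1. d(x_i, x_{i+1}) < avg
2. d(x_{i-1}, x_i) > max(avg, avg_k + sd_k)
3. d(x_{i-1}, x_i) > d(x_i, x_{i+1}) > d(x_{i+1}, x_{i+2})

plus the size rule: x_i must lie at least `min_cluster_size` (default 30)
cells past the current cluster's start, which suppresses the spurious
splits criterion 2 would otherwise allow while sd_k is still near zero.

**The reference average.** The pipeline compares gaps against the mean
distance over *all* read pairs of the dataset, not the chainmap mean: once
the lattice has converged, most consecutive pairs are within-cluster, so
the chainmap mean collapses onto the within-cluster noise level and
criterion 1 degenerates to a coin flip at true boundaries. The all-pairs
mean sits between the within- and between-cluster levels (measured
0.072 vs 0.044/0.10 on the default mixture) and keeps criteria 1–2
discriminative. `detect_boundaries` itself defaults to the chainmap mean;
the pipeline passes the all-pairs value (`avg_reference="dataset"`,
switchable to `"chain"`).

**Known limitation.** Criterion 3 demands a strictly descending distance
pattern across the boundary; its second inequality compares two i.i.d.
within-cluster distances and therefore fails at roughly half of all true
gaps regardless of how separated the species are. On well-ordered
lattices with few gaps this is the dominant error source: missing a
single decisive gap merges two species into one cluster. This is a
property of the printed criteria, not of their implementation; the
evaluation numbers below quantify it.

## Evaluation metrics

With K clusters and N_s species, R_ij counts reads of species j in
cluster i. Each cluster is called as its row-arg-max species (ties to the
lowest species index). Precision is (sum_i max_j R_ij) / (sum_ij R_ij).
The FP rate of species s pools the clusters called s and reports the
fraction of their reads belonging to other species; a species never
called has an undefined (NaN) rate rather than a vacuous zero. Every read
is always assigned, so sensitivity and F-measure coincide with precision
and are exposed only as aliases. All counting is exact integer
arithmetic.

## Synthetic data

The simulator emulates a MetaSim-style multi-species benchmark without
downloads. Genomes are generated by a seeded order-m Markov chain
(default m = 2) whose transition rows are drawn from a flat Dirichlet, so
different composition seeds give compositionally distinct "species";
reads take a species from the normalized abundance weights, a uniform
start, a truncated-normal length, and independent substitution errors.
Layout (species/length/start) and errors use separate seeded streams, so
changing the error rate alone re-reads the same fragments.

Default study design: 3 species, 100 kb genomes, abundance 1:3:9,
lengths ~N(1000, 100) bp, substitution rate 0.01, matching the
three-species benchmark the method is evaluated on. Tests use scaled-down
variants (genomes 20–50 kb, 100–600 reads, reads 300–500 bp) to stay
fast; the reproduction script uses the full 5000-read design.

What the generator does *not* model: indels or platform-specific error
profiles, paired ends, shared/homologous regions between species, GC
bias, chimeras. Real genomes also differ compositionally less than
independent Markov chains do, so passing results here demonstrate the
machinery under favourable separability, not field performance.

## Measured behaviour

At the full design (N = 5000, ten seeded runs) the pipeline converges in
about 17–26 iterations and delivers mean precision around 0.78, with the
most abundant species' FP rate around 0.22: many clusters per species
(K ≈ 11–24), mostly pure, with the misses concentrated where criterion 3
skips a gap. At N = 600 (the scaled test design) mean precision over ten
seeds is ≈ 0.77. `scripts/acceptance.py` recomputes these numbers from
scratch; nothing in this note is asserted beyond what it and the test
suite measure.

## Numerical details

* The pairwise distance matrix is computed once (SciPy `cdist`),
  symmetrised, and shared by the automaton, the chainmap, and the
  reference average; the sweep itself runs through a compiled kernel and
  an identical pure-Python path (tested for equality).
* Ties: equal distances never swap; arg-max ties in species calls go to
  the lowest index; seam ties to the smallest cell index.
* Degenerate inputs: reads shorter than k are dropped at load time with
  a warning (an all-short file is an error); a read whose every window
  contains an ambiguous base gets the zero spectrum; datasets need at
  least 4 reads to iterate and 2 cells to build a chainmap.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` derivation; identical seeds give
  byte-identical output files.
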