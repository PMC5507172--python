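# Methods

This note documents the models and procedures implemented in `magbin`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Coverage model and transform

Coverage is reads per base pair, `reads[c,s] / length[c]`, computed from a
counts table (contig × sample read counts plus lengths). The package does
not map reads; counts are an input, either produced upstream (any
featureCounts-style counter) or by the synthetic generator. An optional
SAM/BAM ingester counts primary alignments only (no MAPQ filter, no
duplicate marking), which makes the multi-mapping convention explicit:
each read counts once, at its primary location.

Before the initial clustering round, coverage is multiplied by a constant
scale factor, default 5. This transform matters only in the low-coverage
regime: affinity propagation's preference sets an absolute similarity cost
per cluster, so when typical coverage values are well below 1 reads/bp the
squared distances between genome profiles would be negligible against a
preference of −3 and everything would collapse into a few bins. Scaling by
5 moves between-genome distances onto the preference's scale. The transform
is a single exposed knob (`scale_factor`), applied exactly once
(re-transforming raises an error).

Two length cutoffs, both inclusive: contigs ≥ 7,500 bp are the binning
universe (`binned_min_length`); contigs ≥ 2,000 bp are the data-rich
read-recruitment universe used for relative abundance
(`data_rich_min_length`).

## Affinity propagation

The clustering core is an in-package implementation of affinity
propagation: similarity `s(i,k) = −‖x_i − x_k‖²` off the diagonal (the
standard choice; nothing else is implied by the protocol), preference on
the diagonal, and damped message passing

    r(i,k) ← s(i,k) − max_{k'≠k} [a(i,k') + s(i,k')]
    a(i,k) ← min(0, r(k,k) + Σ_{i'∉{i,k}} max(0, r(i',k)))   (i ≠ k)
    a(k,k) ← Σ_{i'≠k} max(0, r(i',k))

with every message updated as `new = d·old + (1−d)·computed`, `d = 0.9` by
default. Exemplars are points with `r(k,k) + a(k,k) > 0`; every other point
joins its most similar exemplar, with exact ties resolved to the lowest
input index. Convergence means the exemplar set is unchanged for
`conv_iter` consecutive iterations; hitting `max_iter` without convergence
returns the current exemplars with `converged=False` rather than failing
(rounds run on fixed budgets). If no exemplar has emerged at all, every
contig is returned unbinned.

Numerical choices:

- Exact similarity ties can make the messages oscillate, so the similarity
  matrix receives a seeded uniform jitter of magnitude ≤ 1e−12 (relative to
  the similarity scale), as reference implementations do. It is
  deterministic given the seed and can be disabled (`jitter=False`).
- The similarity matrix is dense, O(n²) memory. The intended desk-scale
  input is up to a few tens of thousands of contigs; the implementation
  preallocates its three n×n work arrays and runs comfortably at n ≈ 5,000
  (the benchmark community) on one CPU.
- On every shipped fixture with n ≤ 12 the exemplar set attains the
  brute-force maximum net similarity over all exemplar subsets; this is a
  test-suite invariant, not a general guarantee of the algorithm.

## Marker QC

CheckM-style lineage-specific marker machinery needs reference trees and
is out of scope; the QC here uses a single universal set of M single-copy
markers (default M = 104, the size of a typical universal bacterial set).
For a bin with per-marker copy counts `n_m`:

- completeness = 100 · |{m : n_m ≥ 1}| / M
- contamination = 100 · Σ_m max(0, n_m − 1) / M
- strain heterogeneity = 100 · (duplicate pairs with pairwise identity
  ≥ 0.9) / (all duplicate pairs), 0 when there are no duplicates
- cumulative redundancy = contamination − contamination · strain_het / 100

Copy identities are carried in the marker table rather than recomputed by
alignment: the stored value is the copy's identity to the marker's
canonical sequence, and a duplicate pair counts as near-identical when
`min(id_a, id_b) ≥ 0.9` — both copies at least that close to the canonical
sequence, hence close to each other. This is a deliberate simplification
(a 1-D stand-in for pairwise alignment identity); it keeps the QC fully
testable and is exact for the two cases that drive the triage logic:
same-strain duplicates written at identity ~1.0, and cross-genome
duplicates whose identities are drawn below the threshold.

Triage: **draft** requires completeness ≥ 50 and cumulative redundancy
≤ 10; **high-contamination** is ≥ 50 complete with redundancy > 10;
**low-completion** is < 50 complete. The two published category
definitions overlap at exactly 10% redundancy ("≤10%" vs "≥10%"); the
boundary resolves to draft because the draft category is defined first.
Both triage thresholds are configurable.

The genome-count estimate used to pick refinement preferences is
`1 + round(contamination/100)` (half-up, floored at 1): k merged complete
genomes score about (k−1)·100% contamination under the definition above,
so the estimate inverts it. The rounding convention at exact .5 is a
declared choice; nothing in the protocol pins it down.

## The refinement ladder

Phase A (transformed coverage): initial clustering at preference −3
(budget 4,000 / window 400, damping 0.9), triage, then per-bin local
re-clustering of high-contamination bins — each bin's own contigs only,
never the global matrix, which is what gives the large preference
magnitudes their meaning — with the preference schedule {2 genomes: −1000,
3: −500, ≥ 4: −100} and budget 2,000 / 200. A second refine pass uses a
fixed preference of −100 and, when `use_composition_in_refine` is set and
sequences are available, coverage concatenated with tetranucleotide
features. Drafts are frozen as soon as they are triaged and never
re-clustered or demoted.

Phase B (raw coverage): every contig not in a draft — including members of
phase-A low-completion and residual high-contamination bins, which are
dissolved back into the pool — is re-clustered on untransformed coverage
with the initial parameters, refined once with the schedule and once at a
fixed −10.

Finalization: the protocol's terminal categories are drafts and
low-completion bins only, so residual high-contamination bins are demoted
to low-completion with a `demoted` flag rather than dropped. Non-draft
bins keep their contigs only with ≥ 5 members (inclusive); smaller bins
dissolve into the unbinned set. Drafts are labeled `TMED1, TMED2, …` and
low-completion bins `TMEDlc1, …` in creation order (prefix configurable).
Contig conservation is asserted after every round and end-to-end; the
ladder is deterministic given config and seed, to the byte in all written
outputs.

Composition features: the 136 canonical tetranucleotides (each 4-mer
pooled with its reverse complement; windows containing N are skipped; a
sequence with fewer than four valid windows yields a zero vector and a
warning). When concatenated to coverage for the second refine pass, both
blocks are column z-scored within the bin being refined and each block is
divided by the square root of its width, so coverage and composition carry
equal weight regardless of dimensionality.

## The synthetic community generator

The generator emulates exactly the statistical structure the binning
exploits, with known truth:

- **Genomes**: G genomes with lengths uniform in a range (default 3.0–3.6
  Mbp, a typical bacterial genome), fragmented into contigs by repeated
  draws from a log-normal length law (default μ = 9.2, σ = 0.8 in log-bp
  ≈ 14 kb mean, floor 2 kb) until the genome is exhausted; a draw
  overshooting the remainder is clipped to it and a final remainder below
  the floor is discarded.
- **Abundance**: genome × sample mean coverage is log-normal across
  genomes, default median 0.5 reads/bp and σ_log = 1.0 — a deliberately
  low-coverage regime, which is the regime the ×5 transform exists for —
  with per-genome sample-to-sample correlation ρ = 0.3 (profiles are
  partially conserved across samples, as real abundances are).
- **Counts**: negative binomial with mean `coverage × length` and variance
  `mean · (1 + dispersion)` via the gamma–Poisson mixture; dispersion 0 is
  Poisson, the default dispersion is 0.5. Real recruitment counts are
  overdispersed; the protocol itself is silent on the noise model because
  it used real mappings. Read length is carried in the config for
  provenance but does not enter the count model (coverage is defined in
  reads, not bases).
- **Markers**: M distinct markers placed once per genome (900 bp each) on
  length-weighted random contigs, coordinates 0-based half-open within the
  contig; identities drawn Uniform(0.55, 0.85) per genome-and-marker so
  cross-genome duplicates read as divergent contaminants. A duplication
  knob places extra copies at a configurable identity (default 1.0) to
  build same-strain-heterogeneity and contamination fixtures. Placement
  that cannot fit (markers exceeding the genome, or no contig long enough)
  raises an error.
- **Noise**: an `unassigned_fraction` adds marker-free contigs whose
  coverage profiles are drawn independently per sample, so they belong to
  no recoverable genome.
- **Sequences**: i.i.d. uniform nucleotides by default (fast, tens of Mbp
  per second, and deliberately free of compositional signal). A
  `composition_alpha` knob switches a genome to an order-1 Markov chain
  with Dirichlet-drawn transition rows, giving genomes distinct tetramer
  profiles; it is generated per-base and intended for the small fixtures
  that exercise composition-assisted refinement.

Identical config and seed reproduce every output file byte-for-byte.

What the generator does **not** emulate: sequencing error and read-level
artifacts, assembly chimeras and fragmentation biases, strain mixtures
sharing most of their sequence, compositional autocorrelation along real
genomes, and sample-specific mapping biases. Passing the recovery
benchmark therefore shows that the ladder's logic is correct and that its
parameters behave as documented on data with the assumed covariance
structure — not that the pipeline will reach the same recovery on real
ocean metagenomes, where contiguity, strain structure and coverage evenness
are all worse.

## Benchmark problem sizes

The recovery benchmark community uses 20 genomes × 6 samples with the
defaults above (≈ 4,600 contigs, of which ≈ 3,000 are ≥ 7.5 kb and enter
binning), chosen as the smallest configuration that exercises every ladder
stage with ≥ 200 contigs per genome. The merged-bin fixture uses two
1.0–1.2 Mbp genomes with a 7.5 kb contig floor so that the whole community
is binnable. Exhaustive-search clustering checks run on fixtures of up to
12 points (4,095 exemplar subsets). The full test suite runs in about two
minutes on one CPU; the acceptance script in about one.

## Known limitations

- Dense O(n²) similarity limits inputs to desk scale; the published runs
  binned ~10⁵ contigs on a large-memory server, which this implementation
  does not target.
- The marker model is universal, not lineage-specific: completeness and
  contamination for taxa with reduced genomes will differ from CheckM's
  collocated-set estimates. Only the three percentages feed the triage, so
  the ladder logic is unaffected.
- Strain heterogeneity from stored canonical identities is a proxy; two
  copies both 60% identical to the canonical sequence but unrelated to
  each other would still be called one pair below threshold correctly, but
  two unrelated copies both at 0.95 would incorrectly read as same-strain.
- The per-genome reads/bp in the abundance equation is length-weighted
  (genome-total reads over genome-total length). The published equation
  does not say whether it weights by length or averages per-contig values;
  the unweighted variant is available as `per_contig_average=True`.
- `estimate_genome_count` saturates in usefulness above ~4 genomes, which
  is harmless because the preference schedule treats ≥ 4 uniformly.
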