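"""Synthetic multi-sample metagenome communities with known truth.

The generator emulates the statistical structure that coverage-profile
binning relies on: every contig of a genome shares that genome's per-sample
mean coverage (reads/bp), so contigs of one genome form a tight cluster in
coverage space, while genomes differ through independent log-normal abundance
draws.  Read counts are overdispersed (negative binomial); single-copy marker
genes are placed on the genomes' contigs with known coordinates, so the
marker-based QC stage can be scored against truth.

Defaults describe a low-coverage ocean-metagenome-like regime: per-genome
per-sample coverage is log-normal with median 0.5 reads/bp and sigma 1.0 in
log space, with modest sample-to-sample correlation per genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .coverage import ContigSet, write_counts_tsv
from .markers import MarkerTable, write_marker_tsv

__all__ = [
    "ContigLengthLaw",
    "AbundanceLaw",
    "CommunityConfig",
    "SyntheticTruth",
    "SyntheticCommunity",
    "fragment_genome",
    "sample_read_counts",
    "simulate_community",
    "write_community",
    "read_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ContigLengthLaw:
    """Log-normal contig-length law (parameters in log-bp), truncated below.

    ``sigma_log = 0`` degenerates to a constant length of exp(mu_log).
    """

    mu_log: float = 9.2
    sigma_log: float = 0.8
    min_length: int = 2000

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be nonnegative")

    def draw(self, rng: np.random.Generator) -> int:
        if self.sigma_log == 0:
            L = int(round(math.exp(self.mu_log)))
            if L < self.min_length:
                raise ValueError(
                    "constant contig-length law below min_length "
                    f"({L} < {self.min_length})"
                )
            return L
        for _ in range(10000):
            L = int(round(rng.lognormal(self.mu_log, self.sigma_log)))
            if L >= self.min_length:
                return L
        # the law essentially never clears the floor; fall back to the floor
        return self.min_length


@dataclass(frozen=True)
class AbundanceLaw:
    """Per-genome per-sample mean-coverage law.

    Coverage is log-normal across genomes (``exp(mu_log + sigma_log * z)``)
    with sample-to-sample correlation ``rho`` per genome: z for genome g in
    sample s is rho * z_g + sqrt(1 - rho^2) * eps_gs.
    """

    mu_log: float = math.log(0.5)
    sigma_log: float = 1.0
    rho: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be nonnegative")

    def draw(self, n_genomes: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        base = rng.standard_normal(n_genomes)[:, None]
        eps = rng.standard_normal((n_genomes, n_samples))
        z = self.rho * base + math.sqrt(1.0 - self.rho**2) * eps
        return np.exp(self.mu_log + self.sigma_log * z)


@dataclass(frozen=True)
class CommunityConfig:
    """Everything the generator needs; identical config + seed reproduces
    byte-identical outputs."""

    n_genomes: int = 10
    n_samples: int = 6
    genome_length_range: tuple[int, int] = (3_000_000, 3_600_000)
    marker_set_size: int = 104
    marker_length: int = 900
    contig_length_law: ContigLengthLaw = field(default_factory=ContigLengthLaw)
    abundance_law: AbundanceLaw = field(default_factory=AbundanceLaw)
    read_length: int = 100
    dispersion: float = 0.5
    unassigned_fraction: float = 0.0
    # genome index (0-based) -> (copies per marker, copy identity); used to
    # build same-strain-duplication / contamination fixtures
    marker_duplication: Mapping[int, tuple[int, float]] = field(default_factory=dict)
    # Dirichlet concentration for per-genome Markov transition rows; None
    # means i.i.d. uniform nucleotides (no compositional signal)
    composition_alpha: float | None = None
    with_sequences: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.genome_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid genome_length_range")
        if not (0.0 <= self.unassigned_fraction < 1.0):
            raise ValueError("unassigned_fraction must lie in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.marker_length <= 0 or self.marker_set_size < 0:
            raise ValueError("invalid marker configuration")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated community."""

    contig_to_genome: dict[str, str]
    genome_coverage: pd.DataFrame  # genomes x samples, true mean reads/bp
    marker_placements: pd.DataFrame  # genome_id, marker_id, contig_id, start, end, identity


class SyntheticCommunity(NamedTuple):
    contigs: ContigSet
    counts: pd.DataFrame
    truth: SyntheticTruth
    markers: MarkerTable


def fragment_genome(
    genome_length: int,
    law: ContigLengthLaw,
    seed: int | np.random.Generator = 0,
    genome_id: str = "genome",
) -> np.ndarray:
    """Fragment a genome into contig lengths under *law*.

    Lengths are drawn from the truncated law until the remaining genome is
    shorter than ``law.min_length``; a draw overshooting the remainder is
    clipped to it (the remainder is then >= min_length by construction), and
    any final remainder below the floor is discarded, so the lengths sum to
    at most ``genome_length`` and each is >= ``law.min_length``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if genome_length < law.min_length:
        raise ValueError(
            f"genome {genome_id!r} shorter than min contig length "
            f"({genome_length} < {law.min_length})"
        )
    lengths: list[int] = []
    remaining = int(genome_length)
    while remaining >= law.min_length:
        L = law.draw(rng)
        if L > remaining:
            L = remaining
        lengths.append(L)
        remaining -= L
    return np.asarray(lengths, dtype=np.int64)


def _nb_counts(means: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized negative-binomial draws with mean mu, variance mu*(1+d).

    Uses the gamma-Poisson mixture: lambda ~ Gamma(shape=mu/d, scale=d),
    count ~ Poisson(lambda).  d = 0 degenerates to Poisson(mu).
    """
    means = np.asarray(means, dtype=float)
    out = np.zeros(means.shape, dtype=np.int64)
    pos = means > 0
    if dispersion == 0:
        out[pos] = rng.poisson(means[pos])
    else:
        lam = rng.gamma(shape=means[pos] / dispersion, scale=dispersion)
        out[pos] = rng.poisson(lam)
    return out


def sample_read_counts(
    true_coverage: float,
    contig_length: int,
    read_length: int = 100,
    dispersion: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> int:
    """Draw one read count for a contig.

    The count is negative binomial with mean ``true_coverage * contig_length``
    and variance ``mean * (1 + dispersion)``; dispersion 0 is Poisson.
    Coverage is reads per bp, so the read length does not enter the mean; the
    parameter is accepted for provenance symmetry with the config.
    """
    if true_coverage < 0 or contig_length < 0 or dispersion < 0:
        raise ValueError("inputs must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = float(true_coverage) * float(contig_length)
    return int(_nb_counts(np.array([mean]), dispersion, rng)[0])


def _random_sequences(
    lengths: Sequence[int],
    rng: np.random.Generator,
    transition: np.ndarray | None,
) -> list[str]:
    """Random nucleotide sequences; i.i.d. uniform, or an order-1 Markov
    chain when a 4x4 transition matrix is given (small fixtures only)."""
    if transition is None:
        total = int(np.sum(lengths))
        codes = rng.integers(0, 4, size=total)
        flat = _BASES[codes].tobytes().decode("ascii")
        seqs = []
        pos = 0
        for L in lengths:
            seqs.append(flat[pos:pos + int(L)])
            pos += int(L)
        return seqs
    cum = np.cumsum(transition, axis=1)
    seqs = []
    for L in lengths:
        u = rng.random(int(L))
        codes = np.empty(int(L), dtype=np.int64)
        state = int(rng.integers(0, 4))
        codes[0] = state
        for i in range(1, int(L)):
            state = int(np.searchsorted(cum[state], u[i]))
            codes[i] = state
        seqs.append(_BASES[codes].tobytes().decode("ascii"))
    return seqs


def simulate_community(config: CommunityConfig) -> SyntheticCommunity:
    """Generate a community: contigs, counts table, truth, marker table.

    Deterministic: identical config and seed give identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    law = config.contig_length_law

    # --- genomes and fragmentation -------------------------------------
    lo, hi = config.genome_length_range
    genome_ids = [f"g{i + 1:03d}" for i in range(config.n_genomes)]
    genome_lengths = rng.integers(lo, hi + 1, size=config.n_genomes)

    contig_ids: list[str] = []
    contig_lengths: list[int] = []
    contig_genome_idx: list[int] = []
    per_genome_contigs: list[list[int]] = []  # indices into contig arrays
    for gi, (gid, glen) in enumerate(zip(genome_ids, genome_lengths)):
        if config.marker_set_size * config.marker_length > glen:
            raise ValueError(
                f"marker placement infeasible: {config.marker_set_size} markers of "
                f"{config.marker_length} bp exceed genome {gid!r} ({glen} bp)"
            )
        lens = fragment_genome(int(glen), law, rng, genome_id=gid)
        idxs = []
        for k, L in enumerate(lens):
            idxs.append(len(contig_ids))
            contig_ids.append(f"{gid}_c{k + 1:04d}")
            contig_lengths.append(int(L))
            contig_genome_idx.append(gi)
        per_genome_contigs.append(idxs)

    # --- abundance profiles --------------------------------------------
    sample_ids = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    genome_cov = config.abundance_law.draw(config.n_genomes, config.n_samples, rng)
    cov_rows = [genome_cov[gi] for gi in contig_genome_idx]

    # --- noise contigs (not recoverable as genomes) ---------------------
    n_real = len(contig_ids)
    n_noise = int(round(
        config.unassigned_fraction / (1.0 - config.unassigned_fraction) * n_real
    ))
    noise_genome_ids: list[str] = []
    for j in range(n_noise):
        gid = f"noise{j + 1:04d}"
        noise_genome_ids.append(gid)
        contig_ids.append(f"{gid}_c0001")
        contig_lengths.append(law.draw(rng))
        contig_genome_idx.append(config.n_genomes + j)
        # erratic per-contig profile: independent draw per sample
        cov_rows.append(np.exp(
            config.abundance_law.mu_log
            + config.abundance_law.sigma_log * rng.standard_normal(config.n_samples)
        ))

    contig_lengths_arr = np.asarray(contig_lengths, dtype=np.int64)
    cov_per_contig = np.vstack(cov_rows)

    # --- read counts -----------------------------------------------------
    means = cov_per_contig * contig_lengths_arr[:, None]
    counts_mat = np.column_stack([
        _nb_counts(means[:, s], config.dispersion, rng)
        for s in range(config.n_samples)
    ])
    counts = pd.DataFrame(
        counts_mat, index=pd.Index(contig_ids, name="contig_id"), columns=sample_ids
    )
    counts.insert(0, "length", contig_lengths_arr)

    # --- marker placement ------------------------------------------------
    marker_ids = [f"M{m + 1:03d}" for m in range(config.marker_set_size)]
    placements: list[tuple[str, str, str, int, int, float]] = []
    for gi, gid in enumerate(genome_ids):
        copies, dup_identity = config.marker_duplication.get(gi, (1, 1.0))
        idxs = per_genome_contigs[gi]
        lens = contig_lengths_arr[idxs]
        eligible = [
            (contig_ids[i], int(L)) for i, L in zip(idxs, lens)
            if L >= config.marker_length
        ]
        if not eligible and config.marker_set_size > 0:
            raise ValueError(
                f"marker placement infeasible: no contig of genome {gid!r} can "
                f"host a {config.marker_length} bp marker"
            )
        weights = np.array([L for _, L in eligible], dtype=float)
        weights /= weights.sum()
        for mid in marker_ids:
            base_identity = float(rng.uniform(0.55, 0.85))
            for copy in range(copies):
                ci = int(rng.choice(len(eligible), p=weights))
                cid, clen = eligible[ci]
                start = int(rng.integers(0, clen - config.marker_length + 1))
                identity = base_identity if copies == 1 else float(dup_identity)
                placements.append(
                    (gid, mid, cid, start, start + config.marker_length, identity)
                )

    marker_frame = pd.DataFrame(
        placements,
        columns=["genome_id", "marker_id", "contig_id", "start", "end", "identity"],
    )
    markers = MarkerTable(frame=marker_frame, universe=marker_ids)

    # --- sequences --------------------------------------------------------
    sequences: dict[str, str] | None = None
    if config.with_sequences:
        sequences = {}
        if config.composition_alpha is None:
            seqs = _random_sequences(contig_lengths_arr.tolist(), rng, None)
            sequences = dict(zip(contig_ids, seqs))
        else:
            all_genomes = config.n_genomes + n_noise
            for gi in range(all_genomes):
                trans = rng.dirichlet(
                    np.full(4, config.composition_alpha), size=4
                )
                idxs = [i for i, g in enumerate(contig_genome_idx) if g == gi]
                seqs = _random_sequences(
                    contig_lengths_arr[idxs].tolist(), rng, trans
                )
                for i, s in zip(idxs, seqs):
                    sequences[contig_ids[i]] = s

    contigs = ContigSet(ids=contig_ids, lengths=contig_lengths_arr, sequences=sequences)

    all_genome_ids = genome_ids + noise_genome_ids
    # noise "genomes" are single contigs; their truth coverage row is the
    # contig's own erratic profile
    cov_table = np.vstack([genome_cov, cov_per_contig[n_real:]]) if n_noise else genome_cov
    truth = SyntheticTruth(
        contig_to_genome={
            cid: all_genome_ids[gi] for cid, gi in zip(contig_ids, contig_genome_idx)
        },
        genome_coverage=pd.DataFrame(
            cov_table,
            index=pd.Index(all_genome_ids, name="genome_id"),
            columns=sample_ids,
        ),
        marker_placements=marker_frame.copy(),
    )
    return SyntheticCommunity(contigs=contigs, counts=counts, truth=truth, markers=markers)


def write_community(
    community: SyntheticCommunity,
    outdir: str | Path,
    config: CommunityConfig,
) -> dict[str, Path]:
    """Write contigs.fasta, counts.tsv, truth.tsv, genome_coverage.tsv and
    markers.tsv to *outdir*, each with a '# seed=...' provenance line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = [f"seed={config.seed}", "generator=magbin.synthetic"]
    paths: dict[str, Path] = {}

    if community.contigs.sequences is not None:
        fasta = outdir / "contigs.fasta"
        with open(fasta, "w") as fh:
            for cid in community.contigs.ids:
                fh.write(f">{cid}\n{community.contigs.sequences[cid]}\n")
        paths["contigs"] = fasta

    counts_path = outdir / "counts.tsv"
    write_counts_tsv(community.counts, counts_path, provenance=prov)
    paths["counts"] = counts_path

    truth_path = outdir / "truth.tsv"
    lines = [f"# {p}\n" for p in prov]
    lines.append("contig_id\tgenome_id\n")
    for cid in community.contigs.ids:
        lines.append(f"{cid}\t{community.truth.contig_to_genome[cid]}\n")
    truth_path.write_text("".join(lines))
    paths["truth"] = truth_path

    cov_path = outdir / "genome_coverage.tsv"
    buf = [f"# {p}\n" for p in prov]
    buf.append(community.truth.genome_coverage.to_csv(
        sep="\t", index_label="genome_id", float_format="%.10g"
    ))
    cov_path.write_text("".join(buf))
    paths["genome_coverage"] = cov_path

    marker_path = outdir / "markers.tsv"
    write_marker_tsv(community.markers, marker_path, provenance=prov)
    paths["markers"] = marker_path
    return paths


def read_truth_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["contig_id"], df["genome_id"]))
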