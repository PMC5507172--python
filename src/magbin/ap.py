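"""Affinity-propagation binning of contigs on coverage (or coverage plus
composition) feature vectors.

Affinity propagation (Frey & Dueck's exemplar-based message passing) selects
a set of exemplar points and assigns every other point to its most similar
exemplar.  Similarity between distinct points is the negative squared
Euclidean distance between their feature vectors; the self-similarity
("preference", the diagonal of the similarity matrix) controls how many
exemplars emerge — more negative preferences yield fewer, larger bins.

The update rules implemented here are the standard damped responsibility /
availability recursions:

    r(i,k) <- s(i,k) - max_{k' != k} [ a(i,k') + s(i,k') ]
    a(i,k) <- min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))   (i != k)
    a(k,k) <- sum_{i' != k} max(0, r(i',k))

with every message damped as new = d*old + (1-d)*computed.  Exemplars are the
points with r(k,k) + a(k,k) > 0; convergence is declared when the exemplar
set is unchanged for ``conv_iter`` consecutive iterations.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

__all__ = [
    "APParams",
    "BinSet",
    "build_similarity",
    "affinity_propagation",
    "bin_contigs",
    "tetranucleotide_profile",
    "composition_matrix",
    "canonical_tetramers",
    "write_bins_tsv",
    "read_bins_tsv",
    "write_bin_fastas",
]


@dataclass(frozen=True)
class APParams:
    """Affinity-propagation parameters.

    Defaults mirror the initial binning round of the coverage ladder:
    preference -3, at most 4,000 iterations, convergence after 400 stable
    iterations, damping 0.9.  ``seed`` only drives the tiny (<=1e-12)
    symmetric jitter used to break exact similarity ties reproducibly;
    set ``jitter=False`` to disable it.
    """

    preference: float = -3.0
    damping: float = 0.9
    max_iter: int = 4000
    conv_iter: int = 400
    seed: int = 0
    jitter: bool = True

    def __post_init__(self) -> None:
        if not (0.5 <= self.damping < 1.0):
            raise ValueError(f"damping must be in [0.5, 1), got {self.damping}")
        if self.conv_iter > self.max_iter:
            raise ValueError("conv_iter must not exceed max_iter")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass
class BinSet:
    """A disjoint assignment of contigs to bins.

    ``assignments`` maps contig id -> bin id; ``exemplars`` maps bin id ->
    its exemplar contig (which is always assigned to its own bin).  Contigs
    left out of every bin (only possible when message passing terminates
    without any exemplar) are listed in ``unbinned``.
    """

    assignments: dict[str, str]
    exemplars: dict[str, str]
    unbinned: list[str] = field(default_factory=list)
    round_label: str = ""
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        for bin_id, ex in self.exemplars.items():
            if self.assignments.get(ex) != bin_id:
                raise ValueError(f"exemplar {ex!r} not assigned to its bin {bin_id!r}")
        overlap = set(self.assignments) & set(self.unbinned)
        if overlap:
            raise ValueError(f"contig {sorted(overlap)[0]!r} both binned and unbinned")

    def bins(self) -> dict[str, list[str]]:
        """bin id -> member contig ids, in input order."""
        out: dict[str, list[str]] = {b: [] for b in self.exemplars}
        for contig, bin_id in self.assignments.items():
            out[bin_id].append(contig)
        return out

    @property
    def n_bins(self) -> int:
        return len(self.exemplars)

    def all_contigs(self) -> list[str]:
        return list(self.assignments) + list(self.unbinned)


def build_similarity(features: np.ndarray, preference: float) -> np.ndarray:
    """Similarity matrix: s(i,k) = -||x_i - x_k||^2, diagonal = preference."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 1:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    n = X.shape[0]
    if n == 1:
        return np.array([[preference]], dtype=float)
    S = -squareform(pdist(X, metric="sqeuclidean"))
    np.fill_diagonal(S, preference)
    return S


def affinity_propagation(
    S: np.ndarray,
    params: APParams,
    contig_ids: Sequence[str] | None = None,
    round_label: str = "",
) -> BinSet:
    """Run damped affinity-propagation message passing on similarity *S*.

    Exact ties in *S* are perturbed by a seeded jitter of magnitude <=1e-12
    (relative to the similarity scale) to prevent message oscillation, as in
    reference implementations; disable with ``params.jitter=False``.

    Returns a :class:`BinSet`.  If no exemplar has emerged at termination,
    every contig is returned unbinned and ``converged`` is False.
    """
    S = np.array(S, dtype=float, copy=True)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    n = S.shape[0]
    if n == 0:
        raise ValueError("empty similarity matrix")
    ids = list(contig_ids) if contig_ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("contig_ids length does not match similarity matrix")

    if n == 1:
        return BinSet(
            assignments={ids[0]: _bin_label(0)},
            exemplars={_bin_label(0): ids[0]},
            round_label=round_label,
            converged=True,
            n_iter=0,
        )

    if params.jitter:
        rng = np.random.default_rng(params.seed)
        scale = max(1.0, float(np.abs(S).max()))
        S += rng.random((n, n)) * 1e-12 * scale

    d = params.damping
    A = np.zeros((n, n))
    R = np.zeros((n, n))
    tmp = np.empty((n, n))
    idx = np.arange(n)

    exemplar_flags = np.zeros(n, dtype=bool)
    stable = 0
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        # responsibilities
        np.add(A, S, out=tmp)              # tmp = a + s
        first = tmp.argmax(axis=1)
        first_val = tmp[idx, first]
        tmp[idx, first] = -np.inf
        second_val = tmp.max(axis=1)
        np.subtract(S, first_val[:, None], out=tmp)   # tmp = s - best
        tmp[idx, first] = S[idx, first] - second_val
        R *= d
        R += (1 - d) * tmp
        # availabilities
        np.maximum(R, 0, out=tmp)
        tmp[idx, idx] = R[idx, idx]
        colsum = tmp.sum(axis=0)
        diag_new = colsum - R[idx, idx]     # a(k,k) before damping
        np.subtract(colsum[None, :], tmp, out=tmp)
        np.minimum(tmp, 0, out=tmp)
        tmp[idx, idx] = diag_new
        A *= d
        A += (1 - d) * tmp

        flags = (A[idx, idx] + R[idx, idx]) > 0
        if np.array_equal(flags, exemplar_flags):
            stable += 1
            if stable >= params.conv_iter and flags.any():
                converged = True
                break
        else:
            stable = 0
            exemplar_flags = flags

    exemplars_idx = np.flatnonzero(exemplar_flags)
    if exemplars_idx.size == 0:
        logger.warning("affinity propagation terminated with no exemplars (n=%d)", n)
        return BinSet(
            assignments={},
            exemplars={},
            unbinned=ids,
            round_label=round_label,
            converged=False,
            n_iter=it,
        )

    # assignment: each point to the exemplar with highest similarity;
    # exemplars to themselves; argmax keeps the lowest index on exact ties.
    labels = exemplars_idx[np.argmax(S[:, exemplars_idx], axis=1)]
    labels[exemplars_idx] = exemplars_idx

    bin_ids = {int(e): _bin_label(j) for j, e in enumerate(exemplars_idx)}
    assignments = {ids[i]: bin_ids[int(labels[i])] for i in range(n)}
    exemplars = {bin_ids[int(e)]: ids[int(e)] for e in exemplars_idx}
    logger.info(
        "AP %s: n=%d bins=%d iter=%d converged=%s",
        round_label or "-", n, len(exemplars), it, converged,
    )
    return BinSet(
        assignments=assignments,
        exemplars=exemplars,
        round_label=round_label,
        converged=converged,
        n_iter=it,
    )


def _bin_label(j: int) -> str:
    return f"bin_{j + 1:04d}"


def bin_contigs(
    features: np.ndarray,
    params: APParams,
    contig_ids: Sequence[str] | None = None,
    round_label: str = "",
) -> BinSet:
    """Cluster contigs: build the similarity matrix and run message passing."""
    S = build_similarity(features, params.preference)
    return affinity_propagation(S, params, contig_ids=contig_ids, round_label=round_label)


# ---------------------------------------------------------------------------
# Tetranucleotide composition

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _revcomp(kmer: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(kmer))


def canonical_tetramers() -> list[str]:
    """The 136 canonical 4-mers (each 4-mer pooled with its reverse
    complement; 16 palindromes + 120 pooled pairs)."""
    seen: dict[str, None] = {}
    bases = "ACGT"
    for a in bases:
        for b in bases:
            for c in bases:
                for e in bases:
                    k = a + b + c + e
                    canon = min(k, _revcomp(k))
                    seen.setdefault(canon, None)
    return sorted(seen)


_CANONICAL = canonical_tetramers()
_CANON_INDEX = {k: i for i, k in enumerate(_CANONICAL)}
# code (base-4 integer of the 4-mer) -> canonical slot, precomputed once
_CODE_TO_SLOT = np.empty(256, dtype=np.int64)
for _k in ("".join(p) for p in itertools.product("ACGT", repeat=4)):
    _code = sum(_BASE_CODE[b] * 4 ** (3 - i) for i, b in enumerate(_k))
    _CODE_TO_SLOT[_code] = _CANON_INDEX[min(_k, _revcomp(_k))]


def tetranucleotide_profile(sequence: str) -> np.ndarray:
    """Frequencies of the 136 canonical 4-mers in *sequence*.

    Windows containing characters outside ACGT (e.g. N) are skipped.  Each
    4-mer count is pooled with its reverse complement and the vector is
    normalized to sum to 1.  A sequence with fewer than 4 valid windows is
    degenerate: a zero vector is returned with a warning.
    """
    seq = sequence.upper()
    buf = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(buf.shape, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        codes[buf == ord(base)] = code
    n = codes.size
    if n >= 4:
        w = (
            codes[:-3] * 64
            + codes[1:-2] * 16
            + codes[2:-1] * 4
            + codes[3:]
        )
        valid = (
            (codes[:-3] >= 0)
            & (codes[1:-2] >= 0)
            & (codes[2:-1] >= 0)
            & (codes[3:] >= 0)
        )
        w = w[valid]
    else:
        w = np.empty(0, dtype=np.int64)
    vec = np.zeros(len(_CANONICAL), dtype=float)
    if w.size < 4:
        warnings.warn(
            f"sequence has {w.size} valid 4-mer windows (<4); returning zero profile",
            stacklevel=2,
        )
        return vec
    np.add.at(vec, _CODE_TO_SLOT[w], 1.0)
    vec /= vec.sum()
    return vec


def composition_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Stack tetranucleotide profiles for a list of sequences (n x 136)."""
    return np.vstack([tetranucleotide_profile(s) for s in sequences])


# ---------------------------------------------------------------------------
# IO


def write_bins_tsv(binset: BinSet, path: str | Path,
                   provenance: Sequence[str] = ()) -> None:
    lines = [f"# {p}\n" for p in provenance]
    lines.append("contig_id\tbin_id\texemplar_flag\tround_label\n")
    exemplar_of = {v: k for k, v in binset.exemplars.items()}
    for contig, bin_id in binset.assignments.items():
        flag = int(exemplar_of.get(contig) == bin_id)
        lines.append(f"{contig}\t{bin_id}\t{flag}\t{binset.round_label}\n")
    for contig in binset.unbinned:
        lines.append(f"{contig}\tunbinned\t0\t{binset.round_label}\n")
    Path(path).write_text("".join(lines))


def read_bins_tsv(path: str | Path) -> BinSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df["exemplar_flag"] = df["exemplar_flag"].astype(int)
    binned = df[df["bin_id"] != "unbinned"]
    assignments = dict(zip(binned["contig_id"], binned["bin_id"]))
    exemplars = {
        row.bin_id: row.contig_id
        for row in binned.itertuples()
        if row.exemplar_flag == 1
    }
    unbinned = list(df.loc[df["bin_id"] == "unbinned", "contig_id"])
    label = str(df["round_label"].iloc[0]) if len(df) else ""
    return BinSet(assignments=assignments, exemplars=exemplars,
                  unbinned=unbinned, round_label=label)


def write_bin_fastas(binset: BinSet, sequences: Mapping[str, str],
                     outdir: str | Path) -> list[Path]:
    """Write one FASTA per bin (requires contig sequences)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for bin_id, members in sorted(binset.bins().items()):
        p = outdir / f"{bin_id}.fasta"
        with open(p, "w") as fh:
            for contig in members:
                fh.write(f">{contig}\n{sequences[contig]}\n")
        paths.append(p)
    return paths
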