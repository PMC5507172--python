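"""Per-contig, per-sample coverage profiles.

Coverage is defined as reads recruited to a contig divided by contig length
(reads/bp).  Profiles across samples are the clustering signal for binning;
in the low-coverage regime they are additionally scaled by a constant factor
(default 5) before clustering so that differences between profiles dominate
the clustering preference.

The canonical on-disk interchange format is a counts TSV with columns
``contig_id``, ``length``, then one integer column per sample.  Lines
beginning ``#`` are provenance comments.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContigSet",
    "CoverageMatrix",
    "compute_coverage",
    "transform_coverage",
    "filter_contigs",
    "recruitment_fraction",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_coverage_tsv",
    "write_coverage_tsv",
    "read_fasta",
    "counts_from_alignments",
]


@dataclass
class ContigSet:
    """An ordered set of contigs: ids, lengths (bp), optional sequences."""

    ids: list[str]
    lengths: np.ndarray
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if len(self.ids) != len(self.lengths):
            raise ValueError("ids and lengths differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate contig ids")
        if np.any(self.lengths <= 0):
            bad = self.ids[int(np.argmax(self.lengths <= 0))]
            raise ValueError(f"non-positive length for contig {bad!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.length_by_id

    @property
    def length_by_id(self) -> dict[str, int]:
        cached = getattr(self, "_length_by_id", None)
        if cached is None or len(cached) != len(self.ids):
            cached = dict(zip(self.ids, (int(x) for x in self.lengths)))
            object.__setattr__(self, "_length_by_id", cached)
        return cached

    def subset(self, ids: Iterable[str]) -> "ContigSet":
        """Return the contigs named in *ids*, preserving this set's order."""
        wanted = set(ids)
        keep = [i for i, c in enumerate(self.ids) if c in wanted]
        seqs = None
        if self.sequences is not None:
            seqs = {self.ids[i]: self.sequences[self.ids[i]] for i in keep}
        return ContigSet(
            ids=[self.ids[i] for i in keep],
            lengths=self.lengths[keep],
            sequences=seqs,
        )


@dataclass
class CoverageMatrix:
    """Contigs x samples matrix of reads/bp values.

    ``transformed`` records whether values have been scaled by
    ``scale_factor`` (the low-coverage delineation transform).
    """

    frame: pd.DataFrame  # index: contig ids, columns: sample ids, float
    transformed: bool = False
    scale_factor: float = 5.0

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("coverage values must be finite")
        if np.any(vals < 0):
            raise ValueError("coverage values must be nonnegative")

    @property
    def contig_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def subset(self, contig_ids: Sequence[str]) -> "CoverageMatrix":
        return CoverageMatrix(
            frame=self.frame.loc[list(contig_ids)],
            transformed=self.transformed,
            scale_factor=self.scale_factor,
        )


def _split_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Split a counts table into its length column and sample columns."""
    if "length" not in counts.columns:
        raise ValueError("counts table lacks a 'length' column")
    lengths = counts["length"]
    samples = counts.drop(columns=["length"])
    return lengths, samples


def compute_coverage(
    counts: pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series | None = None,
) -> CoverageMatrix:
    """Raw coverage: reads recruited to a contig divided by its length.

    Parameters
    ----------
    counts
        Table indexed by contig id with a ``length`` column (unless *lengths*
        is given separately) and one integer read-count column per sample.
    lengths
        Optional contig lengths; overrides / replaces the table's own
        ``length`` column.
    """
    if lengths is None:
        length_series, reads = _split_counts(counts)
    else:
        length_series = pd.Series(lengths, dtype=float)
        reads = counts.drop(columns=["length"], errors="ignore")
        missing = reads.index.difference(length_series.index)
        if len(missing):
            raise ValueError(f"missing length for contig {missing[0]!r}")
        length_series = length_series.reindex(reads.index)

    length_arr = length_series.to_numpy(dtype=float)
    if np.any(~np.isfinite(length_arr)) or np.any(length_arr <= 0):
        bad = reads.index[int(np.argmax(~(length_arr > 0)))]
        raise ValueError(f"non-positive or missing length for contig {bad!r}")
    read_arr = reads.to_numpy(dtype=float)
    if np.any(read_arr < 0):
        i, _ = np.unravel_index(int(np.argmin(read_arr)), read_arr.shape)
        raise ValueError(f"negative read count for contig {reads.index[i]!r}")

    cov = read_arr / length_arr[:, None]
    frame = pd.DataFrame(cov, index=reads.index.copy(), columns=reads.columns.copy())
    return CoverageMatrix(frame=frame, transformed=False)


def transform_coverage(m: CoverageMatrix, factor: float = 5.0) -> CoverageMatrix:
    """Scale raw coverage by *factor* (default 5) for cluster delineation."""
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    if m.transformed:
        raise ValueError("coverage matrix is already transformed")
    return CoverageMatrix(frame=m.frame * factor, transformed=True, scale_factor=factor)


def filter_contigs(contigs: ContigSet, min_length: int) -> ContigSet:
    """Contigs with length >= min_length, order preserved (inclusive bound)."""
    keep = contigs.lengths >= int(min_length)
    ids = [c for c, k in zip(contigs.ids, keep) if k]
    seqs = None
    if contigs.sequences is not None:
        seqs = {c: contigs.sequences[c] for c in ids}
    return ContigSet(ids=ids, lengths=contigs.lengths[keep], sequences=seqs)


def recruitment_fraction(
    counts: pd.DataFrame,
    subset: ContigSet | Sequence[str],
    total_reads_per_sample: Mapping[str, float] | pd.Series | None = None,
) -> pd.Series:
    """Percent of each sample's reads recruited to *subset* contigs.

    When *total_reads_per_sample* is omitted, the per-sample totals over the
    whole counts table are used.  A sample with zero total reads yields NaN
    (undefined), never 0.
    """
    _, reads = _split_counts(counts) if "length" in counts.columns else (None, counts)
    ids = subset.ids if isinstance(subset, ContigSet) else list(subset)
    missing = set(ids) - set(reads.index)
    if missing:
        raise ValueError(f"subset contig {sorted(missing)[0]!r} absent from counts")
    sub = reads.loc[ids].sum(axis=0).astype(float)
    if total_reads_per_sample is None:
        total = reads.sum(axis=0).astype(float)
    else:
        total = pd.Series(total_reads_per_sample, dtype=float).reindex(reads.columns)
    if np.any(total.to_numpy() + 1e-9 < sub.to_numpy()):
        raise ValueError("total reads per sample smaller than reads on subset")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 100.0 * sub / total
    return frac.where(total > 0, other=np.nan)


# ---------------------------------------------------------------------------
# IO


def _write_tsv(frame: pd.DataFrame, path: str | Path, provenance: Sequence[str],
               index_label: str, float_format: str | None = None) -> None:
    buf = _io.StringIO()
    for line in provenance:
        buf.write(f"# {line}\n")
    frame.to_csv(buf, sep="\t", index_label=index_label, float_format=float_format)
    Path(path).write_text(buf.getvalue())


def write_counts_tsv(counts: pd.DataFrame, path: str | Path,
                     provenance: Sequence[str] = ()) -> None:
    _write_tsv(counts, path, provenance, index_label="contig_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="contig_id")
    if "length" not in df.columns:
        raise ValueError(f"{path}: counts TSV lacks a 'length' column")
    return df


def write_coverage_tsv(m: CoverageMatrix, path: str | Path,
                       provenance: Sequence[str] = ()) -> None:
    lines = [f"transformed={str(m.transformed).lower()} scale_factor={m.scale_factor:g}"]
    lines.extend(provenance)
    _write_tsv(m.frame, path, lines, index_label="contig_id", float_format="%.10g")


def read_coverage_tsv(path: str | Path) -> CoverageMatrix:
    transformed = False
    scale = 5.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "transformed=" in first:
        fields = dict(tok.split("=", 1) for tok in first[1:].split() if "=" in tok)
        transformed = fields.get("transformed", "false") == "true"
        scale = float(fields.get("scale_factor", "5"))
    frame = pd.read_csv(path, sep="\t", comment="#", index_col="contig_id")
    return CoverageMatrix(frame=frame, transformed=transformed, scale_factor=scale)


def read_fasta(path: str | Path, with_sequences: bool = True) -> ContigSet:
    """Load contigs from a FASTA file."""
    from Bio import SeqIO

    ids: list[str] = []
    lengths: list[int] = []
    seqs: dict[str, str] | None = {} if with_sequences else None
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        lengths.append(len(rec.seq))
        if seqs is not None:
            seqs[rec.id] = str(rec.seq).upper()
    return ContigSet(ids=ids, lengths=np.array(lengths, dtype=np.int64), sequences=seqs)


def counts_from_alignments(
    path: str | Path,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Count primary alignments per contig from a SAM/BAM file.

    Secondary, supplementary and unmapped records are ignored; no MAPQ filter
    and no duplicate marking (multi-mapped reads count once, at their primary
    location).  Returns a counts table in the standard dialect with a single
    sample column.
    """
    import pysam

    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    sample = sample_id or path.stem
    with pysam.AlignmentFile(str(path), mode) as fh:
        refs = list(fh.references)
        lengths = {r: int(l) for r, l in zip(fh.references, fh.lengths)}
        counts = {r: 0 for r in refs}
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            counts[rec.reference_name] += 1
    return pd.DataFrame(
        {"length": [lengths[r] for r in refs], sample: [counts[r] for r in refs]},
        index=pd.Index(refs, name="contig_id"),
    )
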