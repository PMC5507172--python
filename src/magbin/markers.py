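"""Single-copy-marker quality control for contig bins.

A bin that represents one genome should carry each universal single-copy
marker gene exactly once.  From a table of marker hits on contigs this module
estimates, per bin:

* completeness        — percent of the marker universe present at least once,
* contamination       — percent of redundant marker copies,
* strain heterogeneity — percent of duplicate copy pairs that are
  near-identical (same-strain duplicates rather than distinct contaminants),
* cumulative redundancy — contamination discounted by strain heterogeneity:
  contamination − (contamination × strain heterogeneity / 100),

and triages the bin into one of three categories: ``draft`` (≥50% complete,
≤10% cumulative redundancy), ``high_contamination`` (≥50% complete, >10%
cumulative redundancy) or ``low_completion`` (<50% complete).

This is a deliberately universal (lineage-agnostic) marker model: the marker
universe is a configurable flat set (default size 104), and copy identities
are read from the table rather than recomputed by alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerTable",
    "QCReport",
    "tally_markers",
    "completeness",
    "contamination",
    "strain_heterogeneity",
    "cumulative_redundancy",
    "triage_bin",
    "estimate_genome_count",
    "qc_bin",
    "read_marker_tsv",
    "write_marker_tsv",
    "write_qc_tsv",
    "marker_table_from_hmmer",
    "DRAFT",
    "HIGH_CONTAMINATION",
    "LOW_COMPLETION",
]

DRAFT = "draft"
HIGH_CONTAMINATION = "high_contamination"
LOW_COMPLETION = "low_completion"

_COLUMNS = ["contig_id", "marker_id", "start", "end", "identity"]


@dataclass
class MarkerTable:
    """Marker hits on contigs plus the expected single-copy marker universe."""

    frame: pd.DataFrame  # columns: contig_id, marker_id, start, end, identity
    universe: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"marker table lacks column(s) {missing}")
        self.universe = list(self.universe)
        unknown = set(self.frame["marker_id"]) - set(self.universe)
        if unknown:
            raise ValueError(f"marker {sorted(unknown)[0]!r} not in marker universe")
        ident = self.frame["identity"].to_numpy(dtype=float)
        if len(ident) and (ident.min() < 0 or ident.max() > 1):
            raise ValueError("identity values must lie in [0, 1]")
        bad = self.frame["start"] >= self.frame["end"]
        if bad.any():
            row = self.frame[bad].iloc[0]
            raise ValueError(
                f"empty/inverted marker interval for {row['marker_id']!r} "
                f"on {row['contig_id']!r}"
            )

    @property
    def size(self) -> int:
        return len(self.universe)

    def rows_for(self, contig_ids: Iterable[str]) -> pd.DataFrame:
        wanted = set(contig_ids)
        return self.frame[self.frame["contig_id"].isin(wanted)]


@dataclass
class QCReport:
    """Per-bin marker-based quality estimates and triage category."""

    completeness: float
    contamination: float
    strain_heterogeneity: float
    cumulative_redundancy: float
    category: str
    est_genomes: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError("completeness out of [0, 100]")
        if self.contamination < 0:
            raise ValueError("contamination negative")
        if not (0.0 <= self.strain_heterogeneity <= 100.0):
            raise ValueError("strain heterogeneity out of [0, 100]")
        if not (-1e-9 <= self.cumulative_redundancy <= self.contamination + 1e-9):
            raise ValueError("cumulative redundancy out of [0, contamination]")


def tally_markers(contig_ids: Iterable[str], table: MarkerTable) -> pd.Series:
    """Copy count of every marker in the universe over the given contigs."""
    rows = table.rows_for(contig_ids)
    counts = rows["marker_id"].value_counts()
    return counts.reindex(table.universe, fill_value=0).astype(int)


def completeness(counts: pd.Series | np.ndarray, marker_set_size: int) -> float:
    """Percent of the marker universe present at least once."""
    c = np.asarray(counts)
    return 100.0 * float((c >= 1).sum()) / float(marker_set_size)


def contamination(counts: pd.Series | np.ndarray, marker_set_size: int) -> float:
    """Percent of redundant marker copies: 100 * sum(max(0, n_m - 1)) / M."""
    c = np.asarray(counts)
    return 100.0 * float(np.maximum(0, c - 1).sum()) / float(marker_set_size)


def strain_heterogeneity(
    duplicate_rows: pd.DataFrame,
    identity_threshold: float = 0.9,
) -> float:
    """Percent of duplicate copy pairs that look like same-strain copies.

    For every marker with two or more copies in the bin, all unordered copy
    pairs are formed; a pair is near-identical when min(identity_a,
    identity_b) >= threshold (both copies at least that close to the marker's
    canonical sequence).  Returns 0 when there are no duplicates.
    """
    if len(duplicate_rows) == 0:
        return 0.0
    total = 0
    close = 0
    for _, grp in duplicate_rows.groupby("marker_id"):
        idents = grp["identity"].to_numpy(dtype=float)
        if len(idents) < 2:
            continue
        for a, b in combinations(idents, 2):
            total += 1
            if min(a, b) >= identity_threshold:
                close += 1
    if total == 0:
        return 0.0
    return 100.0 * close / total


def cumulative_redundancy(contamination_pct: float, strain_het_pct: float) -> float:
    """contamination − (contamination × strain heterogeneity / 100)."""
    return contamination_pct - (contamination_pct * strain_het_pct / 100.0)


def triage_bin(
    completeness_pct: float,
    cumulative_redundancy_pct: float,
    complete_min: float = 50.0,
    redundancy_max: float = 10.0,
) -> str:
    """Three-way triage; boundaries inclusive for the draft category."""
    if completeness_pct < complete_min:
        return LOW_COMPLETION
    if cumulative_redundancy_pct <= redundancy_max:
        return DRAFT
    return HIGH_CONTAMINATION


def estimate_genome_count(contamination_pct: float) -> int:
    """Approximate number of genomes in a bin from its contamination.

    k merged complete genomes score about (k-1)*100% contamination under the
    redundant-copy definition, so the estimate is 1 + round(contamination /
    100) (half-up), floored at 1.
    """
    return max(1, 1 + int(math.floor(contamination_pct / 100.0 + 0.5)))


def qc_bin(
    contig_ids: Iterable[str],
    table: MarkerTable,
    identity_threshold: float = 0.9,
    complete_min: float = 50.0,
    redundancy_max: float = 10.0,
) -> QCReport:
    """Full marker QC for one bin: tally, estimates, triage."""
    contig_ids = list(contig_ids)
    counts = tally_markers(contig_ids, table)
    comp = completeness(counts, table.size)
    cont = contamination(counts, table.size)
    dup_markers = counts[counts >= 2].index
    rows = table.rows_for(contig_ids)
    dup_rows = rows[rows["marker_id"].isin(set(dup_markers))]
    sh = strain_heterogeneity(dup_rows, identity_threshold)
    cr = cumulative_redundancy(cont, sh)
    return QCReport(
        completeness=comp,
        contamination=cont,
        strain_heterogeneity=sh,
        cumulative_redundancy=cr,
        category=triage_bin(comp, cr, complete_min, redundancy_max),
        est_genomes=estimate_genome_count(cont),
    )


# ---------------------------------------------------------------------------
# IO


def write_marker_tsv(table: MarkerTable, path: str | Path,
                     provenance: Sequence[str] = ()) -> None:
    lines = [f"# {p}\n" for p in provenance]
    lines.append("# marker_universe=" + ",".join(table.universe) + "\n")
    lines.append("\t".join(["genome_id"] + _COLUMNS) + "\n" if "genome_id" in table.frame.columns
                 else "\t".join(_COLUMNS) + "\n")
    cols = (["genome_id"] + _COLUMNS) if "genome_id" in table.frame.columns else _COLUMNS
    for row in table.frame[cols].itertuples(index=False):
        vals = [f"{v:.6f}" if isinstance(v, float) else str(v) for v in row]
        lines.append("\t".join(vals) + "\n")
    Path(path).write_text("".join(lines))


def read_marker_tsv(path: str | Path, universe: Sequence[str] | None = None) -> MarkerTable:
    """Read a marker TSV; the universe comes from a '# marker_universe=' header
    line unless given explicitly."""
    header_universe: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# marker_universe="):
                header_universe = line.split("=", 1)[1].strip().split(",")
    df = pd.read_csv(path, sep="\t", comment="#")
    uni = list(universe) if universe is not None else header_universe
    if uni is None:
        uni = sorted(df["marker_id"].unique())
    return MarkerTable(frame=df, universe=uni)


def write_qc_tsv(reports: dict[str, QCReport], path: str | Path,
                 provenance: Sequence[str] = ()) -> None:
    lines = [f"# {p}\n" for p in provenance]
    lines.append(
        "bin_id\tcompleteness\tcontamination\tstrain_heterogeneity"
        "\tcumulative_redundancy\tcategory\test_genomes\n"
    )
    for bin_id in sorted(reports):
        r = reports[bin_id]
        lines.append(
            f"{bin_id}\t{r.completeness:.4f}\t{r.contamination:.4f}"
            f"\t{r.strain_heterogeneity:.4f}\t{r.cumulative_redundancy:.4f}"
            f"\t{r.category}\t{r.est_genomes}\n"
        )
    Path(path).write_text("".join(lines))


def marker_table_from_hmmer(
    path: str | Path,
    universe: Sequence[str],
    default_identity: float = 1.0,
) -> MarkerTable:
    """Convert HMMER tabular hits (``hmmsearch --tblout``) to a MarkerTable.

    The query (HMM) name is taken as the marker id and the target name as the
    contig id.  tblout carries no alignment coordinates or identities, so
    intervals default to [0, 1) placeholders and identity to
    *default_identity*; hits to markers outside *universe* are dropped.
    """
    rows = []
    uni = set(universe)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            target, query = parts[0], parts[2]
            if query not in uni:
                continue
            rows.append((target, query, 0, 1, default_identity))
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    return MarkerTable(frame=frame, universe=list(universe))
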