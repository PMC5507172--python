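"""Length-normalized relative abundance of draft genomes, and truth-based
evaluation of binning runs.

For each draft genome g and sample s the abundance is

    ( (reads/bp of g) / sum over genomes of (reads/bp) )
      x ( reads recruited to all genomes / reads recruited to all
          data-rich contigs (>= 2 kb) ) x 100

so per-sample genome abundances sum to 100 x (genome-recruited reads /
all data-rich-recruited reads) and never exceed 100.  "reads/bp of g" is, by
default, the genome's total recruited reads divided by its total length
(length-weighted); the mean of per-contig reads/bp is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

from .coverage import ContigSet
from .synthetic import SyntheticTruth

__all__ = [
    "AbundanceTable",
    "genome_relative_abundance",
    "summarize_abundance",
    "adjusted_rand_index",
    "evaluate_bins",
    "write_abundance_tsv",
]


@dataclass
class AbundanceTable:
    """Genomes x samples percent abundances (NaN where undefined)."""

    frame: pd.DataFrame

    @property
    def genome_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)


def genome_relative_abundance(
    genome_bins: Mapping[str, Sequence[str]],
    counts: pd.DataFrame,
    data_rich: ContigSet | Sequence[str] | None = None,
    min_length: int = 2000,
    per_contig_average: bool = False,
) -> AbundanceTable:
    """Length-normalized relative abundance per draft genome per sample.

    Parameters
    ----------
    genome_bins
        genome label -> its contig ids.
    counts
        Counts table (contig_id index, 'length' column, sample columns) over
        at least the data-rich universe.
    data_rich
        The read-recruitment universe (contigs >= 2 kb).  When omitted it is
        derived from the counts table with *min_length*.
    per_contig_average
        Use the mean of per-contig reads/bp as the genome's reads/bp instead
        of the length-weighted genome total.
    """
    lengths = counts["length"].astype(float)
    reads = counts.drop(columns=["length"])
    if data_rich is None:
        rich_ids = list(lengths.index[lengths >= min_length])
    else:
        rich_ids = data_rich.ids if isinstance(data_rich, ContigSet) else list(data_rich)
    missing = set(rich_ids) - set(reads.index)
    if missing:
        raise ValueError(f"data-rich contig {sorted(missing)[0]!r} absent from counts")

    samples = list(reads.columns)
    genomes = list(genome_bins)
    rpb = np.zeros((len(genomes), len(samples)))
    genome_reads = np.zeros((len(genomes), len(samples)))
    for i, g in enumerate(genomes):
        members = list(genome_bins[g])
        miss = set(members) - set(reads.index)
        if miss:
            raise ValueError(f"genome contig {sorted(miss)[0]!r} absent from counts")
        sub_reads = reads.loc[members].to_numpy(dtype=float)
        sub_len = lengths.loc[members].to_numpy()
        genome_reads[i] = sub_reads.sum(axis=0)
        if per_contig_average:
            rpb[i] = (sub_reads / sub_len[:, None]).mean(axis=0)
        else:
            rpb[i] = genome_reads[i] / sub_len.sum()

    total_rpb = rpb.sum(axis=0)
    total_genome_reads = genome_reads.sum(axis=0)
    total_rich_reads = reads.loc[rich_ids].sum(axis=0).to_numpy(dtype=float)

    with np.errstate(invalid="ignore", divide="ignore"):
        values = (rpb / total_rpb) * (total_genome_reads / total_rich_reads) * 100.0
    # zero reads on the whole >=2 kb universe: abundance is undefined
    values[:, total_rich_reads == 0] = np.nan
    # a sample where no genome recruited anything: all-zero rpb -> 0/0
    zero_rpb = (total_rpb == 0) & (total_rich_reads > 0)
    values[:, zero_rpb] = 0.0
    frame = pd.DataFrame(values, index=pd.Index(genomes, name="genome_id"),
                         columns=samples)
    return AbundanceTable(frame=frame)


def summarize_abundance(table: AbundanceTable, n: int = 10) -> pd.DataFrame:
    """Per-sample totals over all draft genomes and over the n most abundant.

    Ties at rank n are broken by genome label so the summary is deterministic.
    """
    rows = []
    for s in table.sample_ids:
        col = table.frame[s]
        order = sorted(zip(col.to_numpy(), col.index), key=lambda t: (-t[0], t[1]))
        top = sum(v for v, _ in order[:n])
        rows.append({
            "sample_id": s,
            "relative_abundance_drafts_pct": float(col.sum()),
            f"relative_abundance_top{n}_pct": float(top),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two labelings of the same items.

    Hubert-Arabie adjustment of the Rand index via the pair-counting
    contingency table; 1 for identical partitions, ~0 for independent ones.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings differ in length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty labelings")
    ct = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b)).to_numpy()
    sum_comb = comb(ct, 2).sum()
    a = comb(ct.sum(axis=1), 2).sum()
    b = comb(ct.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = a * b / total
    max_index = (a + b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def evaluate_bins(
    result,
    truth: SyntheticTruth,
    contigs: ContigSet,
    universe: Sequence[str] | None = None,
    recovery_completeness: float = 0.8,
    recovery_contamination: float = 0.1,
) -> dict:
    """Score a pipeline result against synthetic truth.

    *universe* defaults to the contigs the pipeline actually partitioned
    (result.all_contigs()).  Truth completeness of a genome is the fraction
    of its universe bp that lies in its majority (best) bin; truth
    contamination of that bin is the fraction of the bin's bp coming from
    other genomes.  The adjusted Rand index is computed over binned contigs
    (drafts and low-completion bins).
    """
    assignment = result.assignment_map() if hasattr(result, "assignment_map") else dict(result)
    if universe is None:
        universe = result.all_contigs() if hasattr(result, "all_contigs") else list(assignment)
    universe = list(universe)
    length_of = contigs.length_by_id

    draft_labels = {b.label for b in getattr(result, "draft_genomes", [])} or None

    # per-bin bp by genome
    bin_genome_bp: dict[str, dict[str, float]] = {}
    for c in universe:
        lab = assignment.get(c)
        if lab is None:
            continue
        g = truth.contig_to_genome[c]
        bin_genome_bp.setdefault(lab, {}).setdefault(g, 0.0)
        bin_genome_bp[lab][g] += length_of[c]

    genome_bp: dict[str, float] = {}
    for c in universe:
        g = truth.contig_to_genome[c]
        genome_bp[g] = genome_bp.get(g, 0.0) + length_of[c]

    per_genome = []
    for g, total_bp in sorted(genome_bp.items()):
        best_bin, best_bp = None, 0.0
        for lab, by_genome in bin_genome_bp.items():
            bp = by_genome.get(g, 0.0)
            if bp > best_bp or (bp == best_bp and best_bin is None):
                best_bin, best_bp = lab, bp
        if best_bin is None:
            per_genome.append({
                "genome_id": g, "best_bin": "", "best_bin_is_draft": False,
                "truth_completeness": 0.0, "truth_contamination": np.nan,
            })
            continue
        bin_total = sum(bin_genome_bp[best_bin].values())
        per_genome.append({
            "genome_id": g,
            "best_bin": best_bin,
            "best_bin_is_draft": (draft_labels is None or best_bin in draft_labels),
            "truth_completeness": best_bp / total_bp,
            "truth_contamination": 1.0 - bin_genome_bp[best_bin][g] / bin_total,
        })
    per_genome_df = pd.DataFrame(per_genome).set_index("genome_id")

    binned = [c for c in universe if c in assignment]
    if binned:
        ari = adjusted_rand_index(
            [truth.contig_to_genome[c] for c in binned],
            [assignment[c] for c in binned],
        )
    else:
        ari = np.nan

    recovered = per_genome_df[
        per_genome_df["best_bin_is_draft"]
        & (per_genome_df["truth_completeness"] >= recovery_completeness)
        & (per_genome_df["truth_contamination"] <= recovery_contamination)
    ]
    real = [g for g in genome_bp if not g.startswith("noise")]
    summary = {
        "ari": float(ari),
        "n_genomes": len(real),
        "n_recovered": int(recovered.index.isin(real).sum()),
        "recovery_rate": float(recovered.index.isin(real).sum() / len(real)) if real else np.nan,
        "n_binned_contigs": len(binned),
        "n_unbinned_contigs": len(universe) - len(binned),
    }
    if hasattr(result, "summary"):
        summary.update(result.summary())
    return {"per_genome": per_genome_df, "summary": summary}


def write_abundance_tsv(table: AbundanceTable, path: str | Path,
                        provenance: Sequence[str] = ()) -> None:
    lines = [f"# {p}\n" for p in provenance]
    lines.append(table.frame.to_csv(sep="\t", index_label="genome_id",
                                    float_format="%.4f"))
    Path(path).write_text("".join(lines))
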