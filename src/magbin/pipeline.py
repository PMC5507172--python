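"""The multi-round binning ladder.

Phase A (transformed coverage): contigs >= 7.5 kb are clustered by affinity
propagation on coverage profiles scaled by 5, preference -3 (4,000 iteration
budget, 400-iteration convergence window, damping 0.9).  Bins are triaged by
marker QC; high-contamination bins are re-binned locally with a preference
chosen from the estimated number of resident genomes (two: -1000, three:
-500, four or more: -100; 2,000/200 iteration budget), then once more at a
fixed preference of -100 (optionally on coverage + tetranucleotide features).
Draft bins are frozen as soon as they are triaged.

Phase B (raw coverage): every contig not assigned to a draft is re-binned on
raw (untransformed) coverage with the initial parameters, refined once with
the genome-count preference schedule and once more at a fixed preference of
-10.

Finalization: remaining non-draft bins with at least five contigs become
low-completion bins (residual high-contamination bins are demoted into this
set, flagged); smaller bins dissolve into the unbinned set.  Drafts,
low-completion bins and unbinned contigs partition the binned-contig
universe, and the whole ladder is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ap import APParams, BinSet, bin_contigs
from .coverage import (
    ContigSet,
    CoverageMatrix,
    compute_coverage,
    filter_contigs,
    transform_coverage,
)
from .markers import (
    DRAFT,
    HIGH_CONTAMINATION,
    LOW_COMPLETION,
    MarkerTable,
    QCReport,
    qc_bin,
    write_qc_tsv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LadderConfig",
    "Bin",
    "PipelineResult",
    "run_initial_binning",
    "refine_high_contamination",
    "rebin_unassigned",
    "finalize_bins",
    "run_pipeline",
    "write_result",
]


@dataclass(frozen=True)
class LadderConfig:
    """Parameters of the full binning ladder (defaults follow the published
    BinSanity-style protocol)."""

    initial: APParams = field(default_factory=lambda: APParams(
        preference=-3.0, damping=0.9, max_iter=4000, conv_iter=400))
    refine_max_iter: int = 2000
    refine_conv_iter: int = 200
    refine_damping: float = 0.9
    # estimated genome count -> refine preference; >=4 uses the default
    preference_schedule: Mapping[int, float] = field(
        default_factory=lambda: {2: -1000.0, 3: -500.0})
    default_refine_preference: float = -100.0
    second_refine_preference: float = -100.0
    leftover_second_preference: float = -10.0
    min_bin_contigs: int = 5
    binned_min_length: int = 7500
    data_rich_min_length: int = 2000
    scale_factor: float = 5.0
    use_composition_in_refine: bool = False
    identity_threshold: float = 0.9
    complete_min: float = 50.0
    redundancy_max: float = 10.0
    draft_prefix: str = "TMED"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(p >= 0 for p in self.preference_schedule.values()):
            raise ValueError("refine preferences must be negative")
        if self.min_bin_contigs < 1:
            raise ValueError("min_bin_contigs must be >= 1")

    def schedule_preference(self, est_genomes: int) -> float:
        return float(self.preference_schedule.get(
            est_genomes, self.default_refine_preference))

    def refine_params(self, preference: float, seed_offset: int = 0) -> APParams:
        return APParams(
            preference=preference,
            damping=self.refine_damping,
            max_iter=self.refine_max_iter,
            conv_iter=self.refine_conv_iter,
            seed=self.seed + seed_offset,
        )


@dataclass
class Bin:
    """A candidate bin: member contigs, marker QC, and provenance."""

    contigs: list[str]
    qc: QCReport
    provenance: str
    label: str = ""
    demoted: bool = False


@dataclass
class PipelineResult:
    """Final ladder output: drafts, low-completion bins, unbinned contigs."""

    draft_genomes: list[Bin]
    low_completion_bins: list[Bin]
    unbinned_contigs: list[str]
    round_log: list[dict] = field(default_factory=list)

    def assignment_map(self) -> dict[str, str]:
        """contig id -> final bin label (drafts and low-completion bins)."""
        out: dict[str, str] = {}
        for b in self.draft_genomes + self.low_completion_bins:
            for c in b.contigs:
                out[c] = b.label
        return out

    def all_contigs(self) -> list[str]:
        out = []
        for b in self.draft_genomes + self.low_completion_bins:
            out.extend(b.contigs)
        out.extend(self.unbinned_contigs)
        return out

    def summary(self) -> dict[str, int]:
        return {
            "draft_genomes": len(self.draft_genomes),
            "low_completion_bins": len(self.low_completion_bins),
            "draft_contigs": sum(len(b.contigs) for b in self.draft_genomes),
            "low_completion_contigs": sum(
                len(b.contigs) for b in self.low_completion_bins),
            "unbinned_contigs": len(self.unbinned_contigs),
        }


def _qc(contigs: Sequence[str], markers: MarkerTable, cfg: LadderConfig) -> QCReport:
    return qc_bin(
        contigs, markers,
        identity_threshold=cfg.identity_threshold,
        complete_min=cfg.complete_min,
        redundancy_max=cfg.redundancy_max,
    )


def _triage_binset(
    binset: BinSet,
    markers: MarkerTable,
    cfg: LadderConfig,
    provenance: str,
) -> tuple[list[Bin], list[Bin], list[Bin], list[str]]:
    """QC every bin of a BinSet; split into (drafts, high-contam, low-completion,
    unbinned contigs)."""
    drafts: list[Bin] = []
    high: list[Bin] = []
    low: list[Bin] = []
    for bin_id, members in binset.bins().items():
        report = _qc(members, markers, cfg)
        b = Bin(contigs=members, qc=report, provenance=provenance)
        if report.category == DRAFT:
            drafts.append(b)
        elif report.category == HIGH_CONTAMINATION:
            high.append(b)
        else:
            low.append(b)
    return drafts, high, low, list(binset.unbinned)


def _assert_conservation(input_ids: Sequence[str], *groups: Sequence[str]) -> None:
    seen: list[str] = []
    for g in groups:
        seen.extend(g)
    if sorted(seen) != sorted(input_ids):
        raise RuntimeError(
            f"contig conservation violated: {len(seen)} out vs {len(input_ids)} in")


def _composition_features(
    cov_values: np.ndarray,
    contig_ids: Sequence[str],
    sequences: Mapping[str, str],
) -> np.ndarray:
    """Coverage + tetranucleotide features: both blocks column-z-scored, each
    divided by sqrt(its width) so the blocks carry equal weight."""
    from .ap import composition_matrix

    tetra = composition_matrix([sequences[c] for c in contig_ids])

    def zblock(X: np.ndarray) -> np.ndarray:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd / np.sqrt(X.shape[1])

    return np.hstack([zblock(cov_values.astype(float)), zblock(tetra)])


def run_initial_binning(
    coverage: CoverageMatrix,
    markers: MarkerTable,
    cfg: LadderConfig,
    round_label: str = "initial",
) -> tuple[list[Bin], list[Bin], list[Bin], list[str]]:
    """Cluster all contigs of *coverage* and triage every bin.

    The caller supplies coverage already restricted to the binnable universe
    (>= ``binned_min_length``) and transformed or raw as the phase requires.
    """
    if len(coverage.contig_ids) == 0:
        raise ValueError("no contigs to bin")
    params = replace(cfg.initial, seed=cfg.seed)
    binset = bin_contigs(
        coverage.values, params, contig_ids=coverage.contig_ids,
        round_label=round_label,
    )
    groups = _triage_binset(binset, markers, cfg, provenance=round_label)
    _assert_conservation(
        coverage.contig_ids,
        *[b.contigs for g in groups[:3] for b in g], groups[3],
    )
    return groups


def refine_high_contamination(
    bins: list[Bin],
    coverage: CoverageMatrix,
    markers: MarkerTable,
    cfg: LadderConfig,
    round_label: str,
    fixed_preference: float | None = None,
    sequences: Mapping[str, str] | None = None,
    seed_offset: int = 0,
) -> tuple[list[Bin], list[Bin], list[Bin], list[str]]:
    """Re-bin each high-contamination bin locally on its own contigs.

    With ``fixed_preference=None`` the preference comes from the genome-count
    schedule (first refine round); otherwise the given preference is used for
    every bin (second refine round), optionally with composition features.
    Bins with fewer than two contigs pass through unchanged.
    """
    drafts: list[Bin] = []
    high: list[Bin] = []
    low: list[Bin] = []
    unbinned: list[str] = []
    use_comp = (
        fixed_preference is not None
        and cfg.use_composition_in_refine
        and sequences is not None
    )
    for j, b in enumerate(bins):
        if len(b.contigs) < 2:
            logger.info("%s: bin of %d contig(s) passed through", round_label, len(b.contigs))
            high.append(b)
            continue
        pref = fixed_preference if fixed_preference is not None \
            else cfg.schedule_preference(b.qc.est_genomes)
        sub = coverage.subset(b.contigs)
        feats = sub.values
        if use_comp:
            feats = _composition_features(feats, sub.contig_ids, sequences)
        params = cfg.refine_params(pref, seed_offset=seed_offset + j + 1)
        binset = bin_contigs(
            feats, params, contig_ids=sub.contig_ids,
            round_label=f"{round_label}[p={pref:g}]",
        )
        d, h, l, u = _triage_binset(binset, markers, cfg,
                                    provenance=f"{round_label}[p={pref:g}]")
        _assert_conservation(
            b.contigs, *[x.contigs for g in (d, h, l) for x in g], u)
        drafts.extend(d)
        high.extend(h)
        low.extend(l)
        unbinned.extend(u)
    return drafts, high, low, unbinned


def _ladder_phase(
    coverage: CoverageMatrix,
    markers: MarkerTable,
    cfg: LadderConfig,
    phase: str,
    second_preference: float,
    sequences: Mapping[str, str] | None,
    round_log: list[dict],
    seed_offset: int = 0,
) -> tuple[list[Bin], list[Bin], list[str]]:
    """One full phase: initial AP + two refine rounds.

    Returns (drafts, non-draft bins, unbinned); residual high-contamination
    bins after the second refine are demoted to the non-draft (low-completion
    candidate) set with ``demoted=True``.
    """
    drafts, high, low, unbinned = run_initial_binning(
        coverage, markers, cfg, round_label=f"{phase}:initial")
    round_log.append(_record(f"{phase}:initial", coverage.values.shape[0],
                             cfg.initial.preference, drafts, high, low, unbinned))

    d1, high, l1, u1 = refine_high_contamination(
        high, coverage, markers, cfg, round_label=f"{phase}:refine1",
        seed_offset=seed_offset + 1000)
    drafts += d1
    low += l1
    unbinned += u1
    round_log.append(_record(f"{phase}:refine1", sum(len(b.contigs) for b in high)
                             + sum(len(b.contigs) for b in d1 + l1) + len(u1),
                             None, d1, high, l1, u1))

    d2, high, l2, u2 = refine_high_contamination(
        high, coverage, markers, cfg, round_label=f"{phase}:refine2",
        fixed_preference=second_preference, sequences=sequences,
        seed_offset=seed_offset + 2000)
    drafts += d2
    low += l2
    unbinned += u2
    round_log.append(_record(f"{phase}:refine2", sum(len(b.contigs) for b in high)
                             + sum(len(b.contigs) for b in d2 + l2) + len(u2),
                             second_preference, d2, high, l2, u2))

    # terminal categories are draft or low-completion: residual
    # high-contamination bins are demoted, flagged
    for b in high:
        b.demoted = True
        low.append(b)
    return drafts, low, unbinned


def _record(label: str, n_in: int, preference: float | None,
            drafts: list[Bin], high: list[Bin], low: list[Bin],
            unbinned: list[str]) -> dict:
    return {
        "round": label,
        "n_contigs_in": int(n_in),
        "preference": preference,
        "draft": len(drafts),
        "high_contamination": len(high),
        "low_completion": len(low),
        "unbinned_contigs": len(unbinned),
    }


def rebin_unassigned(
    leftover_ids: Sequence[str],
    raw_coverage: CoverageMatrix,
    markers: MarkerTable,
    cfg: LadderConfig,
    round_log: list[dict] | None = None,
) -> tuple[list[Bin], list[Bin], list[str]]:
    """Raw-coverage re-binning of contigs not assigned to any draft.

    Runs the initial-style clustering on untransformed coverage followed by
    the two refine rounds (genome-count schedule, then fixed preference -10).
    """
    if round_log is None:
        round_log = []
    if len(leftover_ids) == 0:
        return [], [], []
    if raw_coverage.transformed:
        raise ValueError("leftover re-binning requires raw (untransformed) coverage")
    sub = raw_coverage.subset(list(leftover_ids))
    return _ladder_phase(
        sub, markers, cfg, phase="leftover",
        second_preference=cfg.leftover_second_preference,
        sequences=None, round_log=round_log, seed_offset=50000,
    )


def finalize_bins(
    drafts: list[Bin],
    other_bins: list[Bin],
    unbinned: Sequence[str],
    cfg: LadderConfig,
    universe: Sequence[str],
    round_log: list[dict] | None = None,
) -> PipelineResult:
    """Label drafts and low-completion bins; dissolve small non-draft bins.

    Non-draft bins keep their contigs only if they have at least
    ``min_bin_contigs`` members (inclusive bound); smaller bins dissolve into
    the unbinned set.  The result partitions *universe*.
    """
    unbinned = list(unbinned)
    kept_low: list[Bin] = []
    for b in other_bins:
        if len(b.contigs) >= cfg.min_bin_contigs:
            kept_low.append(b)
        else:
            unbinned.extend(b.contigs)
    for i, b in enumerate(drafts):
        b.label = f"{cfg.draft_prefix}{i + 1}"
    for i, b in enumerate(kept_low):
        b.label = f"{cfg.draft_prefix}lc{i + 1}"
    result = PipelineResult(
        draft_genomes=drafts,
        low_completion_bins=kept_low,
        unbinned_contigs=sorted(unbinned),
        round_log=list(round_log or []),
    )
    _assert_conservation(universe, result.all_contigs())
    return result


def run_pipeline(
    contigs: ContigSet,
    counts: pd.DataFrame,
    markers: MarkerTable,
    cfg: LadderConfig | None = None,
) -> PipelineResult:
    """End-to-end ladder: length filter, coverage, both phases, finalization."""
    cfg = cfg or LadderConfig()
    binnable = filter_contigs(contigs, cfg.binned_min_length)
    if len(binnable) == 0:
        raise ValueError(
            f"no contigs of length >= {cfg.binned_min_length} bp to bin")
    raw_all = compute_coverage(counts)
    raw = raw_all.subset(binnable.ids)
    transformed = transform_coverage(raw, cfg.scale_factor)
    sequences = binnable.sequences if cfg.use_composition_in_refine else None

    round_log: list[dict] = []
    drafts, nondraft_a, unbinned_a = _ladder_phase(
        transformed, markers, cfg, phase="transformed",
        second_preference=cfg.second_refine_preference,
        sequences=sequences, round_log=round_log,
    )

    # everything not in a draft is re-binned from scratch on raw coverage
    draft_members = {c for b in drafts for c in b.contigs}
    leftover = [c for c in binnable.ids if c not in draft_members]
    d_b: list[Bin] = []
    nondraft_b: list[Bin] = []
    unbinned_b: list[str] = []
    if leftover:
        d_b, nondraft_b, unbinned_b = rebin_unassigned(
            leftover, raw, markers, cfg, round_log=round_log)
    drafts += d_b

    return finalize_bins(
        drafts, nondraft_b, unbinned_b, cfg,
        universe=binnable.ids, round_log=round_log,
    )


def write_result(
    result: PipelineResult,
    outdir: str | Path,
    cfg: LadderConfig | None = None,
    manifest_extra: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write bin assignments, QC, the round log and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    bins_path = outdir / "bins.tsv"
    lines = ["contig_id\tbin_id\tcategory\tprovenance\n"]
    for b in result.draft_genomes:
        for c in b.contigs:
            lines.append(f"{c}\t{b.label}\tdraft\t{b.provenance}\n")
    for b in result.low_completion_bins:
        cat = "low_completion_demoted" if b.demoted else "low_completion"
        for c in b.contigs:
            lines.append(f"{c}\t{b.label}\t{cat}\t{b.provenance}\n")
    for c in result.unbinned_contigs:
        lines.append(f"{c}\tunbinned\tunbinned\t-\n")
    bins_path.write_text("".join(lines))
    paths["bins"] = bins_path

    qc_path = outdir / "qc.tsv"
    reports = {b.label: b.qc for b in result.draft_genomes + result.low_completion_bins}
    write_qc_tsv(reports, qc_path)
    paths["qc"] = qc_path

    log_path = outdir / "round_log.tsv"
    pd.DataFrame(result.round_log).to_csv(log_path, sep="\t", index=False)
    paths["round_log"] = log_path

    manifest = {"summary": result.summary()}
    if cfg is not None:
        manifest["config"] = {
            "initial_preference": cfg.initial.preference,
            "initial_max_iter": cfg.initial.max_iter,
            "initial_conv_iter": cfg.initial.conv_iter,
            "damping": cfg.initial.damping,
            "preference_schedule": {str(k): v for k, v in cfg.preference_schedule.items()},
            "second_refine_preference": cfg.second_refine_preference,
            "leftover_second_preference": cfg.leftover_second_preference,
            "min_bin_contigs": cfg.min_bin_contigs,
            "binned_min_length": cfg.binned_min_length,
            "scale_factor": cfg.scale_factor,
            "use_composition_in_refine": cfg.use_composition_in_refine,
            "seed": cfg.seed,
        }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path
    return paths
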