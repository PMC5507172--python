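"""Length-normalized relative abundance and truth-based evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import magbin as mb


def make_counts(lengths, reads):
    idx = pd.Index([f"c{i}" for i in range(len(lengths))], name="contig_id")
    df = pd.DataFrame(reads, index=idx)
    df.insert(0, "length", lengths)
    return df


class TestRelativeAbundance:
    def test_single_genome_owning_everything_is_100(self):
        counts = make_counts([3000, 5000], {"S1": [30, 70], "S2": [4, 5]})
        table = mb.genome_relative_abundance({"G1": ["c0", "c1"]}, counts)
        assert table.frame.loc["G1", "S1"] == pytest.approx(100.0)
        assert table.frame.loc["G1", "S2"] == pytest.approx(100.0)

    def test_equal_rpb_genomes_recruiting_half_score_25_each(self):
        # two genomes with identical reads/bp; a third data-rich contig
        # absorbs the other half of the reads
        counts = make_counts(
            [10_000, 10_000, 20_000],
            {"S1": [100, 100, 200]},
        )
        table = mb.genome_relative_abundance(
            {"GA": ["c0"], "GB": ["c1"]}, counts)
        assert table.frame.loc["GA", "S1"] == pytest.approx(25.0)
        assert table.frame.loc["GB", "S1"] == pytest.approx(25.0)

    def test_sub2kb_contigs_excluded_from_denominator(self):
        counts = make_counts(
            [10_000, 1_000],  # c1 is below the data-rich threshold
            {"S1": [100, 900]},
        )
        table = mb.genome_relative_abundance({"G1": ["c0"]}, counts)
        assert table.frame.loc["G1", "S1"] == pytest.approx(100.0)

    def test_zero_rich_reads_is_missing_not_zero(self):
        counts = make_counts([10_000, 5_000], {"S1": [0, 0]})
        table = mb.genome_relative_abundance({"G1": ["c0"]}, counts)
        assert np.isnan(table.frame.loc["G1", "S1"])

    def test_normalization_identity(self):
        """Per-sample sums equal 100 x genome reads / all >=2 kb reads."""
        rng = np.random.default_rng(17)
        lengths = rng.integers(2000, 30000, size=30)
        counts = make_counts(lengths,
                             {f"S{j}": rng.integers(0, 5000, size=30)
                              for j in range(4)})
        genome_bins = {"G1": [f"c{i}" for i in range(0, 10)],
                       "G2": [f"c{i}" for i in range(10, 18)]}
        table = mb.genome_relative_abundance(genome_bins, counts)
        reads = counts.drop(columns="length")
        genome_ids = [c for g in genome_bins.values() for c in g]
        for j in range(4):
            col = f"S{j}"
            expect = 100.0 * reads.loc[genome_ids, col].sum() / reads[col].sum()
            assert table.frame[col].sum() == pytest.approx(expect, rel=1e-12)
            assert table.frame[col].sum() <= 100.0 + 1e-9

    def test_scale_invariance_per_sample(self):
        rng = np.random.default_rng(23)
        lengths = rng.integers(2000, 30000, size=12)
        counts = make_counts(lengths,
                             {"S1": rng.integers(1, 500, size=12),
                              "S2": rng.integers(1, 500, size=12)})
        genome_bins = {"G1": ["c0", "c1"], "G2": ["c5", "c6", "c7"]}
        base = mb.genome_relative_abundance(genome_bins, counts)
        scaled = counts.copy()
        scaled["S1"] = scaled["S1"] * 17
        after = mb.genome_relative_abundance(genome_bins, scaled)
        np.testing.assert_allclose(after.frame["S1"], base.frame["S1"], rtol=1e-12)
        np.testing.assert_allclose(after.frame["S2"], base.frame["S2"], rtol=1e-12)

    def test_ranking_matches_truth_coverage(self, small_community):
        """Per-sample abundance ranking of recovered genomes tracks the true
        coverage ranking (Spearman rho >= 0.95)."""
        com = small_community
        cfg = mb.LadderConfig(binned_min_length=2000, seed=1)
        result = mb.run_pipeline(com.contigs, com.counts, com.markers, cfg)
        report = mb.evaluate_bins(result, com.truth, com.contigs)
        genome_of_bin = dict(zip(report["per_genome"]["best_bin"],
                                 report["per_genome"].index))
        bins = {b.label: b.contigs for b in result.draft_genomes}
        table = mb.genome_relative_abundance(bins, com.counts)
        for s in table.sample_ids:
            est = table.frame[s]
            truth = [com.truth.genome_coverage.loc[genome_of_bin[lbl], s]
                     for lbl in est.index]
            rho, _ = spearmanr(est.to_numpy(), truth)
            assert rho >= 0.95

    def test_per_contig_average_variant_differs_under_skew(self):
        counts = make_counts([2000, 50_000], {"S1": [200, 500]})
        weighted = mb.genome_relative_abundance({"G": ["c0", "c1"]}, counts)
        averaged = mb.genome_relative_abundance({"G": ["c0", "c1"]}, counts,
                                                per_contig_average=True)
        # both own all reads -> both 100; ratios only differ with >1 genome
        assert weighted.frame.loc["G", "S1"] == pytest.approx(100.0)
        assert averaged.frame.loc["G", "S1"] == pytest.approx(100.0)


class TestSummaries:
    def test_topn_equals_total_when_n_covers_all(self):
        frame = pd.DataFrame({"S1": [5.0, 3.0, 2.0]},
                             index=["a", "b", "c"])
        summary = mb.summarize_abundance(mb.AbundanceTable(frame), n=10)
        row = summary.loc["S1"]
        assert row["relative_abundance_top10_pct"] == row["relative_abundance_drafts_pct"]

    def test_single_genome_totals_equal(self):
        frame = pd.DataFrame({"S1": [42.0]}, index=["a"])
        summary = mb.summarize_abundance(mb.AbundanceTable(frame), n=10)
        assert summary.loc["S1"].tolist() == [42.0, 42.0]

    def test_matches_sort_and_sum_oracle(self):
        rng = np.random.default_rng(31)
        frame = pd.DataFrame(
            {f"S{j}": rng.uniform(0, 10, size=12) for j in range(3)},
            index=[f"g{i}" for i in range(12)])
        summary = mb.summarize_abundance(mb.AbundanceTable(frame), n=5)
        for j in range(3):
            col = f"S{j}"
            expect_top = sum(sorted(frame[col], reverse=True)[:5])
            assert summary.loc[col, "relative_abundance_top5_pct"] == \
                pytest.approx(expect_top, rel=1e-12)
            assert summary.loc[col, "relative_abundance_drafts_pct"] == \
                pytest.approx(frame[col].sum(), rel=1e-12)


class TestAdjustedRandIndex:
    def test_identical_partitions_are_1(self):
        assert mb.adjusted_rand_index([0, 0, 1, 1], [5, 5, 9, 9]) == 1.0

    def test_one_cluster_vs_many_is_0(self):
        labels = ["a"] * 4 + ["b"] * 4
        assert mb.adjusted_rand_index(labels, [0] * 8) == pytest.approx(0.0)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.integers(0, 5, size=60)
            b = rng.integers(0, 4, size=60)
            assert mb.adjusted_rand_index(a, b) == pytest.approx(
                sklearn_metrics.adjusted_rand_score(a, b), abs=1e-12)

    def test_random_assignment_null_near_zero(self):
        """Mean ARI of random labelings stays within +/-0.05 of 0."""
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 10, size=200)
        aris = []
        for _ in range(100):
            guess = rng.permutation(truth)
            aris.append(mb.adjusted_rand_index(truth, guess))
        assert abs(np.mean(aris)) < 0.05


class TestEvaluateBins:
    def test_perfect_binning_scores_perfectly(self, small_community):
        com = small_community
        by_genome: dict[str, list[str]] = {}
        for c, g in com.truth.contig_to_genome.items():
            by_genome.setdefault(g, []).append(c)
        assignment = {c: g for g, cs in by_genome.items() for c in cs}
        report = mb.evaluate_bins(assignment, com.truth, com.contigs,
                                  universe=com.contigs.ids)
        assert report["summary"]["ari"] == 1.0
        assert (report["per_genome"]["truth_contamination"] == 0.0).all()
        assert (report["per_genome"]["truth_completeness"] == 1.0).all()

    def test_everything_in_one_bin_scores_zero_ari(self, small_community):
        com = small_community
        assignment = {c: "all" for c in com.contigs.ids}
        report = mb.evaluate_bins(assignment, com.truth, com.contigs,
                                  universe=com.contigs.ids)
        assert report["summary"]["ari"] == pytest.approx(0.0, abs=1e-9)
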