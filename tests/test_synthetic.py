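"""Synthetic community generator: fragmentation law, the overdispersed count
model, cross-consistency of outputs, and byte-identical determinism."""

import numpy as np
import pytest

import magbin as mb
from magbin.synthetic import _nb_counts


class TestFragmentGenome:
    def test_genome_at_minimum_yields_single_contig(self):
        law = mb.ContigLengthLaw(mu_log=9.2, sigma_log=0.8, min_length=2000)
        lengths = mb.fragment_genome(2000, law, seed=0)
        assert lengths.tolist() == [2000]

    def test_constant_law_exact_division(self):
        law = mb.ContigLengthLaw(mu_log=np.log(2500), sigma_log=0.0, min_length=2000)
        lengths = mb.fragment_genome(10_000, law, seed=0)
        assert lengths.tolist() == [2500, 2500, 2500, 2500]

    def test_short_genome_error_names_genome(self):
        law = mb.ContigLengthLaw(min_length=2000)
        with pytest.raises(ValueError, match="tiny_genome"):
            mb.fragment_genome(1500, law, seed=0, genome_id="tiny_genome")

    def test_deterministic_given_seed(self):
        law = mb.ContigLengthLaw(mu_log=9.2, sigma_log=0.8, min_length=2000)
        a = mb.fragment_genome(500_000, law, seed=42)
        b = mb.fragment_genome(500_000, law, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_lengths_conserve_and_respect_floor(self):
        law = mb.ContigLengthLaw(mu_log=9.2, sigma_log=0.8, min_length=2000)
        lengths = mb.fragment_genome(1_000_000, law, seed=3)
        assert lengths.sum() <= 1_000_000
        assert lengths.min() >= 2000

    def test_mean_matches_truncated_law_monte_carlo_oracle(self):
        """Empirical mean contig length within 10% of the truncated-law mean
        estimated by an independent 1e5-draw rejection oracle."""
        mu, sigma, floor = 9.2, 0.8, 2000
        rng = np.random.default_rng(1234)
        draws = rng.lognormal(mu, sigma, size=200_000)
        draws = draws[draws >= floor][:100_000]
        oracle_mean = draws.mean()

        law = mb.ContigLengthLaw(mu_log=mu, sigma_log=sigma, min_length=floor)
        # pool several 2 Mbp genomes: a single genome yields only ~150
        # contigs, whose mean has ~7% standard error under this heavy tail
        lengths = np.concatenate([
            mb.fragment_genome(2_000_000, law, seed=7 + s) for s in range(10)
        ])
        assert lengths.mean() == pytest.approx(oracle_mean, rel=0.10)


class TestReadCounts:
    def test_zero_coverage_always_zero(self):
        assert mb.sample_read_counts(0.0, 5000, dispersion=2.0, seed=1) == 0

    def test_poisson_moment_check(self):
        """dispersion=0 degenerates to Poisson: sample mean within 3 SE."""
        rng = np.random.default_rng(10)
        counts = _nb_counts(np.full(10_000, 500.0), 0.0, rng)
        se = np.sqrt(500.0 / 10_000)
        assert abs(counts.mean() - 500.0) < 3 * se

    def test_negative_binomial_overdispersion(self):
        """mean 500, dispersion 2: variance/mean within 15% of 3."""
        rng = np.random.default_rng(11)
        counts = _nb_counts(np.full(10_000, 500.0), 2.0, rng)
        ratio = counts.var() / counts.mean()
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mb.sample_read_counts(-1.0, 100)


class TestSimulateCommunity:
    def test_single_genome_single_sample(self):
        cfg = mb.CommunityConfig(
            n_genomes=1, n_samples=1,
            genome_length_range=(200_000, 250_000),
            seed=2,
        )
        com = mb.simulate_community(cfg)
        genomes = set(com.truth.contig_to_genome.values())
        assert genomes == {"g001"}
        assert (com.counts.drop(columns="length") >= 0).all().all()

    def test_observed_coverage_tracks_truth(self):
        """Per-genome mean observed reads/bp within 10% of the truth matrix."""
        cfg = mb.CommunityConfig(
            n_genomes=3, n_samples=4,
            genome_length_range=(500_000, 600_000),
            dispersion=0.5, seed=3,
        )
        com = mb.simulate_community(cfg)
        reads = com.counts.drop(columns="length")
        lengths = com.counts["length"]
        for gid in com.truth.genome_coverage.index:
            members = [c for c, g in com.truth.contig_to_genome.items() if g == gid]
            observed = reads.loc[members].sum() / lengths.loc[members].sum()
            truth = com.truth.genome_coverage.loc[gid]
            np.testing.assert_allclose(observed, truth, rtol=0.10)

    def test_marker_conservation_and_coordinates(self, small_community):
        com = small_community
        placements = com.truth.marker_placements
        # one copy of each marker per genome
        per_genome = placements.groupby("genome_id").size()
        assert (per_genome == 104).all()
        # marker intervals lie within the host contig (0-based half-open)
        lengths = dict(zip(com.contigs.ids, com.contigs.lengths))
        assert (placements["start"] >= 0).all()
        ends_ok = [
            row.end <= lengths[row.contig_id]
            for row in placements.itertuples()
        ]
        assert all(ends_ok)

    def test_cross_consistency(self, small_community):
        com = small_community
        assert set(com.counts.index) == set(com.contigs.ids)
        assert set(com.truth.contig_to_genome) == set(com.contigs.ids)
        assert set(com.markers.frame["contig_id"]) <= set(com.contigs.ids)
        seq_lengths = {c: len(s) for c, s in com.contigs.sequences.items()}
        assert all(seq_lengths[c] == L for c, L in
                   zip(com.contigs.ids, com.contigs.lengths))

    def test_duplicated_markers_read_as_full_strain_heterogeneity(self):
        """Doubling every marker of one genome at identity 1.0 must score
        contamination 100% and strain heterogeneity 100% downstream."""
        cfg = mb.CommunityConfig(
            n_genomes=1, n_samples=2,
            genome_length_range=(300_000, 350_000),
            marker_duplication={0: (2, 1.0)},
            seed=4,
        )
        com = mb.simulate_community(cfg)
        report = mb.qc_bin(com.contigs.ids, com.markers)
        assert report.contamination == 100.0
        assert report.strain_heterogeneity == 100.0
        assert report.cumulative_redundancy == 0.0

    def test_infeasible_marker_placement_rejected(self):
        cfg = mb.CommunityConfig(
            n_genomes=1, n_samples=1,
            genome_length_range=(50_000, 60_000),
            marker_length=900,
            contig_length_law=mb.ContigLengthLaw(min_length=2000),
            seed=5,
        )
        # 104 markers x 900 bp = 93,600 bp > genome
        with pytest.raises(ValueError, match="infeasible"):
            mb.simulate_community(cfg)

    def test_unassigned_fraction_adds_noise_contigs(self):
        cfg = mb.CommunityConfig(
            n_genomes=2, n_samples=3,
            genome_length_range=(300_000, 350_000),
            unassigned_fraction=0.2, seed=6,
        )
        com = mb.simulate_community(cfg)
        noise = [c for c in com.contigs.ids if c.startswith("noise")]
        frac = len(noise) / len(com.contigs)
        assert frac == pytest.approx(0.2, abs=0.03)
        # noise contigs carry no markers
        assert not set(com.markers.frame["contig_id"]) & set(noise)

    def test_byte_identical_outputs_for_same_seed(self, tmp_path,
                                                  small_community_config):
        a = mb.simulate_community(small_community_config)
        b = mb.simulate_community(small_community_config)
        pa = mb.write_community(a, tmp_path / "a", small_community_config)
        pb = mb.write_community(b, tmp_path / "b", small_community_config)
        for name in pa:
            assert pa[name].read_bytes() == pb[name].read_bytes(), name

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            mb.CommunityConfig(n_genomes=0)
        with pytest.raises(ValueError):
            mb.CommunityConfig(unassigned_fraction=1.0)
        with pytest.raises(ValueError):
            mb.CommunityConfig(dispersion=-0.1)

    def test_composition_bias_separates_genomes_in_tetramer_space(self):
        """With the Markov bias knob, genomes differ compositionally."""
        cfg = mb.CommunityConfig(
            n_genomes=2, n_samples=2,
            genome_length_range=(100_000, 120_000),
            contig_length_law=mb.ContigLengthLaw(
                mu_log=np.log(8000), sigma_log=0.2, min_length=5000),
            composition_alpha=0.2,
            marker_length=900,
            seed=8,
        )
        com = mb.simulate_community(cfg)
        by_genome = {"g001": [], "g002": []}
        for c in com.contigs.ids:
            by_genome[com.truth.contig_to_genome[c]].append(
                mb.tetranucleotide_profile(com.contigs.sequences[c]))
        mean_a = np.mean(by_genome["g001"], axis=0)
        mean_b = np.mean(by_genome["g002"], axis=0)
        within = np.linalg.norm(by_genome["g001"] - mean_a, axis=1).mean()
        between = np.linalg.norm(mean_a - mean_b)
        assert between > 3 * within
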