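"""Shared fixtures: small feature sets for clustering oracles and synthetic
communities exercising the full ladder."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import magbin as mb


def net_similarity(S: np.ndarray, exemplar_idx: list[int]) -> float:
    """Net similarity of an exemplar subset: sum of preferences of chosen
    exemplars plus, for every other point, its best similarity to one."""
    n = S.shape[0]
    K = list(exemplar_idx)
    return float(
        sum(S[k, k] for k in K)
        + sum(max(S[i, k] for k in K) for i in range(n) if i not in K)
    )


def exhaustive_optimum(S: np.ndarray) -> float:
    """Brute-force maximum net similarity over all exemplar subsets (n <= 12)."""
    n = S.shape[0]
    assert n <= 12, "exhaustive search is only for tiny fixtures"
    best = -np.inf
    for r in range(1, n + 1):
        for K in combinations(range(n), r):
            best = max(best, net_similarity(S, list(K)))
    return best


def blobs(centers, spread, per_blob, dims, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.vstack([
        rng.normal(c, spread, size=(per_blob, dims)) for c in centers
    ])


@pytest.fixture(scope="session")
def blob_features() -> np.ndarray:
    """12 points in 3 well-separated blobs (spread << separation)."""
    return blobs(centers=(0.0, 5.0, 10.0), spread=0.05, per_blob=4, dims=3, seed=0)


@pytest.fixture(scope="session")
def small_fixtures(blob_features) -> dict[str, np.ndarray]:
    """The shipped n <= 12 feature sets for exhaustive-oracle checks."""
    rng = np.random.default_rng(7)
    return {
        "three_blobs_12": blob_features,
        "two_blobs_8": blobs(centers=(0.0, 4.0), spread=0.1, per_blob=4, dims=2, seed=1),
        "duplicates_2": np.zeros((2, 3)),
        "single_1": np.array([[1.0, 2.0]]),
        "spread_pairs_10": blobs(centers=(0.0, 3.0, 6.0, 9.0, 12.0),
                                 spread=0.05, per_blob=2, dims=2, seed=2),
        "loose_blobs_9": blobs(centers=(0.0, 2.5, 5.0), spread=0.15,
                               per_blob=3, dims=4, seed=3),
    }


@pytest.fixture(scope="session")
def small_community() -> mb.SyntheticCommunity:
    """5 genomes x 4 samples, ~130 contigs; fully separable."""
    cfg = mb.CommunityConfig(
        n_genomes=5,
        n_samples=4,
        genome_length_range=(300_000, 400_000),
        contig_length_law=mb.ContigLengthLaw(mu_log=9.2, sigma_log=0.8, min_length=2000),
        dispersion=0.5,
        seed=11,
    )
    return mb.simulate_community(cfg)


@pytest.fixture(scope="session")
def small_community_config() -> mb.CommunityConfig:
    return mb.CommunityConfig(
        n_genomes=5,
        n_samples=4,
        genome_length_range=(300_000, 400_000),
        contig_length_law=mb.ContigLengthLaw(mu_log=9.2, sigma_log=0.8, min_length=2000),
        dispersion=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def merged_pair_community() -> mb.SyntheticCommunity:
    """Two genomes with distinct coverage profiles; all contigs >= 7.5 kb so
    the union of both genomes forms a deliberately merged bin fixture."""
    cfg = mb.CommunityConfig(
        n_genomes=2,
        n_samples=6,
        genome_length_range=(1_000_000, 1_200_000),
        contig_length_law=mb.ContigLengthLaw(mu_log=9.2, sigma_log=0.6, min_length=7500),
        dispersion=0.5,
        seed=5,
    )
    return mb.simulate_community(cfg)
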