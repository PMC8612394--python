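"""LD clumping: R^2, planted-partition recovery, representative optimality."""

import itertools

import numpy as np
import pytest

from episcan.clump import (
    bonferroni_threshold,
    cluster_gene,
    genotype_r2,
    select_representatives,
)
from episcan.scan import InteractionResult
from episcan.simulate import GeneSpec, SimulationConfig, simulate_genotypes


class TestGenotypeR2:
    def test_identical_columns(self, rng):
        g = rng.integers(0, 3, 200).astype(float)
        assert genotype_r2(g, g) == pytest.approx(1.0)

    def test_perfect_negative(self, rng):
        g = rng.integers(0, 3, 200).astype(float)
        assert genotype_r2(g, 2 - g) == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        assert np.isnan(genotype_r2(np.zeros(10), np.arange(10.0)))

    def test_independent_snps_near_zero(self):
        cfg = SimulationConfig(
            n_individuals=10_000,
            genes=[GeneSpec(label="G", mafs=[0.3] * 20)],
            seed=17,
        )
        g = simulate_genotypes(cfg).genotypes
        r2s = [genotype_r2(g[:, i], g[:, j]) for i, j in itertools.combinations(range(20), 2)]
        assert np.mean(np.array(r2s) < 0.01) >= 0.99


def _planted_geno(seed=23, n=3000):
    """63-SNP gene in 8 planted blocks (within R^2 0.8, across 0) + 8-SNP gene."""
    sizes = [8, 8, 8, 8, 8, 8, 8, 7]
    blocks, start = [], 0
    for s in sizes:
        blocks.append(list(range(start, start + s)))
        start += s
    gene_a = GeneSpec(label="GENEA", mafs=[0.3] * 63, blocks=blocks, block_r2=0.8)
    gene_b = GeneSpec(label="GENEB", mafs=[0.14] * 8, blocks=[list(range(8))], block_r2=0.8)
    cfg = SimulationConfig(n_individuals=n, genes=[gene_a, gene_b], seed=seed)
    return simulate_genotypes(cfg), blocks


def _fake_results(geno, seed=5):
    """Synthetic p12 per cross-gene pair (no model fits needed for clumping)."""
    rng = np.random.default_rng(seed)
    out = []
    for a in sorted(geno.gene_snps("GENEA")):
        for b in sorted(geno.gene_snps("GENEB")):
            out.append(
                InteractionResult(
                    rsid1=a, rsid2=b, p12=float(rng.random()),
                    b12=float(rng.standard_normal()), converged=True,
                )
            )
    return out


class TestClusterGene:
    def test_all_correlated_one_cluster(self):
        cfg = SimulationConfig(
            n_individuals=2000,
            genes=[GeneSpec(label="G", mafs=[0.3] * 5, blocks=[list(range(5))], block_r2=0.9)],
            seed=3,
        )
        geno = simulate_genotypes(cfg)
        clusters = cluster_gene(geno.gene_snps("G"), geno, [], 0.1, "G")
        assert len(clusters) == 1

    def test_all_independent_one_cluster_each(self):
        cfg = SimulationConfig(
            n_individuals=5000, genes=[GeneSpec(label="G", mafs=[0.3] * 6)], seed=4
        )
        geno = simulate_genotypes(cfg)
        clusters = cluster_gene(geno.gene_snps("G"), geno, [], 0.1, "G")
        assert len(clusters) == 6

    def test_planted_partition_recovered(self):
        geno, blocks = _planted_geno()
        results = _fake_results(geno)
        snps_a = geno.gene_snps("GENEA")
        clusters = cluster_gene(snps_a, geno, results, 0.1, "GENEA")
        found = {frozenset(c.members) for c in clusters}
        planted = {frozenset(snps_a[i] for i in b) for b in blocks}
        assert found == planted
        clusters_b = cluster_gene(geno.gene_snps("GENEB"), geno, results, 0.1, "GENEB")
        assert len(clusters_b) == 1

    def test_threshold_monotonicity(self):
        geno, _ = _planted_geno(seed=29, n=1500)
        snps = geno.gene_snps("GENEA")
        counts = [
            len(cluster_gene(snps, geno, [], thr, "GENEA"))
            for thr in (0.05, 0.1, 0.3, 0.6, 0.95)
        ]
        assert counts == sorted(counts)

    def test_clusters_partition_input(self):
        geno, _ = _planted_geno(seed=31, n=1000)
        snps = geno.gene_snps("GENEA")
        clusters = cluster_gene(snps, geno, _fake_results(geno, 7), 0.1, "GENEA")
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(snps)


class TestRepresentatives:
    def test_matches_brute_force_minimum(self):
        geno, blocks = _planted_geno(seed=37, n=2500)
        results = _fake_results(geno, seed=11)
        lookup = {(r.rsid1, r.rsid2): r for r in results}
        snps_a = geno.gene_snps("GENEA")
        clusters_a = cluster_gene(snps_a, geno, results, 0.1, "GENEA")
        clusters_b = cluster_gene(geno.gene_snps("GENEB"), geno, results, 0.1, "GENEB")
        pairset = select_representatives(clusters_a, clusters_b, results)
        assert pairset.n_independent_tests == len(clusters_a) * len(clusters_b) == 8
        assert len(pairset.representatives) == 8
        # brute force: per-cell exhaustive minimum
        for rep in pairset.representatives:
            ca = next(c for c in clusters_a if rep.rsid1 in c.members)
            cb = next(c for c in clusters_b if rep.rsid2 in c.members)
            best = min(
                lookup[(a, b)].p12 for a in ca.members for b in cb.members
            )
            assert rep.p12 == best

    def test_representatives_mutually_independent(self):
        geno, _ = _planted_geno(seed=41, n=2500)
        results = _fake_results(geno, seed=13)
        clusters_a = cluster_gene(geno.gene_snps("GENEA"), geno, results, 0.1, "GENEA")
        clusters_b = cluster_gene(geno.gene_snps("GENEB"), geno, results, 0.1, "GENEB")
        pairset = select_representatives(clusters_a, clusters_b, results)
        snps1 = [r.rsid1 for r in pairset.representatives]
        for a, b in itertools.combinations(snps1, 2):
            assert genotype_r2(geno.column(a), geno.column(b)) < 0.1

    def test_single_cell_takes_global_minimum(self):
        results = [
            InteractionResult(rsid1="a1", rsid2="b1", p12=0.5, converged=True),
            InteractionResult(rsid1="a2", rsid2="b1", p12=0.01, converged=True),
        ]
        from episcan.clump import LDCluster

        ca = [LDCluster(gene="A", seed="a1", members=["a1", "a2"])]
        cb = [LDCluster(gene="B", seed="b1", members=["b1"])]
        ps = select_representatives(ca, cb, results)
        assert len(ps.representatives) == 1
        assert ps.representatives[0].pair == ("a2", "b1")
        assert ps.bonferroni_alpha == 0.05


class TestBonferroni:
    def test_printed_thresholds(self):
        assert bonferroni_threshold(8) == pytest.approx(6.25e-3)
        assert bonferroni_threshold(504) == pytest.approx(9.92e-5, rel=5e-3)
        assert bonferroni_threshold(1) == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)
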