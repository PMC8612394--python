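"""LD clumping of interacting SNP pairs and Bonferroni correction.

SNPs within each gene are grouped into LD clusters (squared Pearson
correlation of additive codes, default threshold R^2 >= 0.1) by a greedy
significance-seeded pass: the seed is the not-yet-assigned SNP appearing
in the most significant remaining pair, and its cluster absorbs every
unassigned gene-mate with R^2(seed, snp) >= threshold.  One
representative pair — the smallest interaction P-value among member
pairs — is kept per (cluster-A, cluster-B) cell, and the Bonferroni
threshold is alpha divided by the number of cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .scan import InteractionResult
from .simulate import GenotypeMatrix

__all__ = [
    "LDCluster",
    "IndependentPairSet",
    "genotype_r2",
    "cluster_gene",
    "select_representatives",
    "bonferroni_threshold",
]


@dataclass
class LDCluster:
    gene: str
    seed: str
    members: list[str]


@dataclass
class IndependentPairSet:
    representatives: list[InteractionResult]
    n_independent_tests: int
    bonferroni_alpha: float
    significant: list[InteractionResult] = field(default_factory=list)
    dropped_cells: list[tuple[str, str]] = field(default_factory=list)


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete individuals.

    Returns NaN (flagged undefined) when either vector is constant over
    the shared non-missing individuals.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a, b = g1[ok], g2[ok]
    if a.size < 2 or np.unique(a).size < 2 or np.unique(b).size < 2:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pair_sort_key(res: InteractionResult) -> tuple:
    return (res.p12, res.rsid1, res.rsid2)


def cluster_gene(
    gene_snps: Sequence[str],
    geno: GenotypeMatrix,
    results: Sequence[InteractionResult],
    r2_threshold: float = 0.1,
    gene_label: str = "",
) -> list[LDCluster]:
    """Greedy significance-seeded LD clustering of one gene's SNPs.

    Pairs are consumed smallest-p12 first (ties by rsid); each pair
    contributes its this-gene SNP as the next seed if still unassigned.
    SNPs appearing in no testable pair are clustered afterwards, seeded
    in rsid order.  Deterministic.
    """
    snps = list(gene_snps)
    if not snps:
        return []
    snp_set = set(snps)
    cols = {s: geno.column(s) for s in snps}
    assigned: set[str] = set()
    clusters: list[LDCluster] = []

    def grow(seed: str) -> None:
        members = [seed]
        assigned.add(seed)
        for s in snps:
            if s in assigned:
                continue
            r2 = genotype_r2(cols[seed], cols[s])
            if not math.isnan(r2) and r2 >= r2_threshold:
                members.append(s)
                assigned.add(s)
        clusters.append(LDCluster(gene=gene_label, seed=seed, members=members))

    testable = sorted(
        (r for r in results if r.testable and not math.isnan(r.p12)),
        key=_pair_sort_key,
    )
    for res in testable:
        for rsid in (res.rsid1, res.rsid2):
            if rsid in snp_set and rsid not in assigned:
                grow(rsid)
    for s in sorted(snp_set - assigned):
        if s not in assigned:
            grow(s)
    return clusters


def select_representatives(
    clustersA: Sequence[LDCluster],
    clustersB: Sequence[LDCluster],
    results: Sequence[InteractionResult],
    alpha: float = 0.05,
) -> IndependentPairSet:
    """One representative pair (minimal p12, ties by rsid) per cluster cell.

    ``n_independent_tests`` is the number of cluster cells; cells with no
    testable pair are dropped from the representative list and recorded.
    """
    lookup: dict[tuple[str, str], InteractionResult] = {}
    for r in results:
        lookup[(r.rsid1, r.rsid2)] = r
        lookup[(r.rsid2, r.rsid1)] = r
    reps: list[InteractionResult] = []
    dropped: list[tuple[str, str]] = []
    for ca in clustersA:
        for cb in clustersB:
            candidates = [
                lookup[(a, b)]
                for a in ca.members
                for b in cb.members
                if (a, b) in lookup
                and lookup[(a, b)].testable
                and not math.isnan(lookup[(a, b)].p12)
            ]
            if not candidates:
                dropped.append((ca.seed, cb.seed))
                continue
            reps.append(min(candidates, key=_pair_sort_key))
    n_tests = len(clustersA) * len(clustersB)
    thr = bonferroni_threshold(n_tests, alpha)
    reps.sort(key=_pair_sort_key)
    return IndependentPairSet(
        representatives=reps,
        n_independent_tests=n_tests,
        bonferroni_alpha=thr,
        significant=[r for r in reps if r.p12 <= thr],
        dropped_cells=dropped,
    )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
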