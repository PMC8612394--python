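"""Genotype quality control with two-protocol union retention.

Two independently configured filter protocols are applied to the same
input snapshot; individuals and SNPs passing EITHER protocol remain.
The union rule deliberately enlarges the analysis set relative to a
single protocol, which is the point: the analysis trades a slightly
laxer QC for sample size.

Filters are computed on the pre-filter snapshot and applied jointly
(single pass, no iterative re-estimation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .simulate import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "snp_stats",
    "individual_filters",
    "snp_filters",
    "union_qc",
]


@dataclass
class QCThresholds:
    """One QC protocol's cutoffs.

    Defaults: drop individuals with > 5% missing calls, heterozygosity
    outside mean +/- 3 SD, or any PC outside mean +/- 8 SD; drop SNPs
    with MAF < 1%, call rate < 95%, or HWE exact P < 1e-7.
    """

    ind_missing_max: float = 0.05
    het_outlier_sd: float = 3.0
    ancestry_outlier_sd: float = 8.0
    maf_min: float = 0.01
    snp_missing_max: float = 0.05
    hwe_p_min: float = 1.0e-7

    def __post_init__(self) -> None:
        for name in ("ind_missing_max", "maf_min", "snp_missing_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.het_outlier_sd <= 0 or self.ancestry_outlier_sd <= 0:
            raise ValueError("SD multipliers must be > 0")
        if not (0.0 < self.hwe_p_min < 1.0):
            raise ValueError("hwe_p_min must be in (0, 1)")


@dataclass
class QCReport:
    n_input_individuals: int
    n_input_snps: int
    kept_individuals: list[str]
    kept_snps: list[str]
    removal_counts: dict = field(default_factory=dict)
    snp_table: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "n_input_individuals": self.n_input_individuals,
            "n_input_snps": self.n_input_snps,
            "n_kept_individuals": len(self.kept_individuals),
            "n_kept_snps": len(self.kept_snps),
            "removal_counts": self.removal_counts,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test P-value.

    Conditions on the allele counts and sums, over all heterozygote counts
    with the observed parity, the probabilities of tables no more probable
    than the observed one.  Monomorphic tables return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_A, n_a)
    if n_minor == 0:
        return 1.0
    # log P(het = h | n, n_A) up to the shared normalizer:
    #   C(n; hom1, h, hom2) * 2^h / C(2n, n_A)
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    logp = (
        hs * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(hs + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hs == n_Aa][0]
    return float(min(p[p <= obs * (1 + 1e-12)].sum(), 1.0))


def snp_stats(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP minor allele frequency, call rate, and HWE exact P.

    MAF folds the allele frequency over non-missing calls to min(p, 1-p).
    A SNP with no non-missing calls gets NaN MAF / HWE P and call rate 0.
    """
    if geno.n_snps == 0 or geno.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    g = geno.genotypes
    obs = ~np.isnan(g)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(g, axis=0) / (2.0 * n_obs)
    maf = np.minimum(freq, 1.0 - freq)
    call_rate = n_obs / geno.n_individuals
    hwe = np.empty(geno.n_snps)
    for j in range(geno.n_snps):
        if n_obs[j] == 0:
            hwe[j] = np.nan
            continue
        col = g[obs[:, j], j]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        hwe[j] = hwe_exact_test(n2, n1, n0)
    maf = np.where(n_obs == 0, np.nan, maf)
    return pd.DataFrame(
        {"rsid": geno.rsids, "maf": maf, "call_rate": call_rate, "hwe_p": hwe}
    )


def individual_filters(
    geno: GenotypeMatrix, pcs: pd.DataFrame | None, thresholds: QCThresholds
) -> list[str]:
    """Individuals surviving missingness, heterozygosity, ancestry and
    duplicate checks.  The sex-mismatch check is a no-op stub: it needs
    sex-chromosome data, which this pipeline does not model; a
    reported-vs-genetic-sex table can be screened upstream if available.
    """
    g = geno.genotypes
    obs = ~np.isnan(g)
    n_snps = geno.n_snps
    miss_rate = 1.0 - obs.sum(axis=1) / n_snps
    keep = miss_rate <= thresholds.ind_missing_max

    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_obs > 0, (g == 1).sum(axis=1) / np.maximum(n_obs, 1), np.nan)
    mu, sd = np.nanmean(het), np.nanstd(het)
    if sd > 0:
        keep &= np.abs(het - mu) <= thresholds.het_outlier_sd * sd

    if pcs is not None:
        pc_cols = [c for c in pcs.columns if c.upper().startswith("PC")]
        pc = pcs.loc[geno.individual_ids, pc_cols].to_numpy(dtype=float)
        mu_pc = pc.mean(axis=0)
        sd_pc = pc.std(axis=0)
        ok = np.ones(len(pc), dtype=bool)
        for k in range(pc.shape[1]):
            if sd_pc[k] > 0:
                ok &= np.abs(pc[:, k] - mu_pc[k]) <= thresholds.ancestry_outlier_sd * sd_pc[k]
        keep &= ok

    # duplicate genotype vectors (NaN-equal) -> keep first occurrence
    seen: dict[bytes, int] = {}
    for i in range(geno.n_individuals):
        key = np.nan_to_num(g[i], nan=-1.0).tobytes()
        if key in seen:
            keep[i] = False
        else:
            seen[key] = i
    return [iid for iid, k in zip(geno.individual_ids, keep) if k]


def snp_filters(stats_df: pd.DataFrame, thresholds: QCThresholds) -> list[str]:
    """SNPs surviving MAF, call-rate and HWE filters (NaN stats fail)."""
    maf_ok = stats_df["maf"] >= thresholds.maf_min
    call_ok = stats_df["call_rate"] >= 1.0 - thresholds.snp_missing_max
    hwe_ok = stats_df["hwe_p"] >= thresholds.hwe_p_min
    keep = maf_ok.fillna(False) & call_ok & hwe_ok.fillna(False)
    return list(stats_df.loc[keep, "rsid"])


def union_qc(
    geno: GenotypeMatrix,
    pcs: pd.DataFrame | None,
    protoA: QCThresholds,
    protoB: QCThresholds,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply two protocols to the same snapshot; keep the union of survivors,
    for individuals and SNPs independently."""
    stats_df = snp_stats(geno)
    kept_parts = {}
    for name, thr in (("A", protoA), ("B", protoB)):
        kept_parts[name] = {
            "individuals": set(individual_filters(geno, pcs, thr)),
            "snps": set(snp_filters(stats_df, thr)),
        }
    kept_ind = kept_parts["A"]["individuals"] | kept_parts["B"]["individuals"]
    kept_snp = kept_parts["A"]["snps"] | kept_parts["B"]["snps"]
    # preserve input order
    kept_ind_list = [i for i in geno.individual_ids if i in kept_ind]
    kept_snp_list = [r for r in geno.rsids if r in kept_snp]

    out = geno.subset_individuals(
        [iid in kept_ind for iid in geno.individual_ids]
    ).subset_snps(kept_snp_list)
    report = QCReport(
        n_input_individuals=geno.n_individuals,
        n_input_snps=geno.n_snps,
        kept_individuals=kept_ind_list,
        kept_snps=kept_snp_list,
        removal_counts={
            "individuals_removed": geno.n_individuals - len(kept_ind_list),
            "snps_removed": geno.n_snps - len(kept_snp_list),
            "protocol_A": {
                "individuals_failed": geno.n_individuals
                - len(kept_parts["A"]["individuals"]),
                "snps_failed": geno.n_snps - len(kept_parts["A"]["snps"]),
            },
            "protocol_B": {
                "individuals_failed": geno.n_individuals
                - len(kept_parts["B"]["individuals"]),
                "snps_failed": geno.n_snps - len(kept_parts["B"]["snps"]),
            },
        },
        snp_table=stats_df,
    )
    return out, report
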