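"""Synthetic genotype / covariate / survival-trait generator.

Emulates a two-gene candidate study of late-life survival: a large gene
(by default 63 SNPs on chromosome 15) and a small gene (8 SNPs on
chromosome 12), block-structured linkage disequilibrium within each gene,
main-effect-free SNPs carrying a cross-gene interaction effect on the
log-odds of surviving to age 85+, and the usual epidemiological
covariates (education, smoking, sex, five genotype principal components).

Genotypes are produced by a latent-Gaussian threshold model: each
haplotype carries one standard-normal latent value per SNP, the minor
allele is present when the latent value falls below the MAF quantile, and
a genotype is the sum of two independent haplotypes.  The latent
correlation within an LD block is calibrated numerically (monotone
bisection on the bivariate-normal orthant probability) so that the
realized genotype R^2 matches the requested target; see
:func:`latent_rho_for_target_r2`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "GeneSpec",
    "CovariateSpec",
    "TraitModel",
    "SimulationConfig",
    "GenotypeMatrix",
    "PhenotypeRecord",
    "ConfigError",
    "max_attainable_r2",
    "latent_rho_for_target_r2",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_trait",
    "default_config",
    "write_truth_sidecar",
]

# Substream tags: one independent generator per stage so that, e.g.,
# changing the missingness rate does not perturb the trait draw.
_STAGE_GENO = 0
_STAGE_MISSING = 1
_STAGE_COVAR = 2
_STAGE_TRAIT = 3

_ALLELE_CYCLE = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T")]


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid or unattainable."""


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), stage)))


@dataclass
class GeneSpec:
    """One gene: target MAF per SNP and an LD block partition.

    ``blocks`` partitions ``range(len(mafs))``; ``block_r2`` is the target
    pairwise genotype R^2 inside each block (scalar, or one value per
    block).  Across blocks the latent values are independent, so genotype
    R^2 converges to 0.
    """

    label: str
    mafs: Sequence[float]
    blocks: Sequence[Sequence[int]] | None = None
    block_r2: float | Sequence[float] = 0.0
    chromosome: str = "1"
    position_start: int = 1_000_000
    position_step: int = 500
    rsids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.mafs)
        if n == 0:
            raise ConfigError(f"gene {self.label!r} has no SNPs")
        for m in self.mafs:
            if not (0.0 < m <= 0.5):
                raise ConfigError(
                    f"gene {self.label!r}: MAF {m} outside (0, 0.5]"
                )
        if self.blocks is None:
            self.blocks = [[i] for i in range(n)]
        flat = sorted(i for b in self.blocks for i in b)
        if flat != list(range(n)):
            raise ConfigError(
                f"gene {self.label!r}: blocks must partition the {n} SNPs exactly once"
            )
        r2s = self.block_r2_list()
        for r2 in r2s:
            if not (0.0 <= r2 <= 1.0):
                raise ConfigError(f"gene {self.label!r}: block R^2 {r2} outside [0, 1]")
        if self.rsids is not None and len(self.rsids) != n:
            raise ConfigError(f"gene {self.label!r}: rsids length != number of SNPs")

    def block_r2_list(self) -> list[float]:
        if np.isscalar(self.block_r2):
            return [float(self.block_r2)] * len(self.blocks)
        out = list(map(float, self.block_r2))  # type: ignore[arg-type]
        if len(out) != len(self.blocks):
            raise ConfigError(
                f"gene {self.label!r}: need one block_r2 per block ({len(self.blocks)})"
            )
        return out

    @property
    def n_snps(self) -> int:
        return len(self.mafs)


@dataclass
class CovariateSpec:
    """Bernoulli prevalences for the binary covariates plus five iid N(0,1) PCs."""

    education_prevalence: float = 0.94
    smoking_prevalence: float = 0.565
    prop_female: float = 0.569
    n_pcs: int = 5

    def __post_init__(self) -> None:
        for name in ("education_prevalence", "smoking_prevalence", "prop_female"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} {v} outside [0, 1]")
        if self.n_pcs < 0:
            raise ConfigError("n_pcs must be >= 0")

    def names(self) -> list[str]:
        return ["education", "smoking", "sex"] + [f"PC{i + 1}" for i in range(self.n_pcs)]


@dataclass
class TraitModel:
    """Logistic model generating the case indicator.

    logit P(case) = intercept + sum(main_effects * g)
                  + sum(interaction_effects * g_a * g_b)
                  + sum(covariate_effects * x)
    """

    intercept: float = 0.0
    main_effects: Mapping[str, float] = field(default_factory=dict)
    interaction_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_individuals: int
    genes: Sequence[GeneSpec]
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    trait_model: TraitModel = field(default_factory=TraitModel)
    missing_rate: float = 0.0
    exclusion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.exclusion_rate < 1.0):
            raise ConfigError("exclusion_rate must be in [0, 1)")
        labels = [g.label for g in self.genes]
        if len(set(labels)) != len(labels):
            raise ConfigError("gene labels must be unique")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive minor-allele counts (NaN = missing).

    ``snp_meta`` carries rsid, gene label, chromosome, 1-based position,
    effect / non-effect alleles and the minor allele, one row per SNP in
    column order of ``genotypes``.
    """

    genotypes: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x SNPs)")
        n_ind, n_snp = self.genotypes.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length mismatch")
        if len(self.snp_meta) != n_snp:
            raise ValueError("snp_meta length mismatch")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing genotypes must be in {0, 1, 2}")
        if self.snp_meta["rsid"].duplicated().any():
            raise ValueError("duplicate SNP identifiers")
        if len(set(self.individual_ids)) != n_ind:
            raise ValueError("duplicate individual identifiers")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def rsids(self) -> list[str]:
        return list(self.snp_meta["rsid"])

    def column(self, rsid: str) -> np.ndarray:
        idx = self.snp_meta.index[self.snp_meta["rsid"] == rsid]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP {rsid!r}")
        return self.genotypes[:, idx[0]]

    def gene_snps(self, gene: str) -> list[str]:
        return list(self.snp_meta.loc[self.snp_meta["gene"] == gene, "rsid"])

    def subset_individuals(self, keep: Sequence[bool] | Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            self.genotypes[idx],
            self.snp_meta.copy(),
            [self.individual_ids[i] for i in idx],
        )

    def subset_snps(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        pos = {r: i for i, r in enumerate(self.snp_meta["rsid"])}
        idx = [pos[r] for r in rsids]
        return GenotypeMatrix(
            self.genotypes[:, idx],
            self.snp_meta.iloc[idx].reset_index(drop=True),
            list(self.individual_ids),
        )


@dataclass
class PhenotypeRecord:
    individual_id: str
    lifespan_or_last_age: float
    died: bool

    def __post_init__(self) -> None:
        if self.lifespan_or_last_age <= 0:
            raise ValueError("age must be positive")


# ---------------------------------------------------------------------------
# Latent-correlation calibration
# ---------------------------------------------------------------------------

def _bvn_orthant(t1: float, t2: float, rho: float) -> float:
    """P(Z1 < t1, Z2 < t2) for standard bivariate normal with correlation rho."""
    if rho >= 1.0 - 1e-12:
        return float(stats.norm.cdf(min(t1, t2)))
    if rho <= -1.0 + 1e-12:
        return float(max(stats.norm.cdf(t1) + stats.norm.cdf(t2) - 1.0, 0.0))
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    return float(mvn.cdf([t1, t2]))


def max_attainable_r2(maf1: float, maf2: float) -> float:
    """Upper bound on genotype R^2 between two loci of given MAFs.

    With unequal allele frequencies the allele indicators cannot be
    perfectly correlated: max corr = (min(p1,p2) - p1 p2) / sqrt(p1 q1 p2 q2).
    """
    denom = np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))
    r_max = (min(maf1, maf2) - maf1 * maf2) / denom
    return float(min(r_max, 1.0) ** 2)


def latent_rho_for_target_r2(maf1: float, maf2: float, target_r2: float) -> float:
    """Calibrate the latent Gaussian correlation for a target genotype R^2.

    A genotype is the sum of two iid haplotypes, so the genotype
    correlation equals the per-haplotype allele-indicator correlation
    r = sqrt(target_r2).  The allele correlation is monotone increasing in
    the latent rho, so a bisection on rho in [0, 1] solves
    corr(1{Z1<t1}, 1{Z2<t2}) = r.
    """
    if target_r2 == 0.0:
        return 0.0
    r_target = float(np.sqrt(target_r2))
    bound = max_attainable_r2(maf1, maf2)
    if r_target > np.sqrt(bound) + 1e-9:
        raise ConfigError(
            f"target R^2 {target_r2:.4g} unattainable for MAFs "
            f"({maf1:.4g}, {maf2:.4g}); maximum attainable R^2 is {bound:.4g}"
        )
    t1 = float(stats.norm.ppf(maf1))
    t2 = float(stats.norm.ppf(maf2))
    denom = float(np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2)))

    def allele_corr(rho: float) -> float:
        return (_bvn_orthant(t1, t2, rho) - maf1 * maf2) / denom

    if r_target >= allele_corr(1.0) - 1e-12:
        return 1.0
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if allele_corr(mid) < r_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _block_latent_cov(mafs: Sequence[float], target_r2: float) -> np.ndarray:
    """Pairwise-calibrated latent correlation matrix, eigenvalue-clipped to PSD."""
    k = len(mafs)
    sigma = np.eye(k)
    cache: dict[tuple[float, float], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            key = tuple(sorted((mafs[i], mafs[j])))
            if key not in cache:
                cache[key] = latent_rho_for_target_r2(mafs[i], mafs[j], target_r2)
            sigma[i, j] = sigma[j, i] = cache[key]
    w, v = np.linalg.eigh(sigma)
    if w.min() < 0:
        w = np.clip(w, 0.0, None)
        sigma = (v * w) @ v.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    return sigma


def _sample_block(
    rng: np.random.Generator, sigma: np.ndarray, mafs: Sequence[float], n_hap: int
) -> np.ndarray:
    """Draw n_hap haplotypes (0/1 alleles) for one LD block."""
    w, v = np.linalg.eigh(sigma)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    eps = rng.standard_normal((n_hap, len(mafs)))
    latent = eps @ root.T
    thresholds = stats.norm.ppf(np.asarray(mafs, dtype=float))
    return (latent < thresholds).astype(np.int8)


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Generate the genotype matrix described by ``config``.

    Deterministic given ``config.seed``; uses its own substream so other
    stages do not perturb it.  Missing calls (rate ``missing_rate``) are
    missing-completely-at-random.
    """
    rng = _rng(config.seed, _STAGE_GENO)
    n = config.n_individuals
    cols: list[np.ndarray] = []
    meta_rows: list[dict] = []
    allele_i = 0
    for gene in config.genes:
        r2s = gene.block_r2_list()
        geno_gene = np.empty((n, gene.n_snps), dtype=float)
        for block, r2 in zip(gene.blocks, r2s):
            mafs = [gene.mafs[i] for i in block]
            sigma = _block_latent_cov(mafs, r2)
            hap = _sample_block(rng, sigma, mafs, 2 * n)
            geno_gene[:, list(block)] = (hap[:n] + hap[n:]).astype(float)
        cols.append(geno_gene)
        for i in range(gene.n_snps):
            ea, nea = _ALLELE_CYCLE[allele_i % len(_ALLELE_CYCLE)]
            allele_i += 1
            rsid = (
                gene.rsids[i]
                if gene.rsids is not None
                else f"rs{gene.label}{i + 1:04d}"
            )
            meta_rows.append(
                {
                    "rsid": rsid,
                    "gene": gene.label,
                    "chrom": gene.chromosome,
                    "pos": gene.position_start + i * gene.position_step,
                    "effect_allele": ea,
                    "other_allele": nea,
                    "minor_allele": ea,
                }
            )
    genotypes = np.concatenate(cols, axis=1)
    if config.missing_rate > 0:
        mrng = _rng(config.seed, _STAGE_MISSING)
        mask = mrng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = np.nan
    ids = [f"I{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(genotypes, pd.DataFrame(meta_rows), ids)


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Binary covariates (Bernoulli) and iid standard-normal PCs.

    sex is coded 1 = female.  Indexed by individual_id, aligned with
    :func:`simulate_genotypes` for the same config.
    """
    rng = _rng(config.seed, _STAGE_COVAR)
    n = config.n_individuals
    cs = config.covariates
    data = {
        "education": (rng.random(n) < cs.education_prevalence).astype(int),
        "smoking": (rng.random(n) < cs.smoking_prevalence).astype(int),
        "sex": (rng.random(n) < cs.prop_female).astype(int),
    }
    for i in range(cs.n_pcs):
        data[f"PC{i + 1}"] = rng.standard_normal(n)
    ids = [f"I{i + 1:06d}" for i in range(n)]
    return pd.DataFrame(data, index=pd.Index(ids, name="individual_id"))


def trait_linear_predictor(
    geno: GenotypeMatrix, covariates: pd.DataFrame, model: TraitModel
) -> np.ndarray:
    """Log-odds of case status per individual (missing genotypes count 0)."""
    g = np.nan_to_num(geno.genotypes, nan=0.0)
    rsid_pos = {r: i for i, r in enumerate(geno.rsids)}
    eta = np.full(geno.n_individuals, model.intercept, dtype=float)
    for rsid, beta in model.main_effects.items():
        if rsid not in rsid_pos:
            raise ConfigError(f"main effect references unknown SNP {rsid!r}")
        eta += beta * g[:, rsid_pos[rsid]]
    for (a, b), beta in model.interaction_effects.items():
        for rsid in (a, b):
            if rsid not in rsid_pos:
                raise ConfigError(f"interaction effect references unknown SNP {rsid!r}")
        eta += beta * g[:, rsid_pos[a]] * g[:, rsid_pos[b]]
    for name, beta in model.covariate_effects.items():
        if name not in covariates.columns:
            raise ConfigError(f"covariate effect references unknown covariate {name!r}")
        eta += beta * covariates[name].to_numpy(dtype=float)
    return eta


def simulate_trait(
    geno: GenotypeMatrix, covariates: pd.DataFrame, config: SimulationConfig
) -> list[PhenotypeRecord]:
    """Draw case status and assign ages.

    Cases get ages uniform on [85, 95); controls uniform on [75, 85).
    Controls and cases alike may be alive at last follow-up (cases by
    definition already demonstrate survival to 85).  A fraction
    ``exclusion_rate`` of individuals is reassigned an age uniform on
    [65, 75) to exercise downstream exclusion logic.
    """
    if list(covariates.index) != geno.individual_ids:
        raise ValueError("genotypes and covariates are not aligned on individuals")
    rng = _rng(config.seed, _STAGE_TRAIT)
    eta = trait_linear_predictor(geno, covariates, config.trait_model)
    case = rng.random(len(eta)) < expit(eta)
    age = np.where(
        case,
        85.0 + 10.0 * rng.random(len(eta)),
        75.0 + 10.0 * rng.random(len(eta)),
    )
    died = rng.random(len(eta)) < np.where(case, 0.8, 0.5)
    if config.exclusion_rate > 0:
        excl = rng.random(len(eta)) < config.exclusion_rate
        age = np.where(excl, 65.0 + 10.0 * rng.random(len(eta)), age)
    return [
        PhenotypeRecord(iid, float(a), bool(d))
        for iid, a, d in zip(geno.individual_ids, age, died)
    ]


# ---------------------------------------------------------------------------
# Default study-scale fixture
# ---------------------------------------------------------------------------

# SNPs in strong LD share ancestry and hence similar allele frequencies, so
# each default block jitters a base MAF by <= 12%; block bases span 0.02-0.47.
_BLOCK_JITTER = (1.0, 0.92, 0.96, 1.04, 1.08, 0.88, 1.12, 0.98)


def _jittered_block(base: float, size: int) -> list[float]:
    return [
        float(np.clip(round(base * f, 4), 0.02, 0.497))
        for f in _BLOCK_JITTER[:size]
    ]


def _default_mafs_large() -> tuple[list[float], list[list[int]]]:
    """63 SNPs in 8 LD blocks; SNP 1 (the planted interactor) has MAF 0.06."""
    bases = [0.06, 0.025, 0.10, 0.15, 0.21, 0.28, 0.36, 0.45]
    sizes = [8, 8, 8, 8, 8, 8, 8, 7]
    mafs: list[float] = []
    blocks: list[list[int]] = []
    start = 0
    for base, size in zip(bases, sizes):
        mafs.extend(_jittered_block(base, size))
        blocks.append(list(range(start, start + size)))
        start += size
    mafs[0] = 0.06
    return mafs, blocks


def default_config(
    n_individuals: int = 6142,
    seed: int = 0,
    missing_rate: float = 0.002,
    exclusion_rate: float = 0.0,
    interaction_beta: float = 0.60,
) -> SimulationConfig:
    """Study-scale default: 63 + 8 SNPs, two genes, one planted cross-gene
    interaction of log-odds 0.60 between a MAF-0.06 SNP of the large gene
    and a MAF-0.14 SNP of the small gene; no main effects.

    The large gene is partitioned into 8 LD blocks (~8 SNPs each) and the
    small gene is a single block, so clumping at R^2 = 0.1 yields 8 x 1
    independent pairs.  Intercept 0.08 puts the marginal case fraction
    near 2564/6142 given the default covariate effects.
    """
    mafs_a, blocks_a = _default_mafs_large()
    gene_a = GeneSpec(
        label="GENEA",
        mafs=mafs_a,
        blocks=blocks_a,
        block_r2=0.45,
        chromosome="15",
        position_start=39_900_000,
    )
    mafs_b = _jittered_block(0.14, 8)
    gene_b = GeneSpec(
        label="GENEB",
        mafs=mafs_b,
        blocks=[list(range(8))],
        block_r2=0.45,
        chromosome="12",
        position_start=57_500_000,
    )
    trait = TraitModel(
        intercept=0.08,
        main_effects={},
        interaction_effects={("rsGENEA0001", "rsGENEB0001"): interaction_beta},
        covariate_effects={"education": -0.35, "smoking": -0.33, "sex": 0.14},
    )
    return SimulationConfig(
        n_individuals=n_individuals,
        genes=[gene_a, gene_b],
        trait_model=trait,
        missing_rate=missing_rate,
        exclusion_rate=exclusion_rate,
        seed=seed,
    )


def write_truth_sidecar(
    path, config: SimulationConfig, records: list[PhenotypeRecord] | None = None
) -> None:
    """JSON sidecar with the true generative parameters (for recovery tests)."""
    payload = {
        "seed": config.seed,
        "n_individuals": config.n_individuals,
        "missing_rate": config.missing_rate,
        "exclusion_rate": config.exclusion_rate,
        "genes": [
            {
                "label": g.label,
                "mafs": list(map(float, g.mafs)),
                "blocks": [list(map(int, b)) for b in g.blocks],
                "block_r2": g.block_r2_list(),
                "chromosome": g.chromosome,
            }
            for g in config.genes
        ],
        "trait_model": {
            "intercept": config.trait_model.intercept,
            "main_effects": dict(config.trait_model.main_effects),
            "interaction_effects": {
                f"{a}|{b}": v
                for (a, b), v in config.trait_model.interaction_effects.items()
            },
            "covariate_effects": dict(config.trait_model.covariate_effects),
        },
    }
    if records is not None:
        n_case = sum(1 for r in records if r.lifespan_or_last_age >= 85)
        n_excl = sum(1 for r in records if r.lifespan_or_last_age < 75)
        payload["counts"] = {
            "cases": n_case,
            "controls": len(records) - n_case - n_excl,
            "excluded": n_excl,
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
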