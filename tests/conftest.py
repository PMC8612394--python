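import numpy as np
import pandas as pd
import pytest

from episcan.scan import ScanConfig
from episcan.simulate import (
    CovariateSpec,
    GeneSpec,
    SimulationConfig,
    TraitModel,
    simulate_covariates,
    simulate_genotypes,
    simulate_trait,
)
from episcan.trait import SurvivalTraitConfig, build_cohort


def small_config(
    n: int = 1500,
    seed: int = 11,
    beta12: float = 0.6,
    missing_rate: float = 0.0,
) -> SimulationConfig:
    """Two genes (8 + 4 SNPs), two LD blocks in the large gene, one planted
    cross-gene interaction; small enough for fast unit tests."""
    gene_a = GeneSpec(
        label="GENEA",
        mafs=[0.06, 0.055, 0.065, 0.06, 0.25, 0.24, 0.26, 0.25],
        blocks=[[0, 1, 2, 3], [4, 5, 6, 7]],
        block_r2=0.5,
        chromosome="15",
    )
    gene_b = GeneSpec(
        label="GENEB",
        mafs=[0.14, 0.13, 0.15, 0.14],
        blocks=[[0, 1, 2, 3]],
        block_r2=0.5,
        chromosome="12",
    )
    trait = TraitModel(
        intercept=0.0,
        interaction_effects=(
            {("rsGENEA0001", "rsGENEB0001"): beta12} if beta12 else {}
        ),
        covariate_effects={"education": -0.35, "smoking": -0.33, "sex": 0.14},
    )
    return SimulationConfig(
        n_individuals=n,
        genes=[gene_a, gene_b],
        trait_model=trait,
        missing_rate=missing_rate,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated genotypes, covariates, records and labels at n=1500."""
    cfg = small_config()
    geno = simulate_genotypes(cfg)
    covars = simulate_covariates(cfg)
    records = simulate_trait(geno, covars, cfg)
    labels, summary = build_cohort(
        records, SurvivalTraitConfig(), geno.individual_ids, covars
    )
    return {
        "config": cfg,
        "geno": geno,
        "covars": covars,
        "records": records,
        "labels": labels,
        "summary": summary,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def null_cohort(n: int, n_snps: int, seed: int, mafs=None):
    """Independent SNPs, no genetic effects; labels ~ Bernoulli via covariates."""
    if mafs is None:
        mafs = [0.1 + 0.35 * (i % 7) / 6 for i in range(n_snps)]
    cfg = SimulationConfig(
        n_individuals=n,
        genes=[GeneSpec(label="NULL", mafs=mafs)],
        trait_model=TraitModel(
            intercept=-0.3,
            covariate_effects={"education": -0.35, "smoking": -0.33, "sex": 0.14},
        ),
        seed=seed,
    )
    geno = simulate_genotypes(cfg)
    covars = simulate_covariates(cfg)
    records = simulate_trait(geno, covars, cfg)
    labels, _ = build_cohort(records, SurvivalTraitConfig(), geno.individual_ids, covars)
    return geno, covars, labels


def no_covariate_scan_config(**kw) -> ScanConfig:
    return ScanConfig(covariates=(), **kw)


@pytest.fixture(scope="session")
def siprs_null_replicates():
    """SIPRS P-values under the global null, in-sample vs split-sample.

    60 replicates at n=700 with 30 candidate partner SNPs and selection
    threshold 0.2; returns (p_in_sample, p_split_sample, split_aucs).
    """
    from episcan.scan import fixed_snp_scan
    from episcan.siprs import EmptyIndexError, build_index, evaluate_index, split_sample_sweep

    cfg = no_covariate_scan_config(test="wald")
    thr = 0.2
    p_in, p_split, aucs = [], [], []
    for rep in range(60):
        geno, covars, labels = null_cohort(n=700, n_snps=30, seed=9000 + rep)
        fixed = "rsNULL0001"
        results = fixed_snp_scan(geno, fixed, covars, labels, cfg)
        try:
            idx = build_index(results, fixed, thr, geno)
            ev = evaluate_index(idx, labels)
            p_in.append(ev.p_assoc)
        except (EmptyIndexError, ValueError):
            pass
        evs = split_sample_sweep(geno, fixed, labels, None, cfg, grid=[thr], seed=rep)
        if evs[0].n_pairs > 0 and not np.isnan(evs[0].p_assoc):
            p_split.append(evs[0].p_assoc)
            aucs.append(evs[0].auc)
    return np.array(p_in), np.array(p_split), np.array(aucs)
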