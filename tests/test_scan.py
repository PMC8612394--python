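"""Interaction scans: counts, symmetry, degeneracy, test agreement."""

import numpy as np
import pandas as pd
import pytest

from episcan.scan import (
    ScanConfig,
    cross_gene_scan,
    fixed_snp_scan,
    results_to_frame,
    frame_to_results,
    stratify_by_sex,
)
from episcan.scan import test_pair as fit_pair
from episcan.scan import test_single as fit_single

from conftest import no_covariate_scan_config, null_cohort


def _series(geno, rsid):
    return pd.Series(geno.column(rsid), index=geno.individual_ids, name=rsid)


@pytest.fixture(scope="module")
def cohort():
    from conftest import small_config
    from episcan.simulate import simulate_covariates, simulate_genotypes, simulate_trait
    from episcan.trait import SurvivalTraitConfig, build_cohort

    cfg = small_config(n=1200, seed=31)
    geno = simulate_genotypes(cfg)
    covars = simulate_covariates(cfg)
    recs = simulate_trait(geno, covars, cfg)
    labels, _ = build_cohort(recs, SurvivalTraitConfig(), geno.individual_ids, covars)
    return geno, covars, labels


class TestPair:
    def test_symmetry_of_b12_and_p12(self, cohort):
        geno, covars, labels = cohort
        cfg = ScanConfig()
        r_ab = fit_pair(_series(geno, "rsGENEA0001"), _series(geno, "rsGENEB0001"),
                         covars, labels, cfg)
        r_ba = fit_pair(_series(geno, "rsGENEB0001"), _series(geno, "rsGENEA0001"),
                         covars, labels, cfg)
        assert r_ab.b12 == pytest.approx(r_ba.b12, rel=1e-9)
        assert r_ab.p12 == pytest.approx(r_ba.p12, rel=1e-9)

    def test_constant_partner_degenerate(self, cohort):
        geno, covars, labels = cohort
        zero = pd.Series(0.0, index=geno.individual_ids, name="zero")
        res = fit_pair(_series(geno, "rsGENEA0001"), zero, covars, labels, ScanConfig())
        assert not res.testable

    def test_sparse_joint_carriers_guard(self, cohort):
        geno, covars, labels = cohort
        g1 = pd.Series(0.0, index=geno.individual_ids, name="rare1")
        g2 = pd.Series(0.0, index=geno.individual_ids, name="rare2")
        g1.iloc[:3] = 1.0
        g2.iloc[:3] = 1.0
        res = fit_pair(g1, g2, covars, labels, ScanConfig(min_cell=5))
        assert not res.testable and "carriers" in res.reason

    def test_complete_case_rows_counted(self, cohort):
        geno, covars, labels = cohort
        g1 = _series(geno, "rsGENEA0001").copy()
        g1.iloc[:50] = np.nan
        res = fit_pair(g1, _series(geno, "rsGENEB0001"), covars, labels, ScanConfig())
        assert res.n_used == len(labels) - 50

    def test_wald_and_lrt_agree_asymptotically(self):
        geno, covars, labels = null_cohort(n=6142, n_snps=80, seed=101)
        ratios = []
        for k in range(0, 80, 2):
            r_l = fit_pair(_series(geno, f"rsNULL{k+1:04d}"),
                            _series(geno, f"rsNULL{k+2:04d}"),
                            covars, labels, ScanConfig(test="lrt"), p1=1, p2=1)
            r_w = fit_pair(_series(geno, f"rsNULL{k+1:04d}"),
                            _series(geno, f"rsNULL{k+2:04d}"),
                            covars, labels, ScanConfig(test="wald"), p1=1, p2=1)
            if r_l.testable and r_w.testable:
                ratios.append(abs(np.log10(r_l.p12 / r_w.p12)))
        assert np.median(ratios) < 0.1


class TestSingle:
    def test_constant_genotype_flagged(self, cohort):
        geno, covars, labels = cohort
        g = pd.Series(1.0, index=geno.individual_ids, name="const_g")
        p, testable = fit_single(g, covars, labels, ScanConfig())
        assert not testable

    def test_strong_main_effect_detected(self):
        from conftest import small_config
        from episcan.simulate import TraitModel, simulate_covariates, simulate_genotypes, simulate_trait
        from episcan.trait import SurvivalTraitConfig, build_cohort

        hits = 0
        for seed in range(10):
            cfg = small_config(n=6142, seed=500 + seed, beta12=0.0)
            cfg.trait_model = TraitModel(
                intercept=0.0, main_effects={"rsGENEA0005": 1.0}
            )  # MAF 0.25 SNP
            geno = simulate_genotypes(cfg)
            covars = simulate_covariates(cfg)
            recs = simulate_trait(geno, covars, cfg)
            labels, _ = build_cohort(recs, SurvivalTraitConfig(), geno.individual_ids, covars)
            p, ok = fit_single(_series(geno, "rsGENEA0005"), covars, labels, ScanConfig())
            hits += ok and p < 0.05
        assert hits == 10


class TestScans:
    def test_cross_gene_counts(self, cohort):
        geno, covars, labels = cohort
        a = geno.gene_snps("GENEA")
        b = geno.gene_snps("GENEB")
        res = cross_gene_scan(geno, a, b, covars, labels, ScanConfig())
        assert len(res) == len(a) * len(b) == 32
        assert res == sorted(res, key=lambda r: (r.rsid1, r.rsid2))
        res1 = cross_gene_scan(geno, a[:1], b[:1], covars, labels, ScanConfig())
        assert len(res1) == 1
        assert cross_gene_scan(geno, [], b, covars, labels, ScanConfig()) == []

    def test_overlapping_gene_sets_rejected(self, cohort):
        geno, covars, labels = cohort
        with pytest.raises(ValueError):
            cross_gene_scan(geno, ["rsGENEA0001"], ["rsGENEA0001"], covars, labels)

    def test_fixed_snp_scan_count_and_equivalence(self, cohort):
        geno, covars, labels = cohort
        res = fixed_snp_scan(geno, "rsGENEA0001", covars, labels, ScanConfig())
        assert len(res) == geno.n_snps - 1
        direct = fit_pair(
            _series(geno, "rsGENEA0001"), _series(geno, "rsGENEB0002"),
            covars, labels, ScanConfig(),
        )
        match = next(r for r in res if r.rsid2 == "rsGENEB0002")
        assert match.b12 == pytest.approx(direct.b12, rel=1e-12)
        assert match.p12 == pytest.approx(direct.p12, rel=1e-12)

    def test_fixed_snp_absent_raises(self, cohort):
        geno, covars, labels = cohort
        with pytest.raises(KeyError):
            fixed_snp_scan(geno, "rsNOPE", covars, labels)

    def test_sex_stratification_drops_sex_covariate(self, cohort):
        geno, covars, labels = cohort
        cov_f, lab_f, cfg_f = stratify_by_sex(covars, labels, female=True)
        assert "sex" not in cfg_f.covariates
        assert (covars.loc[cov_f.index, "sex"] == 1).all()
        assert len(lab_f) < len(labels)


def test_results_frame_roundtrip(cohort, tmp_path):
    geno, covars, labels = cohort
    res = cross_gene_scan(geno, geno.gene_snps("GENEA")[:2],
                          geno.gene_snps("GENEB")[:2], covars, labels, ScanConfig())
    df = results_to_frame(res)
    path = tmp_path / "res.tsv"
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    back = frame_to_results(pd.read_csv(path, sep="\t", na_values="NA"))
    assert [r.pair for r in back] == [r.pair for r in res]
    np.testing.assert_allclose([r.b12 for r in back], [r.b12 for r in res])
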