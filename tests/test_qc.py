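"""QC: HWE exact test vs enumeration oracle, stats, filters, union rule."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import norm

from episcan.qc import (
    QCThresholds,
    hwe_exact_test,
    individual_filters,
    snp_filters,
    snp_stats,
    union_qc,
)
from episcan.simulate import GenotypeMatrix, SimulationConfig, GeneSpec, simulate_genotypes


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Independent exact-rational enumeration of the conditional HWE test.

    P(het = h | n, allele counts) = C(n; hom1, h, hom2) 2^h / C(2n, nA),
    computed with exact integer combinatorics.
    """
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_minor = min(n_A, 2 * n - n_A)
    if n_minor == 0:
        return 1.0
    denom = comb(2 * n, n_A, exact=True)
    probs = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        num = (
            comb(n, hom_minor, exact=True)
            * comb(n - hom_minor, h, exact=True)
            * 2**h
        )
        probs[h] = Fraction(num, denom)
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


def _geno(matrix, rsids=None, gene="G"):
    matrix = np.asarray(matrix, dtype=float)
    n_ind, n_snp = matrix.shape
    rsids = rsids or [f"rs{i}" for i in range(n_snp)]
    meta = pd.DataFrame(
        {
            "rsid": rsids,
            "gene": gene,
            "chrom": "1",
            "pos": np.arange(n_snp) + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "minor_allele": "A",
        }
    )
    return GenotypeMatrix(matrix, meta, [f"I{i}" for i in range(n_ind)])


class TestHWE:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_modal_het_count_is_one(self):
        # (5, 10, 5): nA = 20 of 40, modal heterozygote count -> P = 1
        assert hwe_exact_test(5, 10, 5) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", [(5, 10, 5), (20, 2, 3), (0, 1, 24), (7, 0, 7), (1, 1, 1)]
    )
    def test_matches_enumeration_oracle(self, table):
        assert hwe_exact_test(*table) == pytest.approx(hwe_oracle(*table), rel=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestSnpStats:
    def test_all_zero_column(self):
        st = snp_stats(_geno([[0], [0], [0]]))
        assert st.loc[0, "maf"] == 0.0
        assert st.loc[0, "call_rate"] == 1.0

    def test_012_column_maf_half(self):
        st = snp_stats(_geno([[0], [1], [2]]))
        assert st.loc[0, "maf"] == pytest.approx(0.5)

    def test_simulated_maf_recovered(self):
        cfg = SimulationConfig(
            n_individuals=10_000, genes=[GeneSpec(label="G", mafs=[0.06])], seed=8
        )
        st = snp_stats(simulate_genotypes(cfg))
        half = norm.ppf(0.995) * np.sqrt(0.06 * 0.94 / 20_000)
        assert abs(st.loc[0, "maf"] - 0.06) < half

    def test_all_missing_column_flagged(self):
        st = snp_stats(_geno([[np.nan, 0], [np.nan, 1]]))
        assert np.isnan(st.loc[0, "maf"]) and st.loc[0, "call_rate"] == 0.0


class TestIndividualFilters:
    def test_clean_sample_all_kept(self, rng):
        g = _geno(rng.integers(0, 3, size=(30, 40)))
        kept = individual_filters(g, None, QCThresholds())
        assert len(kept) == 30

    def test_high_missingness_dropped(self, rng):
        m = rng.integers(0, 3, size=(20, 40)).astype(float)
        m[0, :4] = np.nan  # 10% missing > 5% threshold
        kept = individual_filters(_geno(m), None, QCThresholds(het_outlier_sd=50))
        assert "I0" not in kept and len(kept) == 19

    def test_duplicate_keeps_first(self, rng):
        m = rng.integers(0, 3, size=(10, 30)).astype(float)
        m[7] = m[2]
        kept = individual_filters(_geno(m), None, QCThresholds(het_outlier_sd=50))
        assert "I2" in kept and "I7" not in kept

    def test_ancestry_outlier_dropped(self, rng):
        # a lone outlier's z-score is bounded by (n-1)/sqrt(n), so the
        # 8-SD rule needs n well above 65 to be able to fire
        m = rng.integers(0, 3, size=(200, 30)).astype(float)
        pcs = pd.DataFrame(
            {"PC1": rng.standard_normal(200)}, index=[f"I{i}" for i in range(200)]
        )
        pcs.iloc[0, 0] = 1000.0
        kept = individual_filters(_geno(m), pcs, QCThresholds(het_outlier_sd=50))
        assert "I0" not in kept


class TestUnionQC:
    def test_identical_protocols_idempotent(self, rng):
        g = _geno(rng.integers(0, 3, size=(40, 20)))
        thr = QCThresholds()
        out, rep = union_qc(g, None, thr, thr)
        st = snp_stats(g)
        assert set(rep.kept_snps) == set(snp_filters(st, thr))

    def test_permissive_protocol_absorbs(self, rng):
        g = _geno(rng.integers(0, 3, size=(40, 20)))
        strict = QCThresholds(maf_min=0.49)
        lax = QCThresholds(maf_min=0.0, hwe_p_min=1e-300, het_outlier_sd=100)
        out, rep = union_qc(g, None, strict, lax)
        assert len(rep.kept_snps) == 20
        assert len(rep.kept_individuals) == 40

    def test_union_rescues_snp_failing_one_protocol(self, rng):
        # column 0 has MAF ~0.03: fails A (maf_min 5%) but passes B (1%)
        n = 400
        col0 = (rng.random(n) < 0.03).astype(float) + (rng.random(n) < 0.03)
        rest = rng.integers(0, 3, size=(n, 5)).astype(float)
        g = _geno(np.column_stack([col0, rest]))
        protoA = QCThresholds(maf_min=0.05)
        protoB = QCThresholds(maf_min=0.01)
        _, rep = union_qc(g, None, protoA, protoB)
        st = snp_stats(g)
        assert "rs0" not in snp_filters(st, protoA)
        assert "rs0" in rep.kept_snps

    def test_union_superset_of_each_protocol(self, rng):
        m = rng.integers(0, 3, size=(60, 25)).astype(float)
        m[rng.random(m.shape) < 0.03] = np.nan
        g = _geno(m)
        a = QCThresholds(maf_min=0.2)
        b = QCThresholds(ind_missing_max=0.01)
        _, rep = union_qc(g, None, a, b)
        st = snp_stats(g)
        for thr in (a, b):
            assert set(snp_filters(st, thr)) <= set(rep.kept_snps)
            assert set(individual_filters(g, None, thr)) <= set(rep.kept_individuals)
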