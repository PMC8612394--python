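"""Per-pair logistic interaction scans.

For a SNP pair (g1, g2) the model is

    logit P(case) = b0 + b1 g1 + b2 g2 + b12 (g1 * g2) + gamma' covariates

with additive minor-allele coding; the interaction coefficient b12 is the
quantity of interest, tested by a 1-df likelihood-ratio test (Wald
optional).  Marginal per-SNP P-values come from separate single-SNP
models, matching a standalone single-locus analysis.

Two scan designs: the cross-gene candidate scan (all pairs between two
disjoint SNP sets) and the fixed-SNP scan (one SNP against every other
SNP, its main effect always in the model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .logistic import RankDeficientError, fit_logistic, lrt_pvalue
from .simulate import GenotypeMatrix

__all__ = [
    "ScanConfig",
    "InteractionResult",
    "test_single",
    "test_pair",
    "cross_gene_scan",
    "fixed_snp_scan",
    "results_to_frame",
    "stratify_by_sex",
]

DEFAULT_COVARIATES = ("education", "smoking", "sex", "PC1", "PC2", "PC3", "PC4", "PC5")


@dataclass
class ScanConfig:
    covariates: Sequence[str] = DEFAULT_COVARIATES
    test: str = "lrt"  # "lrt" | "wald"
    min_cell: int = 5  # minimum number of joint minor-allele carriers
    fixed_snp: str | None = None

    def __post_init__(self) -> None:
        if self.test not in ("lrt", "wald"):
            raise ValueError("test must be 'lrt' or 'wald'")


@dataclass
class InteractionResult:
    rsid1: str
    rsid2: str
    b12: float = np.nan
    se12: float = np.nan
    p12: float = np.nan
    p1: float = np.nan
    p2: float = np.nan
    maf1: float = np.nan
    maf2: float = np.nan
    ea_nea1: str = ""
    ea_nea2: str = ""
    minor_allele1: str = ""
    minor_allele2: str = ""
    n_used: int = 0
    converged: bool = False
    testable: bool = True
    reason: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.rsid1, self.rsid2)


def _covariate_matrix(covariates: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in names if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariates not found: {missing}")
    return covariates[list(names)]


def _maf(g: np.ndarray) -> float:
    obs = g[~np.isnan(g)]
    if obs.size == 0:
        return np.nan
    p = obs.sum() / (2 * obs.size)
    return float(min(p, 1.0 - p))


def test_single(
    g: pd.Series,
    covariates: pd.DataFrame,
    labels: pd.Series,
    cfg: ScanConfig | None = None,
) -> tuple[float, bool]:
    """Marginal LRT P-value of one SNP's main effect; (P, testable)."""
    cfg = cfg or ScanConfig()
    cov = _covariate_matrix(covariates, cfg.covariates)
    df = pd.concat([g.rename("g"), cov, labels.rename("y")], axis=1, join="inner")
    df = df.dropna()
    gv = df["g"].to_numpy()
    if np.unique(gv).size < 2:
        return np.nan, False
    y = df["y"].to_numpy()
    Xcov = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in cfg.covariates])
    X = np.column_stack([Xcov, gv])
    names = ["const", *cfg.covariates, "g"]
    try:
        full = fit_logistic(X, y, names)
        red = fit_logistic(Xcov, y, names[:-1])
    except RankDeficientError:
        return np.nan, False
    if not (full.converged and red.converged):
        return np.nan, False
    return lrt_pvalue(full.llf, red.llf), True


def test_pair(
    g1: pd.Series,
    g2: pd.Series,
    covariates: pd.DataFrame,
    labels: pd.Series,
    cfg: ScanConfig | None = None,
    p1: float | None = None,
    p2: float | None = None,
) -> InteractionResult:
    """Fit the interaction model for one SNP pair.

    ``g1``/``g2`` are Series of additive codes named by rsid and indexed
    by individual_id.  Rows with a missing genotype, covariate, or label
    are dropped (complete-case per pair).  Pass precomputed marginal
    P-values ``p1``/``p2`` to avoid refitting single-SNP models in scans.
    """
    cfg = cfg or ScanConfig()
    rsid1 = str(g1.name)
    rsid2 = str(g2.name)
    res = InteractionResult(rsid1=rsid1, rsid2=rsid2)
    cov = _covariate_matrix(covariates, cfg.covariates)
    df = pd.concat(
        [g1.rename("g1"), g2.rename("g2"), cov, labels.rename("y")],
        axis=1,
        join="inner",
    ).dropna()
    res.n_used = len(df)
    res.maf1 = _maf(df["g1"].to_numpy())
    res.maf2 = _maf(df["g2"].to_numpy())
    inter = (df["g1"] * df["g2"]).to_numpy()
    if np.unique(inter).size < 2:
        res.testable = False
        res.reason = "interaction term constant"
        return res
    if int((inter > 0).sum()) < cfg.min_cell:
        res.testable = False
        res.reason = f"fewer than {cfg.min_cell} joint minor-allele carriers"
        return res
    y = df["y"].to_numpy()
    base_cols = [np.ones(len(df)), df["g1"].to_numpy(), df["g2"].to_numpy()]
    cov_cols = [df[c].to_numpy() for c in cfg.covariates]
    X_full = np.column_stack(base_cols + [inter] + cov_cols)
    names = ["const", "g1", "g2", "g1:g2", *cfg.covariates]
    try:
        full = fit_logistic(X_full, y, names)
    except RankDeficientError as exc:
        res.testable = False
        res.reason = f"rank deficient: {exc.columns}"
        return res
    res.converged = full.converged
    res.b12 = float(full.beta[3])
    res.se12 = float(full.se()[3])
    if not full.converged:
        res.reason = "non-convergence or separation"
        return res
    if cfg.test == "wald":
        res.p12 = float(full.wald_pvalues()[3])
    else:
        X_red = np.column_stack(base_cols + cov_cols)
        try:
            red = fit_logistic(X_red, y, [n for n in names if n != "g1:g2"])
        except RankDeficientError as exc:
            res.testable = False
            res.reason = f"rank deficient: {exc.columns}"
            return res
        if not red.converged:
            res.converged = False
            res.reason = "reduced model non-convergence"
            return res
        res.p12 = lrt_pvalue(full.llf, red.llf)
    if p1 is None:
        p1, _ = test_single(g1, covariates, labels, cfg)
    if p2 is None:
        p2, _ = test_single(g2, covariates, labels, cfg)
    res.p1 = float(p1) if p1 is not None else np.nan
    res.p2 = float(p2) if p2 is not None else np.nan
    return res


def _series(geno: GenotypeMatrix, rsid: str) -> pd.Series:
    return pd.Series(geno.column(rsid), index=geno.individual_ids, name=rsid)


def _annotate(res: InteractionResult, geno: GenotypeMatrix) -> InteractionResult:
    meta = geno.snp_meta.set_index("rsid")
    for side, rsid in ((1, res.rsid1), (2, res.rsid2)):
        if rsid in meta.index:
            row = meta.loc[rsid]
            setattr(res, f"ea_nea{side}", f"{row['effect_allele']}/{row['other_allele']}")
            setattr(res, f"minor_allele{side}", str(row["minor_allele"]))
    return res


def cross_gene_scan(
    geno: GenotypeMatrix,
    geneA_snps: Sequence[str],
    geneB_snps: Sequence[str],
    covariates: pd.DataFrame,
    labels: pd.Series,
    cfg: ScanConfig | None = None,
) -> list[InteractionResult]:
    """All |A| x |B| cross-gene pairs, sorted by (rsid1, rsid2).

    Marginal single-SNP P-values are fitted once per SNP and shared
    across the pairs that SNP participates in.
    """
    cfg = cfg or ScanConfig()
    overlap = set(geneA_snps) & set(geneB_snps)
    if overlap:
        raise ValueError(f"gene SNP sets overlap: {sorted(overlap)}")
    single: dict[str, float] = {}
    for rsid in list(geneA_snps) + list(geneB_snps):
        single[rsid], _ = test_single(_series(geno, rsid), covariates, labels, cfg)
    out = []
    for a in sorted(geneA_snps):
        ga = _series(geno, a)
        for b in sorted(geneB_snps):
            res = test_pair(
                ga, _series(geno, b), covariates, labels, cfg,
                p1=single[a], p2=single[b],
            )
            out.append(_annotate(res, geno))
    return out


def fixed_snp_scan(
    geno: GenotypeMatrix,
    fixed: str,
    covariates: pd.DataFrame,
    labels: pd.Series,
    cfg: ScanConfig | None = None,
    partner_snps: Sequence[str] | None = None,
) -> list[InteractionResult]:
    """Scan one fixed SNP against every other SNP (its main effect always in
    the model).  Pairwise identical to calling :func:`test_pair` per SNP."""
    cfg = cfg or ScanConfig()
    if fixed not in geno.rsids:
        raise KeyError(f"fixed SNP {fixed!r} not in genotype matrix")
    partners = [r for r in (partner_snps or geno.rsids) if r != fixed]
    gf = _series(geno, fixed)
    p_fixed, _ = test_single(gf, covariates, labels, cfg)
    out = []
    for rsid in partners:
        res = test_pair(
            gf, _series(geno, rsid), covariates, labels, cfg, p1=p_fixed
        )
        out.append(_annotate(res, geno))
    return out


def stratify_by_sex(
    covariates: pd.DataFrame,
    labels: pd.Series,
    female: bool,
    cfg: ScanConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, ScanConfig]:
    """Restrict to one sex and drop sex from the covariate list."""
    cfg = cfg or ScanConfig()
    keep = covariates.index[covariates["sex"] == (1 if female else 0)]
    keep = keep.intersection(labels.index)
    new_cfg = replace(cfg, covariates=tuple(c for c in cfg.covariates if c != "sex"))
    return covariates.loc[keep], labels.loc[keep], new_cfg


_FRAME_COLS = [
    "rsid1", "ea_nea1", "minor_allele1", "p1", "maf1",
    "rsid2", "ea_nea2", "minor_allele2", "p2", "maf2",
    "b12", "se12", "p12", "n_used", "converged", "testable",
]


def results_to_frame(results: Sequence[InteractionResult]) -> pd.DataFrame:
    """Tabulate scan results (per-pair summary-statistics table schema)."""
    return pd.DataFrame([{c: getattr(r, c) for c in _FRAME_COLS} for r in results])


def frame_to_results(df: pd.DataFrame) -> list[InteractionResult]:
    str_cols = {"rsid1", "rsid2", "ea_nea1", "ea_nea2", "minor_allele1", "minor_allele2"}
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _FRAME_COLS if c in df.columns}
        for c in str_cols & kwargs.keys():
            kwargs[c] = "" if pd.isna(kwargs[c]) else str(kwargs[c])
        kwargs["converged"] = bool(kwargs.get("converged", False))
        kwargs["testable"] = bool(kwargs.get("testable", True))
        kwargs["n_used"] = int(kwargs.get("n_used", 0))
        out.append(InteractionResult(**kwargs))
    return out
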