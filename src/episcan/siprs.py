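"""SNP-specific Interaction Polygenic Risk Scores (SIPRS).

A SIPRS aggregates, for one fixed SNP, all partner SNPs whose
interaction P-value in a fixed-SNP scan does not exceed a threshold.
Two weightings of the per-individual score are offered:

* ``beta`` (default): sum_k b12_k * g_fixed * g_k — the direct
  interaction analogue of a weighted polygenic risk score, keeping the
  sign of each association;
* ``count``: the number of included pairs for which the individual
  carries minor alleles at both loci (a "genetic dose" count).

Scores are standardized to mean 0, SD 1 before evaluation.  Evaluation
regresses the case/control label on the score plus covariates, reporting
the likelihood-ratio P of the score term, the Nagelkerke pseudo-R^2
increment of the score over the covariate-only model, and the AUC of the
score-bearing model with a DeLong 95% CI.

Evaluating a score on the same individuals used to select its pairs is
anti-conservative under the null (winner's curse); ``split_sample_sweep``
scans on one half of the cohort and evaluates on the held-out half,
restoring calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .logistic import fit_logistic, lrt_pvalue
from .scan import InteractionResult, ScanConfig, fixed_snp_scan
from .simulate import GenotypeMatrix

__all__ = [
    "SIPRSIndex",
    "SIPRSEvaluation",
    "EmptyIndexError",
    "DEFAULT_GRID",
    "build_index",
    "evaluate_index",
    "threshold_sweep",
    "split_sample_sweep",
    "delong_auc_ci",
]

# Nine-point threshold grid; includes every cutoff the sweep table prints.
DEFAULT_GRID = (5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 2e-2, 3e-2, 5e-2)


class EmptyIndexError(ValueError):
    def __init__(self, threshold: float, min_passing: float):
        self.threshold = threshold
        self.min_passing = min_passing
        super().__init__(
            f"no pair passes threshold {threshold:g}; "
            f"smallest passing threshold is {min_passing:g}"
        )


@dataclass
class SIPRSIndex:
    fixed_snp: str
    threshold: float
    pairs: list[tuple[str, float, float]]  # (partner rsid, b12, p12), p12 ascending
    scores: pd.Series
    weighting: str = "beta"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class SIPRSEvaluation:
    threshold: float
    n_pairs: int
    p_assoc: float = np.nan
    r2: float = np.nan
    auc: float = np.nan
    auc_ci95: tuple[float, float] = (np.nan, np.nan)


def build_index(
    results: Sequence[InteractionResult],
    fixed_snp: str,
    threshold: float,
    geno: GenotypeMatrix,
    weighting: str = "beta",
) -> SIPRSIndex:
    """Select pairs at ``p12 <= threshold`` and compute per-individual scores.

    Missing genotypes contribute 0 to the sum.  The returned scores are
    standardized over the cohort (mean 0, SD 1).
    """
    if weighting not in ("beta", "count"):
        raise ValueError("weighting must be 'beta' or 'count'")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    usable = [
        r
        for r in results
        if r.testable and r.converged and not math.isnan(r.p12)
    ]
    included = sorted(
        (r for r in usable if r.p12 <= threshold),
        key=lambda r: (r.p12, r.rsid1, r.rsid2),
    )
    if not included:
        min_passing = min((r.p12 for r in usable), default=np.nan)
        raise EmptyIndexError(threshold, min_passing)
    gf = np.nan_to_num(geno.column(fixed_snp), nan=0.0)
    score = np.zeros(geno.n_individuals)
    pairs = []
    for r in included:
        partner = r.rsid2 if r.rsid1 == fixed_snp else r.rsid1
        gp = np.nan_to_num(geno.column(partner), nan=0.0)
        prod = gf * gp
        if weighting == "beta":
            score += r.b12 * prod
        else:
            score += (prod > 0).astype(float)
        pairs.append((partner, r.b12, r.p12))
    sd = score.std()
    if sd == 0:
        raise ValueError("score is constant over the cohort; cannot standardize")
    scores = pd.Series(
        (score - score.mean()) / sd, index=geno.individual_ids, name="siprs"
    )
    return SIPRSIndex(fixed_snp, threshold, pairs, scores, weighting)


def delong_auc_ci(
    labels: np.ndarray, scores: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong confidence interval.

    Uses the midrank formulation of the DeLong structural components;
    the CI is normal-theory on the AUC scale, clipped to [0, 1].
    """
    y = np.asarray(labels, dtype=int)
    x = np.asarray(scores, dtype=float)
    pos = x[y == 1]
    neg = x[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both cases and controls for AUC")
    r_all = rankdata(np.concatenate([pos, neg]))
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # per-case structural component
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # per-control structural component
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    lo, hi = max(auc - half, 0.0), min(auc + half, 1.0)
    return float(auc), (float(lo), float(hi))


def _nagelkerke_increment(ll_null, ll_cov, ll_full, n: int) -> float:
    def nk(ll):
        cs = 1.0 - math.exp(2.0 * (ll_null - ll) / n)
        denom = 1.0 - math.exp(2.0 * ll_null / n)
        return cs / denom if denom > 0 else np.nan

    return nk(ll_full) - nk(ll_cov)


def _mcfadden_increment(ll_null, ll_cov, ll_full, n: int) -> float:
    return (ll_cov - ll_full) / ll_null


def evaluate_index(
    index: SIPRSIndex,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    covariate_names: Sequence[str] | None = None,
    r2_method: str = "nagelkerke",
) -> SIPRSEvaluation:
    """Association of a SIPRS with the survival trait.

    Model: logit P(case) = a + b*score + gamma'*covariates.  ``r2`` is the
    pseudo-R^2 increment of the score over the covariate-only model
    (Nagelkerke by default, McFadden optional); ``auc`` is for the
    score-bearing model's fitted probabilities.
    """
    df = pd.concat([index.scores, labels.rename("y")], axis=1, join="inner")
    names: list[str] = []
    if covariates is not None:
        names = list(covariate_names) if covariate_names else list(covariates.columns)
        df = pd.concat([df, covariates[names]], axis=1, join="inner")
    df = df.dropna()
    if df["siprs"].std() == 0:
        raise ValueError("score is constant over the evaluated individuals")
    y = df["y"].to_numpy()
    n = len(df)
    ones = np.ones(n)
    cov_cols = [df[c].to_numpy() for c in names]
    X_cov = np.column_stack([ones] + cov_cols)
    X_full = np.column_stack([ones, df["siprs"].to_numpy()] + cov_cols)
    fit_null = fit_logistic(ones[:, None], y, ["const"])
    fit_cov = fit_logistic(X_cov, y, ["const", *names])
    fit_full = fit_logistic(X_full, y, ["const", "siprs", *names])
    p_assoc = lrt_pvalue(fit_full.llf, fit_cov.llf)
    inc = _nagelkerke_increment if r2_method == "nagelkerke" else _mcfadden_increment
    r2 = inc(fit_null.llf, fit_cov.llf, fit_full.llf, n)
    from scipy.special import expit

    fitted = expit(X_full @ fit_full.beta)
    auc, ci = delong_auc_ci(y, fitted)
    return SIPRSEvaluation(
        threshold=index.threshold,
        n_pairs=index.n_pairs,
        p_assoc=float(p_assoc),
        r2=float(r2),
        auc=auc,
        auc_ci95=ci,
    )


def threshold_sweep(
    results: Sequence[InteractionResult],
    fixed_snp: str,
    geno: GenotypeMatrix,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    covariate_names: Sequence[str] | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    weighting: str = "beta",
    r2_method: str = "nagelkerke",
) -> list[SIPRSEvaluation]:
    """One evaluation per grid threshold; empty thresholds yield an
    n_pairs=0 row and the sweep continues."""
    if len(grid) == 0:
        raise ValueError("threshold grid must be non-empty")
    out = []
    for thr in grid:
        try:
            idx = build_index(results, fixed_snp, thr, geno, weighting)
        except EmptyIndexError:
            out.append(SIPRSEvaluation(threshold=thr, n_pairs=0))
            continue
        out.append(
            evaluate_index(idx, labels, covariates, covariate_names, r2_method)
        )
    return out


def sweep_to_frame(evals: Sequence[SIPRSEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "threshold": e.threshold,
                "n_pairs": e.n_pairs,
                "r2": e.r2,
                "p_assoc": e.p_assoc,
                "auc": e.auc,
                "auc_lo": e.auc_ci95[0],
                "auc_hi": e.auc_ci95[1],
            }
            for e in evals
        ]
    )


def split_sample_sweep(
    geno: GenotypeMatrix,
    fixed_snp: str,
    labels: pd.Series,
    covariates: pd.DataFrame | None,
    cfg: ScanConfig | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    weighting: str = "beta",
    seed: int = 0,
    partner_snps: Sequence[str] | None = None,
) -> list[SIPRSEvaluation]:
    """Scan on a random half of the cohort, evaluate on the held-out half.

    Removes the selection bias of in-sample evaluation: under the null
    the held-out p_assoc is uniformly distributed.
    """
    cfg = cfg or ScanConfig()
    rng = np.random.default_rng(seed)
    ids = np.array(labels.index)
    rng.shuffle(ids)
    half = len(ids) // 2
    train, test = set(ids[:half]), set(ids[half:])
    mask_train = [i in train for i in geno.individual_ids]
    mask_test = [i in test for i in geno.individual_ids]
    geno_train = geno.subset_individuals(mask_train)
    geno_test = geno.subset_individuals(mask_test)
    cov_train = covariates.loc[covariates.index.isin(train)] if covariates is not None else None
    cov_test = covariates.loc[covariates.index.isin(test)] if covariates is not None else None
    results = fixed_snp_scan(
        geno_train, fixed_snp, cov_train if cov_train is not None else pd.DataFrame(index=list(train)),
        labels.loc[labels.index.isin(train)], cfg, partner_snps=partner_snps,
    )
    out = []
    for thr in grid:
        try:
            idx = build_index(results, fixed_snp, thr, geno_test, weighting)
        except EmptyIndexError:
            out.append(SIPRSEvaluation(threshold=thr, n_pairs=0))
            continue
        try:
            out.append(
                evaluate_index(
                    idx,
                    labels.loc[labels.index.isin(test)],
                    cov_test,
                    list(cfg.covariates) if cov_test is not None else None,
                )
            )
        except ValueError:
            out.append(SIPRSEvaluation(threshold=thr, n_pairs=idx.n_pairs))
    return out


def plot_sweep(evals: Sequence[SIPRSEvaluation], ax=None, title: str = ""):
    """Bar chart of pseudo-R^2 by threshold, annotated with n_pairs and P."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    xs = np.arange(len(evals))
    heights = [0.0 if math.isnan(e.r2) else e.r2 for e in evals]
    ax.bar(xs, heights, color="steelblue")
    ax.set_xticks(xs)
    ax.set_xticklabels([f"{e.threshold:g}" for e in evals], rotation=45)
    for x, e in zip(xs, evals):
        if e.n_pairs:
            ax.annotate(
                f"{e.n_pairs}\n{e.r2:.3f}\n{e.p_assoc:.1e}",
                (x, max(e.r2, 0)),
                ha="center",
                va="bottom",
                fontsize=7,
            )
    ax.set_xlabel("P-value threshold")
    ax.set_ylabel("pseudo-$R^2$ (increment over covariates)")
    if title:
        ax.set_title(title)
    return ax
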