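"""Maximum-likelihood logistic regression by iteratively reweighted least
squares, with likelihood-ratio and Wald tests.

Convergence: max |score| < 1e-8 or relative log-likelihood change
< 1e-10, at most 100 Newton steps (with step-halving when a step would
decrease the likelihood).  Complete separation is flagged, not hidden:
any |coefficient| > 15 marks the fit non-converged and downstream
P-values are set to missing.  The covariance is the inverse observed
information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.special import expit
from scipy.stats import chi2

__all__ = ["LogisticFit", "RankDeficientError", "fit_logistic", "lrt_pvalue"]

_BETA_MAX = 15.0


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"design matrix rank deficient; collinear columns: {columns}")


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    n_obs: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_pvalues(self) -> np.ndarray:
        z = self.beta / self.se()
        return chi2.sf(z**2, df=1)


def _check_rank(X: np.ndarray, names: Sequence[str] | None) -> None:
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [int(piv[i]) for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        raise RankDeficientError([names[j] for j in sorted(bad)])


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    column_names: Sequence[str] | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> LogisticFit:
    """Fit logit P(y=1) = X beta by Newton/IRLS.

    ``X`` must already contain an intercept column if one is wanted; rows
    with missing values must have been dropped by the caller
    (complete-case analysis happens upstream).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D and aligned with y")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("X and y must be complete cases (no NaN)")
    _check_rank(X, column_names)

    n, p = X.shape
    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = linalg.solve(info, score, assume_a="pos")
        except linalg.LinAlgError:
            break
        # step-halving if the likelihood would decrease
        new_beta = beta + step
        new_ll = _loglik(X, y, new_beta)
        halvings = 0
        while new_ll < ll and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(X, y, new_beta)
            halvings += 1
        rel_change = abs(new_ll - ll) / (abs(ll) + 1e-12)
        beta, ll = new_beta, new_ll
        if np.max(np.abs(score)) < score_tol or rel_change < ll_tol:
            converged = True
            break

    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = linalg.inv(info)
    except linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    if np.max(np.abs(beta)) > _BETA_MAX:
        converged = False  # separation guard
    return LogisticFit(beta=beta, cov=cov, llf=ll, converged=converged, n_iter=it, n_obs=n)


def lrt_pvalue(llf_full: float, llf_reduced: float, df: int = 1) -> float:
    """Likelihood-ratio test P-value; the statistic is floored at 0."""
    stat = max(2.0 * (llf_full - llf_reduced), 0.0)
    return float(chi2.sf(stat, df=df))
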