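"""Maximum-likelihood fitting of dyad-independent ERGMs.

Because the dyads are independent Bernoulli trials with a logistic link,
the MLE is that of a logistic regression over the n(n-1)/2 dyads.  The
fitter is iteratively reweighted least squares (IRLS, i.e. Newton-Raphson
on the log-likelihood) with step halving; it converges when the score
(gradient) sup-norm drops below 1e-8.  Standard errors come from the
inverse observed information at the optimum, Wald Z statistics and
two-sided normal p-values from those.

Effect sizes are reported on two scales: the odds ratio exp(theta), and the
fold-increase in connection probability relative to the baseline cell,
logistic(theta_0 + theta) / logistic(theta_0).  The probability fold is the
headline quantity; in sparse networks (very negative theta_0) the two
coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .dyadmodel import DyadDesign

__all__ = ["FitResult", "fit_model", "fit_grouped", "group_design",
           "fold_change", "theta_for_fold", "information_criteria",
           "InformationCriteria"]

GRAD_TOL = 1e-8
MAX_ITER = 100
SEPARATION_BOUND = 15.0


class InformationCriteria(NamedTuple):
    bic: float
    aic: float
    aicc: float


def information_criteria(loglik: float, k: int, n_obs: int) -> InformationCriteria:
    """BIC, AIC and small-sample-corrected AICc for a fitted model.

    ``n_obs`` is the number of observations used in the BIC penalty — here
    the number of dyads, since each dyad is one Bernoulli observation.
    AICc is undefined (NaN) when n_obs <= k + 1.
    """
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * math.log(n_obs) if n_obs > 0 else aic
    if n_obs > k + 1:
        aicc = aic + 2.0 * k * (k + 1) / (n_obs - k - 1)
    else:
        aicc = math.nan
    return InformationCriteria(bic=bic, aic=aic, aicc=aicc)


def fold_change(theta0: float, theta: float) -> float:
    """Fold-increase in connection probability over the baseline cell.

    Returns logistic(theta0 + theta) / logistic(theta0).  Strictly
    increasing in theta, equal to 1 at theta = 0, and tending to the odds
    ratio exp(theta) as theta0 -> -inf (the sparse-network limit).
    """
    if not (math.isfinite(theta0) and math.isfinite(theta)):
        raise ValueError("fold_change requires finite inputs")
    return float(expit(theta0 + theta) / expit(theta0))


def theta_for_fold(theta0: float, fold: float) -> float:
    """Coefficient producing a given probability fold at baseline ``theta0``.

    Inverse of :func:`fold_change` in its second argument; requires
    fold * logistic(theta0) < 1.
    """
    p = fold * expit(theta0)
    if not (0.0 < p < 1.0):
        raise ValueError(
            f"fold {fold} unreachable at baseline {theta0}: implied probability {p}"
        )
    return float(logit(p) - theta0)


@dataclass
class FitResult:
    """MLE of a dyad-independent ERGM with inference and effect sizes."""

    columns: list[str]
    params: np.ndarray
    se: np.ndarray
    z: np.ndarray
    pvalues: np.ndarray
    loglik: float
    k: int
    n_dyads: int
    ic: InformationCriteria
    fold: np.ndarray          # probability fold per column (intercept -> NaN)
    odds_ratio: np.ndarray    # exp(theta) per column (intercept -> NaN)
    converged: bool
    separated: np.ndarray     # bool per column
    label: str = ""

    @property
    def bic(self) -> float:
        return self.ic.bic

    @property
    def aic(self) -> float:
        return self.ic.aic

    @property
    def aicc(self) -> float:
        return self.ic.aicc

    def pvalue(self, column: str) -> float:
        return float(self.pvalues[self.columns.index(column)])

    def coef(self, column: str) -> float:
        return float(self.params[self.columns.index(column)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "z": self.z,
                "p": self.pvalues,
                "odds_ratio": self.odds_ratio,
                "fold": self.fold,
                "separated": self.separated,
            },
            index=self.columns,
        )


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), stable via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _grouped_loglik(s: np.ndarray, trials: np.ndarray, eta: np.ndarray) -> float:
    # Bernoulli log-likelihood of grouped dyads (no binomial coefficient, so
    # it equals the sum over the underlying individual dyads)
    return float(s @ eta - trials @ np.logaddexp(0.0, eta))


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    if X.shape[1] == 0:
        raise ValueError("empty design")
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [columns[j] for j in np.flatnonzero(diag <= tol)]
    if bad:
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def fit_model(design: DyadDesign, max_iter: int = MAX_ITER,
              tol: float = GRAD_TOL) -> FitResult:
    """Fit the Bernoulli dyad model by IRLS with step halving.

    Raises on a rank-deficient design (naming the collinear columns) or on a
    constant non-intercept column.  Perfect separation — a covariate cell
    whose dyads are all edges or all non-edges — makes the affected
    coefficients diverge; those are flagged ``separated`` with infinite SE
    and NaN p, while the remaining coefficients are still reported.
    """
    X = np.asarray(design.X, dtype=float)
    y = np.asarray(design.y, dtype=float)
    columns = list(design.columns)
    m, k = X.shape
    for j in range(1, k):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"degenerate design: column {columns[j]!r} is constant")
    _check_rank(X, columns)
    return fit_grouped(X, y, np.ones(m), columns, label=design.spec.label,
                       max_iter=max_iter, tol=tol)


def group_design(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse design rows into unique covariate patterns.

    Returns ``(X_patterns, inverse, trials)``: per-replicate sufficient
    statistics are then ``successes = bincount(inverse, weights=y)``, and
    :func:`fit_grouped` on the collapsed data gives the identical MLE,
    standard errors and log-likelihood at a fraction of the cost when the
    number of patterns is small (as for homophily/mixing designs).
    """
    Xp, inverse, trials = np.unique(X, axis=0, return_inverse=True,
                                    return_counts=True)
    return Xp, inverse, trials.astype(float)


def fit_grouped(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    columns: list[str],
    label: str = "",
    max_iter: int = MAX_ITER,
    tol: float = GRAD_TOL,
) -> FitResult:
    """IRLS on (possibly grouped) Bernoulli dyads; see :func:`fit_model`."""
    X = np.asarray(X, dtype=float)
    s = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    k = X.shape[1]
    m = int(round(trials.sum()))

    beta = np.zeros(k)
    ll = _grouped_loglik(s, trials, X @ beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (s - trials * mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.clip(trials * mu * (1.0 - mu), 1e-12, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll = _grouped_loglik(s, trials, X @ new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _grouped_loglik(s, trials, X @ new_beta)
            halvings += 1
        beta, ll = new_beta, new_ll

    # Diverging coefficients indicate separation (a covariate cell that is
    # all edges or all non-edges): the finite MLE does not exist, even if the
    # score has numerically flattened out on the plateau.
    separated = np.abs(beta) > SEPARATION_BOUND
    if separated.any():
        converged = False

    mu = expit(X @ beta)
    w = np.clip(trials * mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se = np.where(separated, np.inf, se)
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(se > 0, beta / se, np.nan)
    pval = 2.0 * norm.sf(np.abs(zval))
    pval = np.where(separated, np.nan, pval)

    fold = np.full(k, np.nan)
    odds = np.full(k, np.nan)
    theta0 = beta[0]
    for j in range(1, k):
        odds[j] = math.exp(beta[j]) if abs(beta[j]) < 700 else math.inf
        fold[j] = (
            fold_change(theta0, beta[j])
            if math.isfinite(beta[j]) and not separated[j]
            else math.inf
        )

    return FitResult(
        columns=columns,
        params=beta,
        se=se,
        z=zval,
        pvalues=pval,
        loglik=ll,
        k=k,
        n_dyads=m,
        ic=information_criteria(ll, k, m),
        fold=fold,
        odds_ratio=odds,
        converged=converged,
        separated=separated,
        label=label,
    )
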