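"""Logistic presence/absence model and its likelihood-ratio test.

The zero part of the two-part model is logit{P(Y>0 | X)} = Z'eta + C'gamma
(intercept included in the design).  Association of the tested covariates
with presence is assessed by the LRT of eta = 0 against the reduced model.

The solver is a damped Newton iteration; complete or quasi-complete
separation is handled by capping coefficients at |coef| <= 15 with a
warning rather than failing, so batch per-feature runs never abort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

COEF_CAP = 15.0


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    log_likelihood: float
    converged: bool
    separated: bool = False


def _loglik(D: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1+exp) via logaddexp for stability
    return float(np.sum(D * eta - np.logaddexp(0.0, eta)))


def fit_logistic(D: np.ndarray, X: np.ndarray, max_iter: int = 50, tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood logistic regression of D on the design X."""
    D = np.asarray(D, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != D.size:
        X = X.T
    if D.min() == D.max():
        raise ValueError("presence indicator has a single class")
    n, k = X.shape
    beta = np.zeros(k)
    ll = _loglik(D, X, beta)
    converged = False
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        grad = X.T @ (D - p)
        H = (X * W[:, None]).T @ X + 1e-12 * np.eye(k)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped update: halve until the likelihood does not decrease
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = _loglik(D, X, cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        beta = cand
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    separated = bool(np.any(np.abs(beta) > COEF_CAP))
    if separated:
        warnings.warn(
            "possible separation in logistic fit; capping coefficients",
            RuntimeWarning,
            stacklevel=2,
        )
        beta = np.clip(beta, -COEF_CAP, COEF_CAP)
        ll = _loglik(D, X, beta)
    return LogisticFit(beta, ll, converged, separated)


def logistic_lrt_pvalue(full: LogisticFit, reduced: LogisticFit, df: int) -> float:
    """Upper-tail chi-square p-value of the likelihood-ratio statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -1e-6 * (abs(full.log_likelihood) + 1.0):
        raise ValueError(
            "reduced model fits better than the full model; models are not nested"
        )
    return float(chi2.sf(max(stat, 0.0), df))
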