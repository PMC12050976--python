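"""Rank-score test for the tested covariates in the single-index quantile
model, and the combined two-part test.

Under the null the score of the smoothed profile loss with respect to the
tested coefficients is approximated empirically by

    s_hat = n^{-1} sum_i {tau - I(Y_i - G_hat(C_i'beta_hat) < 0)}
                    G_hat'(C_i'beta_hat) Zhat_i I(Y_i > 0),

where Zhat are the tested covariates residualized against spline functions
of the fitted index (a weighted least-squares projection over positive
rows).  Its variance is estimated from g_i = G_hat'(u_i) Xhat_i I(Y_i>0) as
Omega = n^{-1} sum g_i g_i', partitioned into tested (block 1) and
adjustment (block 2) coordinates.  The statistic

    T_tau = n {tau(1-tau)}^{-1} s*' S^+ s*,
    S = Omega_11 - Omega_12 Omega_22^+ Omega_21,

projects out the nuisance block and is asymptotically chi^2_p under the
null.  The quadratic form uses the effective score
s* = s_Z - Omega_12 Omega_22^+ s_C: at an exact null optimum the nuisance
score s_C vanishes and s* = s_Z, but the profile fit is derivative-free on
a nonsmooth objective, and without the projection the statistic is badly
anti-conservative whenever the tested covariates are correlated with the
adjustment covariates.  For small samples a fast permutation scheme replaces the chi-square
calibration: the null fit depends only on (Y, C) and is computed once; rows
of Z are permuted jointly and only the projection, score, covariance,
statistic and the logistic LRT are recomputed per permutation.  The per-tau
statistics are calibrated against their permutation distribution and the
resulting p-values enter the Cauchy combination; permuting the combined
statistic itself is also supported but is markedly less powerful (the
permutation null of a Cauchy-type statistic is heavy-tailed, so strong
evidence in one component is diluted), so it is reported as a secondary
quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .combiner import CombinedResult, cauchy_combine, quantile_weights, zero_proportion
from .single_index import (
    Dataset,
    FitConfig,
    NullQuantileFit,
    fit_null,
    predict_G,
)
from .splines import SplineBasis, eval_basis
from .zero_model import fit_logistic, logistic_lrt_pvalue

DEFAULT_GRID = (0.1, 0.25, 0.5, 0.75, 0.9)
PINV_RTOL = 1e-10  # singular values below this fraction of the largest are dropped
ASYMPTOTIC_MIN_POSITIVE = 1000  # n_+ at which chi-square p-values replace permutation


@dataclass
class ScoreResult:
    """Per-quantile-level rank-score test output."""

    tau: float
    score: np.ndarray
    omega11: np.ndarray
    omega12: np.ndarray
    omega21: np.ndarray
    omega22: np.ndarray
    statistic: float
    df: int
    p_value: float


@dataclass
class ZiqsirResult:
    """Full two-part test: logistic LRT + per-tau rank scores + combination."""

    n: int
    n_positive: int
    r_hat: float
    mode: str
    grid: tuple[float, ...]
    p_logistic: float
    score_results: list[ScoreResult]
    combined: CombinedResult
    p_quantile_perm: np.ndarray | None = None
    p_combined_tc_perm: float | None = None
    n_permutations: int = 0

    @property
    def p_combined(self) -> float:
        return self.combined.p_combined

    @property
    def p_quantile(self) -> np.ndarray:
        return self.combined.p_quantile


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def project_covariates(
    X: np.ndarray,
    index: np.ndarray,
    basis: SplineBasis,
    positive_mask: np.ndarray,
) -> np.ndarray:
    """Residualize columns of X against the spline span of the index.

    The projector is trained by least squares over positive rows only;
    orthogonality sum_i B(u_i) Xhat_i' I(Y_i>0) = 0 holds by the normal
    equations.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    pos = np.asarray(positive_mask, dtype=bool)
    if pos.sum() < basis.dimension:
        raise ValueError("fewer positive rows than basis dimension")
    B = eval_basis(basis, index)
    Bp = B[pos]
    gram = Bp.T @ Bp
    cross = Bp.T @ X[pos]
    coef = np.linalg.pinv(gram, rcond=PINV_RTOL) @ cross
    return X - B @ coef


def _score_ingredients(data: Dataset, fit: NullQuantileFit):
    """Shared pieces of score and covariance at the fitted null index."""
    index = data.C @ fit.beta_hat
    G, G1 = predict_G(fit, index)
    psi = fit.tau - (data.Y - G < 0)
    X = np.hstack([data.Z, data.C]) if data.p else data.C
    Xhat = project_covariates(X, index, fit.basis, data.D)
    return Xhat, G1, psi


def empirical_score(data: Dataset, fit: NullQuantileFit) -> np.ndarray:
    """Empirical rank score for the tested covariates (length p)."""
    Xhat, G1, psi = _score_ingredients(data, fit)
    Zhat = Xhat[:, : data.p]
    return (psi * G1 * data.D) @ Zhat / data.n


def score_covariance(
    data: Dataset, fit: NullQuantileFit
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Blocks of Omega = n^{-1} sum g_i g_i', block 1 = tested covariates."""
    Xhat, G1, _ = _score_ingredients(data, fit)
    g = (G1 * data.D)[:, None] * Xhat
    omega = g.T @ g / data.n
    p = data.p
    return omega[:p, :p], omega[:p, p:], omega[p:, :p], omega[p:, p:]


def rank_score_statistic(
    score: np.ndarray,
    omega11: np.ndarray,
    omega12: np.ndarray,
    omega21: np.ndarray,
    omega22: np.ndarray,
    n: int,
    tau: float,
) -> float:
    """Quadratic form T_tau = n {tau(1-tau)}^{-1} s' S^+ s with the nuisance
    block projected out of the covariance."""
    score = np.atleast_1d(np.asarray(score, dtype=float))
    p = score.size
    if p == 0:
        raise ValueError("no tested covariates")
    omega11 = np.atleast_2d(omega11)
    if omega22 is None or np.size(omega22) == 0:
        schur = omega11
    else:
        omega22 = np.atleast_2d(omega22)
        omega12 = omega12.reshape(p, -1)
        omega21 = omega21.reshape(-1, p)
        schur = omega11 - omega12 @ np.linalg.pinv(omega22, rcond=PINV_RTOL) @ omega21
    stat = float(score @ np.linalg.pinv(schur, rcond=PINV_RTOL) @ score * n / (tau * (1 - tau)))
    return max(stat, 0.0)


def chisq_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if statistic < 0:
        raise ValueError("statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.sf(statistic, df))


def effective_score(
    score_tested: np.ndarray,
    score_nuisance: np.ndarray,
    omega12: np.ndarray,
    omega22: np.ndarray,
) -> np.ndarray:
    """Project the nuisance component out of the empirical score.

    At an exact null optimum the nuisance score is zero and this is the
    identity; with an inexact (derivative-free, nonsmooth) profile fit the
    leaked nuisance component must be removed, otherwise the Schur
    complement understates the variance whenever the tested covariates
    correlate with the adjustment covariates.
    """
    if np.size(omega22) == 0:
        return score_tested
    return score_tested - omega12 @ np.linalg.pinv(omega22, rcond=PINV_RTOL) @ score_nuisance


def score_test(data: Dataset, fit: NullQuantileFit) -> ScoreResult:
    """Rank-score test at a single quantile level with chi-square p-value."""
    Xhat, G1, psi = _score_ingredients(data, fit)
    p = data.p
    w = psi * G1 * data.D
    s = w @ Xhat[:, :p] / data.n
    s_nuis = w @ Xhat[:, p:] / data.n
    g = (G1 * data.D)[:, None] * Xhat
    omega = g.T @ g / data.n
    o11, o12, o21, o22 = omega[:p, :p], omega[:p, p:], omega[p:, :p], omega[p:, p:]
    s_eff = effective_score(s, s_nuis, o12, o22)
    stat = rank_score_statistic(s_eff, o11, o12, o21, o22, data.n, fit.tau)
    return ScoreResult(fit.tau, s, o11, o12, o21, o22, stat, p, chisq_pvalue(stat, p))


# ---------------------------------------------------------------------------
# full two-part test with asymptotic / permutation modes
# ---------------------------------------------------------------------------

@dataclass
class _TauEngine:
    """Precomputed per-tau quantities reused across permutations."""

    fit: NullQuantileFit
    B_pos: np.ndarray          # basis design over positive rows
    proj: np.ndarray           # pinv(B'B) B' over positive rows
    psiG1: np.ndarray          # psi * G1 over positive rows
    gC: np.ndarray             # G1 * Chat over positive rows
    oCC_pinv: np.ndarray
    s_nuis: np.ndarray         # nuisance-block empirical score (fixed)
    n: int

    def statistic(self, Z_pos: np.ndarray) -> float:
        Zhat = Z_pos - self.B_pos @ (self.proj @ Z_pos)
        s = self.psiG1 @ Zhat / self.n
        gZ = Zhat * self._G1col
        oZZ = gZ.T @ gZ / self.n
        oZC = gZ.T @ self.gC / self.n
        s_eff = s - oZC @ self.oCC_pinv @ self.s_nuis
        schur = oZZ - oZC @ self.oCC_pinv @ oZC.T
        tau = self.fit.tau
        stat = float(
            s_eff @ np.linalg.pinv(schur, rcond=PINV_RTOL) @ s_eff
            * self.n / (tau * (1 - tau))
        )
        return max(stat, 0.0)

    _G1col: np.ndarray = field(init=False, default=None)


def _build_tau_engine(data: Dataset, fit: NullQuantileFit) -> _TauEngine:
    pos = data.D
    index = data.C @ fit.beta_hat
    G, G1 = predict_G(fit, index)
    psi = fit.tau - (data.Y - G < 0)
    B = eval_basis(fit.basis, index)
    Bp = B[pos]
    proj = np.linalg.pinv(Bp.T @ Bp, rcond=PINV_RTOL) @ Bp.T
    Cpos = data.C[pos]
    Chat = Cpos - Bp @ (proj @ Cpos)
    G1p = G1[pos]
    gC = Chat * G1p[:, None]
    oCC = gC.T @ gC / data.n
    psiG1 = psi[pos] * G1p
    eng = _TauEngine(
        fit=fit,
        B_pos=Bp,
        proj=proj,
        psiG1=psiG1,
        gC=gC,
        oCC_pinv=np.linalg.pinv(oCC, rcond=PINV_RTOL),
        s_nuis=psiG1 @ Chat / data.n,
        n=data.n,
    )
    eng._G1col = G1p[:, None]
    return eng


def ziqsir_test(
    Y: np.ndarray,
    Z: np.ndarray,
    C: np.ndarray,
    grid: tuple[float, ...] = DEFAULT_GRID,
    mode: str = "auto",
    n_permutations: int = 199,
    seed: int | None = None,
    fit_config: FitConfig | None = None,
    asymptotic_min_positive: int = ASYMPTOTIC_MIN_POSITIVE,
) -> ZiqsirResult:
    """Full association test of Z with a zero-inflated Y, adjusting for C.

    Combines the logistic LRT for the presence part with rank-score tests at
    each quantile level in ``grid`` via the weighted Cauchy combination.
    ``mode`` is ``"asymptotic"``, ``"permutation"`` or ``"auto"`` (asymptotic
    when the positive count reaches ``asymptotic_min_positive``).
    """
    data = Dataset(Y=Y, Z=Z, C=C)
    if data.p == 0:
        raise ValueError("no tested covariates")
    if mode not in ("auto", "asymptotic", "permutation"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "asymptotic" if data.n_positive >= asymptotic_min_positive else "permutation"

    grid = tuple(grid)
    weights = quantile_weights(np.asarray(grid))
    r_hat = zero_proportion(data.Y)

    ones = np.ones((data.n, 1))
    X_full = np.hstack([ones, data.Z, data.C])
    X_red = np.hstack([ones, data.C])
    full = fit_logistic(data.D, X_full)
    reduced = fit_logistic(data.D, X_red)
    p_logistic = logistic_lrt_pvalue(full, reduced, df=data.p)

    engines = []
    score_results = []
    for tau in grid:
        fit = fit_null(data, tau, fit_config)
        eng = _build_tau_engine(data, fit)
        Z_pos = data.Z[data.D]
        stat = eng.statistic(Z_pos)
        score_results.append(
            ScoreResult(
                tau=tau,
                score=eng.psiG1 @ (Z_pos - eng.B_pos @ (eng.proj @ Z_pos)) / data.n,
                omega11=None,
                omega12=None,
                omega21=None,
                omega22=None,
                statistic=stat,
                df=data.p,
                p_value=chisq_pvalue(stat, data.p),
            )
        )
        engines.append(eng)

    p_quantile = np.array([r.p_value for r in score_results])
    combined = cauchy_combine(p_logistic, p_quantile, r_hat, weights)

    if mode == "asymptotic":
        return ZiqsirResult(
            n=data.n,
            n_positive=data.n_positive,
            r_hat=r_hat,
            mode=mode,
            grid=grid,
            p_logistic=p_logistic,
            score_results=score_results,
            combined=combined,
        )

    # permutation mode: the null fits depend only on (Y, C) and stay fixed;
    # Z rows are permuted jointly and only score/statistic/LRT recomputed.
    # The per-tau statistics are permutation-calibrated and the resulting
    # p-values are Cauchy-combined with the logistic LRT p-value; the tail
    # of the permuted combined statistic is also reported.
    B = int(n_permutations)
    if B < 19:
        raise ValueError("at least 19 permutations are required for alpha=0.05 resolution")
    rng = np.random.default_rng(seed)
    T_obs = combined.T_C
    stats_obs = np.array([r.statistic for r in score_results])
    count_comb = 0
    perm_stats = np.empty((B, len(grid)))
    pos = data.D
    for b in range(B):
        perm = rng.permutation(data.n)
        Zb = data.Z[perm]
        full_b = fit_logistic(data.D, np.hstack([ones, Zb, data.C]))
        pL_b = logistic_lrt_pvalue(full_b, reduced, df=data.p)
        stats_b = np.array([eng.statistic(Zb[pos]) for eng in engines])
        perm_stats[b] = stats_b
        pQ_b = chi2.sf(stats_b, data.p)
        T_b = cauchy_combine(pL_b, pQ_b, r_hat, weights).T_C
        if T_b >= T_obs - 1e-12:
            count_comb += 1
    p_comb_tc_perm = (1 + count_comb) / (B + 1)
    p_tau_perm = (1 + (perm_stats >= stats_obs[None, :] - 1e-12).sum(axis=0)) / (B + 1)
    # continuous tail calibration: match a scaled chi-square (Satterthwaite)
    # to the permutation moments of each T_tau, so the Cauchy combination is
    # not blunted by the 1/(B+1) resolution of raw permutation p-values
    p_tau_smooth = np.empty(len(grid))
    for k in range(len(grid)):
        m = perm_stats[:, k].mean()
        v = perm_stats[:, k].var()
        if v <= 1e-12 or m <= 1e-12:
            p_tau_smooth[k] = p_tau_perm[k]
            continue
        a = v / (2.0 * m)
        nu = 2.0 * m * m / v
        p_tau_smooth[k] = float(chi2.sf(stats_obs[k] / a, nu))
    combined_perm = cauchy_combine(p_logistic, p_tau_smooth, r_hat, weights)
    return ZiqsirResult(
        n=data.n,
        n_positive=data.n_positive,
        r_hat=r_hat,
        mode=mode,
        grid=grid,
        p_logistic=p_logistic,
        score_results=score_results,
        combined=combined_perm,
        p_quantile_perm=p_tau_perm,
        p_combined_tc_perm=p_comb_tc_perm,
        n_permutations=B,
    )


def permutation_pvalue(
    data: Dataset,
    grid: tuple[float, ...] = DEFAULT_GRID,
    B: int = 199,
    seed: int | None = None,
    fit_config: FitConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Permutation p-values: per-tau and for the combined statistic.

    Convenience wrapper over :func:`ziqsir_test` in permutation mode.
    """
    res = ziqsir_test(
        data.Y, data.Z, data.C, grid=grid, mode="permutation",
        n_permutations=B, seed=seed, fit_config=fit_config,
    )
    return res.p_quantile_perm, res.p_combined_tc_perm
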