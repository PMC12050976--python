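"""Null single-index quantile model for the positive part of a
zero-inflated outcome.

Given Y >= 0, tested covariates Z and adjustment covariates C, the positive
part is modelled as Q_Y(tau | X, Y>0) = G_tau(Z'alpha + C'beta) with unknown
link G_tau.  G_tau is approximated by a B-spline sieve B(u)'theta.  The
pseudo-likelihood is the check loss over positive observations

    L(alpha, beta, theta) = n^{-1} sum_i rho_tau{Y_i - B(Z_i'alpha + C_i'beta)'theta} I(Y_i > 0),

profiled over theta (an ordinary linear-in-parameters quantile regression on
the basis columns) and minimized over the unit sphere ||beta|| = 1 under the
null alpha = 0.  The index excludes the intercept: with a free link G an
intercept inside the index is not identifiable (G absorbs location), so G
absorbs it instead.

The profile loss is nonsmooth in beta, so the sphere is searched with a
multi-started derivative-free simplex in spherical coordinates; the inner
theta-fit uses an iteratively reweighted least-squares approximation to the
exact linear-programming quantile fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .splines import SplineBasis, build_basis, eval_basis, eval_basis_deriv


class UnderdeterminedFitError(ValueError):
    """Too few positive observations for the requested basis dimension."""


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Zero-inflated response with a tested / adjustment covariate split.

    ``Y`` is the non-negative response, ``Z`` (n x p) holds the covariates
    under test, ``C`` (n x q) the adjustment covariates (no intercept
    column), and ``D = I(Y > 0)`` the presence indicator.
    """

    Y: np.ndarray
    Z: np.ndarray
    C: np.ndarray
    D: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        if np.any(self.Y < 0):
            raise ValueError("response must be non-negative")
        n = self.Y.size
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.Z.shape[0] != n and self.Z.shape[1] == n:
            self.Z = self.Z.T
        if self.C.shape[0] != n and self.C.shape[1] == n:
            self.C = self.C.T
        if self.Z.shape[0] != n or self.C.shape[0] != n:
            raise ValueError("Z and C must have one row per sample")
        self.D = self.Y > 0

    @property
    def n(self) -> int:
        return self.Y.size

    @property
    def n_positive(self) -> int:
        return int(self.D.sum())

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def q(self) -> int:
        return self.C.shape[1]


@dataclass
class FitConfig:
    """Tuning knobs for the null fit.

    ``n_interior=None`` applies the default knot rule
    ``max(1, round(n_+^{1/5}))``; ``n_starts`` counts sphere multi-starts
    (one from normalized linear quantile regression plus random unit
    vectors); ``max_outer_evals`` caps profile-loss evaluations per simplex
    start.
    """

    order: int = 4
    n_interior: int | None = None
    n_starts: int = 5
    max_outer_evals: int | None = None
    loss_tol: float = 1e-6
    min_positive: int = 30
    seed: int = 0


DEFAULT_FIT_CONFIG = FitConfig()


@dataclass
class NullQuantileFit:
    """Per-tau null estimate: unit-norm index direction and fitted link."""

    tau: float
    beta_hat: np.ndarray
    theta_hat: np.ndarray
    basis: SplineBasis
    converged: bool
    loss: float


# ---------------------------------------------------------------------------
# check loss and the inner (theta) quantile fit
# ---------------------------------------------------------------------------

def check_loss(u: np.ndarray, tau: float) -> np.ndarray:
    """Quantile check loss rho_tau(u) = u {tau - I(u < 0)}."""
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0,1), got {tau}")
    u = np.asarray(u, dtype=float)
    return u * (tau - (u < 0))


def _qreg_irls(
    X: np.ndarray,
    y: np.ndarray,
    tau: float,
    tol: float = 1e-8,
    max_iter: int = 100,
    beta_init: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Quantile regression of y on X by iteratively reweighted least squares.

    Minimizes sum_i rho_tau(y_i - x_i'b) via the standard fixed-point
    iteration with weights |tau - I(r<0)| / max(|r|, delta).  Returns the
    coefficients and the mean check loss.  ``beta_init`` warm-starts the
    weights from its residuals.
    """
    n, k = X.shape
    scale = max(float(np.abs(y).mean()), 1e-12)
    delta = 1e-6 * scale
    ridge = 1e-10 * np.eye(k)
    if beta_init is not None and beta_init.size == k:
        r0 = y - X @ beta_init
        w = np.abs(tau - (r0 < 0)) / np.maximum(np.abs(r0), delta)
    else:
        w = np.full(n, 1.0)
    beta = beta_init
    loss_prev = np.inf
    for _ in range(max_iter):
        Xw = X * w[:, None]
        A = Xw.T @ X + ridge
        b = Xw.T @ y
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        r = y - X @ beta
        loss = float(check_loss(r, tau).mean())
        if np.isfinite(loss_prev) and abs(loss_prev - loss) <= tol * max(1.0, abs(loss_prev)):
            loss_prev = loss
            break
        loss_prev = loss
        w = np.abs(tau - (r < 0)) / np.maximum(np.abs(r), delta)
    return beta, loss_prev


def fit_theta(
    data: Dataset,
    alpha: np.ndarray,
    beta: np.ndarray,
    tau: float,
    basis: SplineBasis,
) -> np.ndarray:
    """Spline coefficients minimizing the check loss over positive rows."""
    pos = data.D
    if data.n_positive < basis.dimension:
        raise UnderdeterminedFitError(
            f"{data.n_positive} positive rows < basis dimension {basis.dimension}"
        )
    u = _index(data, alpha, beta)[pos]
    B = eval_basis(basis, u)
    theta, _ = _qreg_irls(B, data.Y[pos], tau)
    return theta


def pseudo_likelihood(
    data: Dataset,
    alpha: np.ndarray,
    beta: np.ndarray,
    theta: np.ndarray,
    tau: float,
    basis: SplineBasis,
) -> float:
    """Mean check loss over positive rows at given (alpha, beta, theta)."""
    pos = data.D
    u = _index(data, alpha, beta)[pos]
    resid = data.Y[pos] - eval_basis(basis, u) @ theta
    return float(check_loss(resid, tau).sum() / data.n)


def profile_loss(
    data: Dataset,
    alpha: np.ndarray,
    beta: np.ndarray,
    tau: float,
    config: FitConfig = DEFAULT_FIT_CONFIG,
) -> float:
    """Profile pseudo-likelihood: inner theta minimized out, basis rebuilt
    on the index induced by (alpha, beta)."""
    pos = data.D
    u = _index(data, alpha, beta)
    basis = build_basis(u[pos], _n_interior(data.n_positive, config), config.order)
    theta = fit_theta(data, alpha, beta, tau, basis)
    return pseudo_likelihood(data, alpha, beta, theta, tau, basis)


def _index(data: Dataset, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    alpha = np.zeros(data.p) if alpha is None else np.asarray(alpha, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    u = data.C @ beta
    if data.p and np.any(alpha != 0):
        u = u + data.Z @ alpha
    return u


def _n_interior(n_positive: int, config: FitConfig) -> int:
    if config.n_interior is not None:
        return config.n_interior
    return max(1, int(round(n_positive ** 0.2)))


# ---------------------------------------------------------------------------
# sphere parameterization
# ---------------------------------------------------------------------------

def _angles_to_unit(angles: np.ndarray) -> np.ndarray:
    """Spherical coordinates (q-1 angles) -> unit vector in R^q."""
    angles = np.atleast_1d(angles)
    q = angles.size + 1
    v = np.empty(q)
    s = 1.0
    for i, a in enumerate(angles):
        v[i] = s * np.cos(a)
        s *= np.sin(a)
    v[-1] = s
    return v


def _unit_to_angles(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    q = v.size
    angles = np.empty(q - 1)
    s = 1.0
    for i in range(q - 1):
        c = np.clip(v[i] / s if s > 1e-300 else 1.0, -1.0, 1.0)
        angles[i] = np.arccos(c)
        s *= np.sin(angles[i])
    if v[-1] < 0:
        angles[-1] = 2 * np.pi - angles[-1]
    return angles


def _apply_sign_convention(beta: np.ndarray) -> np.ndarray:
    """First coordinate with magnitude above 1e-12 is made positive."""
    for b in beta:
        if abs(b) > 1e-12:
            return beta if b > 0 else -beta
    return beta


# ---------------------------------------------------------------------------
# null fit
# ---------------------------------------------------------------------------

def fit_null(data: Dataset, tau: float, config: FitConfig | None = None) -> NullQuantileFit:
    """Estimate the null model: alpha = 0, ||beta|| = 1, profiled theta.

    Covariate columns are standardized internally for optimizer
    conditioning; the returned direction lives on the original scale (the
    affine reparameterization is absorbed by the link, and theta is refit
    once on the original-scale index).
    """
    config = config or DEFAULT_FIT_CONFIG
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0,1), got {tau}")
    if data.q < 1:
        raise ValueError("at least one adjustment covariate is required")
    npos = data.n_positive
    if npos < config.min_positive:
        raise UnderdeterminedFitError(
            f"{npos} positive rows < minimum fit size {config.min_positive}"
        )
    n_int = _n_interior(npos, config)
    pos = data.D
    Ypos = data.Y[pos]
    Cpos = data.C[pos]

    if data.q == 1:
        beta = _apply_sign_convention(np.ones(1))
        basis = build_basis((data.C @ beta)[pos], n_int, config.order)
        theta = fit_theta(data, None, beta, tau, basis)
        loss = pseudo_likelihood(data, None, beta, theta, tau, basis)
        return NullQuantileFit(tau, beta, theta, basis, True, loss)

    # standardized working copy of C (positive rows drive the fit)
    center = Cpos.mean(axis=0)
    scale = Cpos.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Cs = (Cpos - center) / scale

    warm: dict[str, np.ndarray | None] = {"theta": None}

    def obj(angles: np.ndarray) -> float:
        b = _angles_to_unit(angles)
        u = Cs @ b
        try:
            basis = build_basis(u, n_int, config.order)
        except ValueError:
            return np.inf
        B = eval_basis(basis, u)
        # warm start from the previous simplex vertex; looser inner
        # tolerance is enough to rank candidate directions
        theta, loss = _qreg_irls(
            B, Ypos, tau, tol=1e-5, max_iter=30, beta_init=warm["theta"]
        )
        warm["theta"] = theta
        return loss * npos / data.n

    rng = np.random.default_rng(config.seed)
    starts = [_qreg_direction(Cs, Ypos, tau)]
    while len(starts) < config.n_starts:
        v = rng.standard_normal(data.q)
        starts.append(v / np.linalg.norm(v))

    best = None
    converged = False
    maxfev = config.max_outer_evals
    for v in starts:
        res = minimize(
            obj,
            _unit_to_angles(v),
            method="Nelder-Mead",
            options={
                "xatol": 1e-3,
                "fatol": config.loss_tol,
                "maxfev": maxfev if maxfev is not None else 200 * (data.q - 1),
            },
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success) or converged
    if not converged:
        warnings.warn(
            "sphere search did not converge; returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    beta_s = _angles_to_unit(best.x)
    beta = beta_s / scale
    beta = _apply_sign_convention(beta / np.linalg.norm(beta))
    basis = build_basis((data.C @ beta)[pos], n_int, config.order)
    theta = fit_theta(data, None, beta, tau, basis)
    loss = pseudo_likelihood(data, None, beta, theta, tau, basis)
    return NullQuantileFit(tau, beta, theta, basis, converged, loss)


def _qreg_direction(C: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Normalized linear quantile-regression coefficients as a warm start."""
    X = np.column_stack([np.ones(len(y)), C])
    coef, _ = _qreg_irls(X, y, tau)
    v = coef[1:]
    nrm = np.linalg.norm(v)
    if not np.isfinite(nrm) or nrm < 1e-12:
        v = np.ones(C.shape[1])
        nrm = np.linalg.norm(v)
    return v / nrm


def predict_G(fit: NullQuantileFit, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fitted link and its first derivative: G = B(u)'theta, G' = B'(u)'theta."""
    G = eval_basis(fit.basis, u) @ fit.theta_hat
    G1 = eval_basis_deriv(fit.basis, u) @ fit.theta_hat
    return G, G1
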