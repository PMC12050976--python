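"""Synthetic zero-inflated data mimicking a microbiome taxon.

The generator produces five covariates styled after a gut-microbiome cohort
(gender, BMI, waist circumference, diastolic and systolic blood pressure),
a logistic presence model calibrated to the taxon *Blautia*, and a positive
part drawn from a quantile single-index process: each present sample draws
a latent level tau ~ U(0,1) and receives its exact conditional tau-quantile

    Y = G_tau(beta_0(tau) + X' beta(tau)),

with polynomial/trigonometric coefficient curves and a quartic link.  Two
covariate settings are provided: Setting 1 (independent covariates) and
Setting 2 (waist circumference coupled to BMI, systolic coupled to
diastolic pressure).  Nulling a coordinate removes it from both the
presence model and the quantile process, giving exact null data for type-I
error studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .single_index import Dataset

DEFAULT_GAMMA = (-0.4, -0.480, -0.022, 0.021, 0.015, -0.009)


@dataclass(frozen=True)
class DGPConfig:
    setting: int = 1
    n: int = 500
    gamma: tuple[float, ...] = DEFAULT_GAMMA
    null_coords: frozenset[int] = frozenset()
    seed: int = 0
    round_counts: bool = False

    def __post_init__(self) -> None:
        if self.setting not in (1, 2):
            raise ValueError(f"setting must be 1 or 2, got {self.setting}")
        if len(self.gamma) != 6:
            raise ValueError("gamma must have 6 entries (intercept + 5 slopes)")
        coords = frozenset(int(j) for j in self.null_coords)
        if not coords <= {1, 2, 3, 4, 5}:
            raise ValueError("null_coords must be a subset of {1,..,5}")
        object.__setattr__(self, "null_coords", coords)


@dataclass
class SyntheticDataset:
    """Generated covariates and response, plus generation diagnostics."""

    X: np.ndarray
    Y: np.ndarray
    config: DGPConfig
    n_clamped: int = 0

    @property
    def zero_fraction(self) -> float:
        return float((self.Y == 0).mean())

    def to_dataset(self, test_coords: tuple[int, ...]) -> Dataset:
        """Split covariates into tested (1-based coords) and adjustment."""
        coords = [int(j) - 1 for j in test_coords]
        if not coords or not set(coords) <= set(range(5)):
            raise ValueError("test_coords must be non-empty 1-based indices in 1..5")
        rest = [j for j in range(5) if j not in coords]
        return Dataset(Y=self.Y, Z=self.X[:, coords], C=self.X[:, rest])


def gen_covariates(n: int, setting: int, seed_or_rng: int | np.random.Generator = 0) -> np.ndarray:
    """Draw the five covariates for the given setting."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if setting not in (1, 2):
        raise ValueError(f"setting must be 1 or 2, got {setting}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    x1 = rng.binomial(1, 0.5, n).astype(float)
    x2 = rng.normal(28.0, 2.0, n)
    x4 = rng.normal(80.0, 12.0, n)
    if setting == 1:
        x3 = rng.normal(92.5, 13.0, n)
        x5 = rng.normal(124.0, 18.5, n)
    else:
        x3 = 2.0 * x2 + rng.normal(36.5, 9.0, n)
        x5 = 1.3 * x4 + rng.normal(20.0, 7.75, n)
    return np.column_stack([x1, x2, x3, x4, x5])


def presence_probability(X: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """P(Y>0 | X) = expit(gamma_0 + sum_j gamma_j x_j)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    gamma = np.asarray(gamma, dtype=float).ravel()
    return expit(gamma[0] + X @ gamma[1:])


def dgp_beta(tau: np.ndarray) -> np.ndarray:
    """Quantile-coefficient curves (beta_0 .. beta_5) at tau; shape (6, ...)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0) or np.any(tau >= 1):
        raise ValueError("tau must lie in (0,1)")
    return np.stack(
        [
            -147.7 * tau - 50.0 * tau**2 - 20.0,
            0.6 * np.sqrt(tau) - 2.0 * tau,
            2.2 * tau**2,
            tau**2 / 30.0 + 0.02,
            0.097 * np.sin(2.0 * np.pi * tau),
            0.086 * (-3.0 * tau**2 + tau),
        ]
    )


def dgp_link(tau: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Quartic quantile link G_tau(u) of the generating process."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0) or np.any(tau >= 1):
        raise ValueError("tau must lie in (0,1)")
    u = np.asarray(u, dtype=float)
    return tau * ((0.1 * u) ** 4 / 12.0 + 13.5 * (0.1 * u) ** 2 + 1.875 * u)


def gen_response(
    X: np.ndarray,
    rng: np.random.Generator,
    gamma: tuple[float, ...] = DEFAULT_GAMMA,
    null_coords: frozenset[int] = frozenset(),
) -> tuple[np.ndarray, int]:
    """Draw one zero-inflated response vector given covariates.

    Presence D ~ Bernoulli(expit(gamma_0 + X'gamma)); present samples get
    their exact conditional quantile at a latent tau ~ U(0,1).  Nulled
    coordinates have gamma_j = 0 and beta_j(.) = 0.  Returns (Y, n_clamped)
    where n_clamped counts the (rare) negative conditional quantiles clamped
    to zero.
    """
    n = X.shape[0]
    g = np.asarray(gamma, dtype=float).copy()
    for j in null_coords:
        g[j] = 0.0
    prob = presence_probability(X, g)
    D = rng.random(n) < prob
    tau = rng.uniform(0.0, 1.0, n)
    # keep tau strictly interior so the coefficient curves are defined
    tau = np.clip(tau, 1e-12, 1 - 1e-12)
    betas = dgp_beta(tau)  # (6, n)
    for j in null_coords:
        betas[j] = 0.0
    index = betas[0] + np.einsum("ij,ji->i", X, betas[1:])
    G = dgp_link(tau, index)
    n_clamped = int(np.sum(D & (G < 0)))
    Y = np.where(D, np.maximum(G, 0.0), 0.0)
    return Y, n_clamped


def gen_dataset(config: DGPConfig) -> SyntheticDataset:
    """Generate a full dataset under the configured setting."""
    rng = np.random.default_rng(config.seed)
    X = gen_covariates(config.n, config.setting, rng)
    Y, n_clamped = gen_response(X, rng, config.gamma, config.null_coords)
    if config.round_counts:
        Y = np.round(Y)
    return SyntheticDataset(X=X, Y=Y, config=config, n_clamped=n_clamped)


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Independent per-replicate seed from a master seed (counter-based)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(replicate),))
    return int(ss.generate_state(1, dtype=np.uint32)[0])
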