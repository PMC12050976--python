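"""Weighted Cauchy combination of the presence-model p-value with the
quantile-level rank-score p-values.

The combined statistic is

    T_C = r_hat * tan{(0.5 - p_L) pi} + (1 - r_hat) * sum_s w_s tan{(0.5 - p_Q_s) pi},

where r_hat is the observed zero proportion, and the weights over quantile
levels up-weight central quantiles:

    w_s ∝ tau_s I(tau_s <= 0.5) + (1 - tau_s) I(tau_s > 0.5),  sum w_s = 1.

Under the global null T_C is asymptotically standard Cauchy, so the
combined p-value is the Cauchy upper tail 0.5 - arctan(T_C)/pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_GRID = (0.1, 0.25, 0.5, 0.75, 0.9)
_P_CLIP = 1e-15  # keep tan{(0.5-p)pi} finite for underflowed p-values


@dataclass(frozen=True)
class QuantileGrid:
    levels: tuple[float, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.size == 0 or np.any(lv <= 0) or np.any(lv >= 1) or np.any(np.diff(lv) <= 0):
            raise ValueError("quantile levels must be strictly increasing inside (0,1)")

    @property
    def weights(self) -> np.ndarray:
        return quantile_weights(np.asarray(self.levels))


@dataclass
class CombinedResult:
    p_logistic: float
    p_quantile: np.ndarray
    r_hat: float
    weights: np.ndarray
    T_C: float
    p_combined: float


def quantile_weights(levels: np.ndarray) -> np.ndarray:
    """Normalized central-heavy weights over quantile levels."""
    lv = np.asarray(levels, dtype=float).ravel()
    if np.any(lv <= 0) or np.any(lv >= 1):
        raise ValueError("quantile levels must lie strictly inside (0,1)")
    raw = np.where(lv <= 0.5, lv, 1.0 - lv)
    return raw / raw.sum()


def zero_proportion(Y: np.ndarray) -> float:
    """Observed fraction of exact zeros in the response."""
    Y = np.asarray(Y, dtype=float).ravel()
    if Y.size == 0:
        raise ValueError("empty response")
    if np.any(Y < 0):
        raise ValueError("response must be non-negative")
    return float((Y == 0).mean())


def _tan_transform(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), _P_CLIP, 1 - _P_CLIP)
    return np.tan((0.5 - p) * np.pi)


def cauchy_combine(
    p_logistic: float,
    p_quantile: np.ndarray,
    r_hat: float,
    weights: np.ndarray | None = None,
) -> CombinedResult:
    """Combine the zero-part and quantile-part p-values into one test."""
    p_quantile = np.asarray(p_quantile, dtype=float).ravel()
    if weights is None:
        if p_quantile.size != len(DEFAULT_GRID):
            raise ValueError("weights required when not using the default grid size")
        weights = quantile_weights(np.asarray(DEFAULT_GRID))
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.size != p_quantile.size:
        raise ValueError("weights and p_quantile must have equal length")
    if not 0 <= r_hat <= 1:
        raise ValueError("r_hat must lie in [0,1]")
    T_C = float(r_hat * _tan_transform(p_logistic) + (1 - r_hat) * weights @ _tan_transform(p_quantile))
    p_combined = float(0.5 - np.arctan(T_C) / np.pi)
    return CombinedResult(
        p_logistic=float(p_logistic),
        p_quantile=p_quantile,
        r_hat=float(r_hat),
        weights=weights,
        T_C=T_C,
        p_combined=p_combined,
    )
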