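"""Per-feature association testing for microbiome-style count tables.

Applies the two-part rank-score test feature by feature to a features x
samples count table: features with too many zeros are dropped, positive
counts are jittered with U(0,1) noise so the continuous quantile machinery
applies, library size (total retained count per sample) is appended as an
adjustment covariate, categorical covariates are dummy coded, and the
per-feature combined p-values are Benjamini-Hochberg adjusted.  Individual
feature failures are logged and reported as NA; the batch never aborts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .rank_score import DEFAULT_GRID, ziqsir_test
from .single_index import FitConfig

logger = logging.getLogger("ziqsir.pipeline")


@dataclass
class FeatureTable:
    """Counts (features x samples) with feature and sample identifiers."""

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_features, n_samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def zero_proportions(self) -> np.ndarray:
        return (self.counts == 0).mean(axis=1)


def read_feature_table(path: str) -> FeatureTable:
    """Read a TSV with sample ids in the header and feature ids in column 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureTable(
        counts=df.to_numpy(dtype=float),
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
    )


def read_covariates(path: str) -> pd.DataFrame:
    """Read a covariate TSV keyed by sample id (first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def filter_features(table: FeatureTable, max_zero_prop: float = 0.8) -> FeatureTable:
    """Keep features whose zero proportion is strictly below the threshold."""
    if not 0 < max_zero_prop <= 1:
        raise ValueError("max_zero_prop must lie in (0, 1]")
    keep = table.zero_proportions < max_zero_prop
    if not keep.any():
        warnings.warn("no features pass the zero-proportion filter", stacklevel=2)
    return FeatureTable(
        counts=table.counts[keep],
        feature_ids=[f for f, k in zip(table.feature_ids, keep) if k],
        sample_ids=table.sample_ids,
    )


def jitter_counts(counts: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add U(0,1) noise to positive counts; zeros stay exactly zero."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.uniform(0.0, 1.0, counts.shape)
    return np.where(counts > 0, counts + noise, 0.0)


def library_size_covariate(table: FeatureTable) -> np.ndarray:
    """Per-sample total count over the (filtered) features."""
    sizes = table.counts.sum(axis=0)
    if np.any(sizes == 0):
        warnings.warn("some samples have zero library size", stacklevel=2)
    return sizes


def dummy_code(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code non-numeric columns (lexicographic levels, first as reference)."""
    out = {}
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:
                out[f"{col}__{lev}"] = (s.astype(str) == lev).astype(float)
    return pd.DataFrame(out, index=covariates.index)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def run_feature_tests(
    table: FeatureTable,
    covariates: pd.DataFrame,
    test_cols: list[str],
    adjust_cols: list[str],
    grid: tuple[float, ...] = DEFAULT_GRID,
    mode: str = "auto",
    n_permutations: int = 199,
    seed: int = 0,
    max_zero_prop: float = 0.8,
    add_library_size: bool = True,
    fit_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Test each retained feature against the tested covariate columns.

    Sample ids must match between the table and the covariates; samples with
    missing covariates are dropped (with a logged count).  Returns one row
    per retained feature with the component and combined p-values and the
    BH-adjusted q-value; failed features carry NA p-values and a status.
    """
    cov = dummy_code(covariates.copy())
    missing = [c for c in test_cols + adjust_cols if c not in cov.columns]
    if missing:
        raise ValueError(f"covariate columns not found after dummy coding: {missing}")
    if set(table.sample_ids) != set(cov.index):
        raise ValueError("sample ids of the feature table and covariates do not match")
    cov = cov.loc[table.sample_ids]

    na_rows = cov[test_cols + adjust_cols].isna().any(axis=1)
    if na_rows.any():
        logger.info("dropping %d samples with missing covariates", int(na_rows.sum()))
    keep_samples = [s for s, bad in zip(table.sample_ids, na_rows) if not bad]
    keep_idx = [table.sample_ids.index(s) for s in keep_samples]
    table = FeatureTable(
        counts=table.counts[:, keep_idx],
        feature_ids=table.feature_ids,
        sample_ids=keep_samples,
    )
    cov = cov.loc[keep_samples]

    filtered = filter_features(table, max_zero_prop)
    Z = cov[test_cols].to_numpy(dtype=float)
    C = cov[adjust_cols].to_numpy(dtype=float)
    if add_library_size:
        C = np.column_stack([C, library_size_covariate(filtered)])

    rng = np.random.default_rng(seed)
    records = []
    for i, fid in enumerate(filtered.feature_ids):
        counts = filtered.counts[i]
        row = {
            "feature_id": fid,
            "n_positive": int((counts > 0).sum()),
            "zero_prop": float((counts == 0).mean()),
        }
        try:
            y = jitter_counts(counts, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = ziqsir_test(
                    y, Z, C, grid=grid, mode=mode,
                    n_permutations=n_permutations,
                    seed=int(rng.integers(2**31 - 1)),
                    fit_config=fit_config,
                )
            row["p_logistic"] = res.p_logistic
            for tau, p in zip(grid, res.p_quantile):
                row[f"p_q_{tau}"] = float(p)
            row["p_combined"] = res.p_combined
            row["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - batch runs must not abort
            logger.warning("feature %s failed: %s", fid, exc)
            row["p_logistic"] = np.nan
            for tau in grid:
                row[f"p_q_{tau}"] = np.nan
            row["p_combined"] = np.nan
            row["status"] = f"failed: {exc}"
        records.append(row)

    out = pd.DataFrame.from_records(records)
    out["q_value"] = bh_adjust(out["p_combined"].to_numpy())
    return out
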