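"""Multiple imputation of missing cost data and Rubin's-rules pooling.

Missing quarterly cost cells are imputed by chained equations with predictive
mean matching (PMM), which replaces each missing value with an *observed*
donor value whose regression-predicted mean is closest — imputations
therefore always lie within the observed support, which is the property that
makes PMM suitable for right-skewed cost data.  The chain visits the target
columns in their declared order (a fixed, documented choice), regressing each
on the fully observed predictors plus the current values of the other target
columns.  Type-1 PMM is used: the coefficient vector is perturbed by a draw
from its large-sample posterior before predicting the missing cases, so that
imputations vary across the m datasets and Rubin's between-imputation
variance is non-degenerate.

Downstream estimates from the m completed datasets are pooled with Rubin's
rules: pooled estimate = mean of the per-dataset estimates; total variance
T = W + (1 + 1/m) B with W the mean within-dataset variance and B the sample
variance of the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ImputationSpec", "PooledResult", "mice_pmm", "pool_rubin"]


@dataclass
class ImputationSpec:
    """Settings for the chained-equation PMM imputation.

    ``predictors`` are baseline variables assumed fully observed (case-mix
    scores and the care-model label in this pipeline); ``matching_pool_size``
    is the number of nearest donors from which one is drawn uniformly.
    """

    m: int = 10
    predictors: tuple[str, ...] = ()
    matching_pool_size: int = 5
    n_iter: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.matching_pool_size < 1:
            raise ValueError("matching_pool_size must be >= 1")


@dataclass
class PooledResult:
    """Rubin's-rules combination of m per-dataset estimates."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    m: int


def _design_matrix(frame: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    X = frame[list(columns)].to_numpy(dtype=float)
    # Cells that are NaN but outside the imputation mask (e.g. rule-determined
    # post-transition cells) must not poison the regressions: mean-fill them.
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        nan_idx = np.where(np.isnan(X))
        X[nan_idx] = col_means[nan_idx[1]]
    return np.column_stack([np.ones(len(frame)), X])


def _pmm_column(
    y: np.ndarray,
    X: np.ndarray,
    obs: np.ndarray,
    mis: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Impute the ``mis`` entries of y by type-1 PMM; returns donor values."""
    X_obs, y_obs = X[obs], y[obs]
    n_obs, p = X_obs.shape
    beta, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta
    rss = float(resid @ resid)
    df = n_obs - rank
    if df > 0 and rss > 0:
        sigma2_star = rss / rng.chisquare(df)
        XtX = X_obs.T @ X_obs
        cov = np.linalg.pinv(XtX) * sigma2_star
        try:
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
            beta_star = beta + L @ rng.standard_normal(p)
        except np.linalg.LinAlgError:
            beta_star = beta
    else:
        # Saturated or exact fit: no posterior spread to draw from.
        beta_star = beta
    eta_obs = X_obs @ beta
    eta_mis = X[mis] @ beta_star
    # k nearest observed predicted means per missing case; draw one donor.
    dist = np.abs(eta_obs[None, :] - eta_mis[:, None])
    k_eff = min(k, n_obs)
    pool = np.argpartition(dist, k_eff - 1, axis=1)[:, :k_eff]
    choice = rng.integers(0, k_eff, size=len(eta_mis))
    donors = pool[np.arange(len(eta_mis)), choice]
    return y_obs[donors]


def mice_pmm(
    data: pd.DataFrame,
    target_cols: Sequence[str],
    spec: ImputationSpec,
    mask: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> list[pd.DataFrame]:
    """Chained-equation PMM imputation; returns ``spec.m`` completed datasets.

    ``mask`` optionally restricts which NaN cells are imputation targets
    (cells outside the mask are left untouched — used to exclude cells whose
    value is determined by the halfway-transition rule rather than by data).
    The m datasets differ only in the imputed cells, and the whole procedure
    is deterministic under the seed.  A target column with no observed value
    has no donors and is an error.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    target_cols = list(target_cols)
    missing_in = {}
    for col in target_cols:
        if col not in data.columns:
            raise KeyError(f"target column {col!r} not in data")
        isna = data[col].isna().to_numpy()
        if mask is not None:
            isna = isna & mask[col].to_numpy()
        if isna.any():
            observed = data[col].notna().to_numpy()
            if not observed.any():
                raise ValueError(f"column {col!r} is 100% missing: no donors")
            missing_in[col] = isna
    for col in spec.predictors:
        if data[col].isna().any():
            raise ValueError(f"predictor {col!r} has missing values")

    completed: list[pd.DataFrame] = []
    child_rngs = rng.spawn(spec.m)
    for d in range(spec.m):
        sub_rng = child_rngs[d]
        work = data.copy()
        if not missing_in:
            completed.append(work)
            continue
        # Initial fill: random draws from each column's observed values.
        for col, isna in missing_in.items():
            obs_vals = data.loc[~data[col].isna(), col].to_numpy(dtype=float)
            work.loc[isna, col] = sub_rng.choice(obs_vals, size=int(isna.sum()))
        for _ in range(spec.n_iter):
            for col, isna in missing_in.items():
                other_targets = [c for c in target_cols if c != col]
                X = _design_matrix(work, list(spec.predictors) + other_targets)
                y = work[col].to_numpy(dtype=float)
                obs = ~data[col].isna().to_numpy()
                imputed = _pmm_column(
                    y, X, obs, isna, spec.matching_pool_size, sub_rng
                )
                work.loc[isna, col] = imputed
        completed.append(work)
    return completed


def pool_rubin(
    estimates: Sequence[float], variances: Sequence[float]
) -> PooledResult:
    """Combine m point estimates and their variances by Rubin's rules."""
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if estimates.shape != variances.shape:
        raise ValueError("estimates and variances must have equal length")
    m = len(estimates)
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2 estimates")
    estimate = float(estimates.mean())
    within = float(variances.mean())
    between = float(estimates.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    return PooledResult(
        estimate=estimate,
        within_var=within,
        between_var=between,
        total_var=total,
        m=m,
    )
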