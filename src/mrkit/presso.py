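"""MR-PRESSO: global pleiotropy test, per-SNP outlier test, re-estimation.

The observed residual sum of squares is

    RSS_obs = sum_j w_j * (beta_Y,j - theta_hat_{-j} * beta_X,j)^2,

with w_j = 1/se_Y,j^2 and theta_hat_{-j} the IVW estimate computed without
SNP j.  Its null distribution is built by a parametric bootstrap:
beta*_X,j ~ N(beta_X,j, se_X,j^2) and beta*_Y,j ~ N(theta_hat_{-j} *
beta_X,j, se_Y,j^2), re-deriving the leave-one-out estimates within each
draw.  The global p-value uses the add-one estimator
(1 + #{RSS* >= RSS_obs}) / (n_sim + 1), so it is never smaller than
1/(n_sim+1).  Per-SNP outlier p-values compare each observed weighted
residual with its simulated distribution using the raw exceedance
fraction (zero allowed, as in the reference implementation — an add-one
floor would make a Bonferroni-adjusted p below alpha unattainable at the
default simulation count) and are Bonferroni-adjusted over the J SNPs.
The distortion test of the original method is not provided; the
outlier-corrected IVW re-estimate on the retained SNPs is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import MrEstimate, ivw, _frame
from .exceptions import EstimationError

__all__ = ["PressoResult", "presso_global", "presso_outliers", "presso_corrected", "presso"]


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    n_sim: int
    outlier_pvals: pd.Series | None = None  #: Bonferroni-adjusted, indexed by snp_id
    outliers: list[str] = field(default_factory=list)
    corrected_estimate: MrEstimate | None = None
    removed_snps: list[str] = field(default_factory=list)


def _loo_theta(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates for every SNP at once (possibly batched).

    Accepts 1-D arrays (J,) or 2-D arrays (n_sim, J); returns the same shape.
    """
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    num = s_xy - w * bx * by
    den = s_xx - w * bx * bx
    return num / den


def _prepare(harmonized):
    df = _frame(harmonized)
    if len(df) < 4:
        raise EstimationError("MR-PRESSO requires at least 4 SNPs")
    if "snp_id" in df:
        # sort so simulated draws (hence p-values) ignore input row order
        df = df.sort_values("snp_id", kind="mergesort").reset_index(drop=True)
    bx = df["beta_exposure"].to_numpy(dtype=float)
    sx = df["se_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    snp = (df["snp_id"].astype(str).to_numpy() if "snp_id" in df
           else np.array([str(i) for i in range(len(df))]))
    return df, bx, sx, by, sy, snp


def _simulate(bx, sx, by, sy, n_sim, seed, include_exposure_uncertainty):
    """Observed and simulated weighted residuals; shared by global and outlier tests."""
    w = 1.0 / sy ** 2
    theta_loo = _loo_theta(bx, by, w)
    resid_obs = w * (by - theta_loo * bx) ** 2
    rng = np.random.default_rng(seed)
    if include_exposure_uncertainty:
        bx_sim = rng.normal(bx, sx, size=(n_sim, len(bx)))
    else:
        bx_sim = np.broadcast_to(bx, (n_sim, len(bx))).copy()
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, len(bx)))
    theta_loo_sim = _loo_theta(bx_sim, by_sim, w)
    resid_sim = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    return resid_obs, resid_sim


def presso_global(harmonized, n_sim: int = 1000, seed: int | None = None, *,
                  include_exposure_uncertainty: bool = True) -> PressoResult:
    """Global test: is the observed RSS extreme against its parametric null?"""
    if seed is None:
        raise EstimationError("presso_global requires an explicit seed")
    if n_sim < 1000:
        raise EstimationError("n_sim must be >= 1000")
    _, bx, sx, by, sy, _ = _prepare(harmonized)
    resid_obs, resid_sim = _simulate(bx, sx, by, sy, n_sim, seed,
                                     include_exposure_uncertainty)
    rss_obs = float(resid_obs.sum())
    rss_sim = resid_sim.sum(axis=1)
    pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)
    return PressoResult(rss_obs=rss_obs, global_pval=float(pval), n_sim=n_sim)


def presso_outliers(harmonized, n_sim: int = 1000, seed: int | None = None,
                    alpha: float = 0.05, *,
                    include_exposure_uncertainty: bool = True) -> PressoResult:
    """Per-SNP outlier test using the same simulation draws as the global test.

    Intended to run after a significant global test (the caller enforces
    that, or overrides deliberately).  SNPs whose Bonferroni-adjusted
    p-value falls below ``alpha`` are flagged.
    """
    if seed is None:
        raise EstimationError("presso_outliers requires an explicit seed")
    if n_sim < 1000:
        raise EstimationError("n_sim must be >= 1000")
    _, bx, sx, by, sy, snp = _prepare(harmonized)
    j = len(bx)
    resid_obs, resid_sim = _simulate(bx, sx, by, sy, n_sim, seed,
                                     include_exposure_uncertainty)
    counts = np.sum(resid_sim >= resid_obs, axis=0)
    raw = counts / float(n_sim)
    adjusted = np.minimum(raw * j, 1.0)
    pvals = pd.Series(adjusted, index=snp, name="presso_outlier_pval")
    outliers = sorted(pvals.index[pvals < alpha])
    rss_obs = float(resid_obs.sum())
    rss_sim = resid_sim.sum(axis=1)
    global_pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)
    return PressoResult(rss_obs=rss_obs, global_pval=float(global_pval), n_sim=n_sim,
                        outlier_pvals=pvals, outliers=list(outliers))


def presso_corrected(harmonized, outliers: list[str]) -> MrEstimate:
    """IVW re-estimate after removing the flagged outliers."""
    df = _frame(harmonized)
    snp = df["snp_id"].astype(str)
    unknown = set(outliers) - set(snp)
    if unknown:
        raise EstimationError(f"outliers not present in the dataset: {sorted(unknown)}")
    kept = df[~snp.isin(outliers)]
    if len(kept) < 2:
        raise EstimationError("fewer than 2 SNPs remain after outlier removal")
    est, _ = ivw(kept)
    return est


def presso(harmonized, n_sim: int = 1000, seed: int | None = None,
           alpha: float = 0.05, *,
           include_exposure_uncertainty: bool = True) -> PressoResult:
    """Full MR-PRESSO sequence: global test, then (if significant at
    ``alpha``) per-SNP outlier identification and corrected re-estimation."""
    result = presso_outliers(harmonized, n_sim=n_sim, seed=seed, alpha=alpha,
                             include_exposure_uncertainty=include_exposure_uncertainty)
    if result.global_pval >= alpha:
        result.outliers = []
        result.outlier_pvals = None
        return result
    if result.outliers:
        result.corrected_estimate = presso_corrected(harmonized, result.outliers)
        result.removed_snps = list(result.outliers)
    return result
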