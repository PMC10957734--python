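"""Univariable two-sample MR estimators and sensitivity statistics.

All estimators consume a :class:`~mrkit.gwas_io.HarmonizedDataset` (or any
DataFrame with beta_exposure / se_exposure / beta_outcome / se_outcome
columns).  Conventions, chosen to match the dominant practice for summary-
data MR:

* IVW is the inverse-variance-weighted meta-analysis of Wald ratios,
  identical to the zero-intercept weighted regression of outcome on
  exposure betas with weights 1/se_outcome^2.  "Random-effects" means
  multiplicative overdispersion: the fixed-effect SE is inflated by
  sqrt(Q/(J-1)) whenever that factor exceeds 1 (two-sided normal p).
* MR-Egger adds an intercept (the average directional pleiotropy) after
  orienting every SNP to a non-negative exposure effect; SEs carry the same
  multiplicative overdispersion floor and p-values use a t distribution
  with J-2 degrees of freedom.
* The weighted median interpolates the inverse-variance-weighted ratio
  distribution at cumulative weight 1/2; its SE comes from a seeded
  parametric bootstrap.
* Wald-ratio SEs use the first-order delta approximation
  se_outcome/|beta_exposure| (set ``second_order=True`` to add the
  exposure-uncertainty term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError
from .gwas_io import HarmonizedDataset, OddsRatio, to_odds_ratio

__all__ = [
    "MrEstimate", "HeterogeneityResult", "WaldRatios", "LeaveOneOutResult",
    "wald_ratios", "ivw", "mr_egger", "weighted_median", "cochrans_q",
    "leave_one_out",
]


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate on the log-odds (or linear) scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    or_ci: OddsRatio

    @classmethod
    def build(cls, method: str, beta: float, se: float, pval: float,
              n_snps: int, level: float = 0.95) -> "MrEstimate":
        return cls(method=method, beta=float(beta), se=float(se), pval=float(pval),
                   n_snps=int(n_snps), or_ci=to_odds_ratio(beta, se, level))


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q (against a given estimate) and the MR-Egger intercept test."""

    q_stat: float
    df: int
    pval: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None


@dataclass
class WaldRatios:
    """Per-SNP ratio estimates beta_outcome/beta_exposure with delta SEs."""

    snp_id: np.ndarray
    ratio: np.ndarray
    se: np.ndarray
    n_dropped_zero_beta: int


@dataclass
class LeaveOneOutResult:
    """IVW re-estimates, each omitting one SNP."""

    table: pd.DataFrame  # omitted_snp, beta, se, pval, sign_change, outside_full_ci
    full: MrEstimate

    @property
    def influential(self) -> list[str]:
        flagged = self.table["sign_change"] | self.table["outside_full_ci"]
        return list(self.table.loc[flagged, "omitted_snp"])


def _frame(h) -> pd.DataFrame:
    df = h.data if isinstance(h, HarmonizedDataset) else h
    required = {"beta_exposure", "se_exposure", "beta_outcome", "se_outcome"}
    missing = required - set(df.columns)
    if missing:
        raise EstimationError(f"harmonized data lacks columns: {sorted(missing)}")
    return df


def wald_ratios(harmonized, *, second_order: bool = False) -> WaldRatios:
    """Per-SNP causal-effect ratios; SNPs with beta_exposure == 0 are dropped."""
    df = _frame(harmonized)
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    nonzero = bx != 0.0
    if not nonzero.any():
        raise EstimationError("all exposure betas are zero; no Wald ratio is defined")
    bx_k, by_k, sy_k = bx[nonzero], by[nonzero], sy[nonzero]
    ratio = by_k / bx_k
    se = sy_k / np.abs(bx_k)
    if second_order:
        sx_k = df["se_exposure"].to_numpy(dtype=float)[nonzero]
        se = np.sqrt(sy_k ** 2 / bx_k ** 2 + by_k ** 2 * sx_k ** 2 / bx_k ** 4)
    snp = (df["snp_id"].to_numpy() if "snp_id" in df
           else np.arange(len(df)))[nonzero]
    return WaldRatios(snp_id=snp, ratio=ratio, se=se,
                      n_dropped_zero_beta=int((~nonzero).sum()))


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Point estimate, fixed-effect SE and Q for inverse-variance weighting."""
    w = 1.0 / sy ** 2
    s_xy = float(np.sum(w * bx * by))
    s_xx = float(np.sum(w * bx * bx))
    if s_xx == 0.0:
        raise EstimationError("all exposure betas are zero; IVW undefined")
    theta = s_xy / s_xx
    se_fixed = 1.0 / np.sqrt(s_xx)
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, se_fixed, q


def ivw(harmonized, *, random_effects: str = "multiplicative",
        level: float = 0.95) -> tuple[MrEstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with heterogeneity statistics.

    ``random_effects`` is one of ``"multiplicative"`` (default: SE scaled
    by max(1, sqrt(Q/(J-1)))), ``"additive"`` (DerSimonian-Laird tau^2
    added to the per-SNP ratio variances) or ``"fixed"``.
    """
    df = _frame(harmonized)
    if len(df) < 2:
        raise EstimationError("IVW requires at least 2 SNPs")
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    theta, se_fixed, q = _ivw_core(bx, by, sy)
    j = len(df)
    dof = j - 1
    q_pval = float(stats.chi2.sf(q, dof))

    if random_effects == "multiplicative":
        scale = max(1.0, np.sqrt(q / dof))
        se = se_fixed * scale
    elif random_effects == "fixed":
        se = se_fixed
    elif random_effects == "additive":
        wr = wald_ratios(df)
        w = 1.0 / wr.se ** 2
        tau2 = max(0.0, (q - dof) / (np.sum(w) - np.sum(w ** 2) / np.sum(w)))
        w_star = 1.0 / (wr.se ** 2 + tau2)
        theta = float(np.sum(w_star * wr.ratio) / np.sum(w_star))
        se = float(1.0 / np.sqrt(np.sum(w_star)))
    else:
        raise EstimationError(f"unknown random_effects mode: {random_effects!r}")

    pval = 2.0 * float(stats.norm.sf(abs(theta) / se)) if se > 0 else (0.0 if theta else 1.0)
    est = MrEstimate.build("ivw", theta, se, min(pval, 1.0), j, level)
    het = HeterogeneityResult(q_stat=q, df=dof, pval=q_pval)
    return est, het


def mr_egger(harmonized, *, level: float = 0.95) -> tuple[MrEstimate, HeterogeneityResult]:
    """MR-Egger regression: slope = causal effect, intercept = average
    directional pleiotropy, tested with J-2 df."""
    df = _frame(harmonized)
    j = len(df)
    if j < 3:
        raise EstimationError("MR-Egger requires at least 3 SNPs")
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = sign * bx, sign * by

    w = 1.0 / sy ** 2
    sw = np.sum(w)
    swx = np.sum(w * bx)
    swy = np.sum(w * by)
    swxx = np.sum(w * bx * bx)
    swxy = np.sum(w * bx * by)
    det = sw * swxx - swx ** 2
    if det <= 0:
        raise EstimationError("degenerate exposure betas; MR-Egger undefined")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    resid = by - intercept - slope * bx
    rss = float(np.sum(w * resid ** 2))
    sigma2 = rss / (j - 2)
    scale = max(1.0, np.sqrt(sigma2))
    se_slope = np.sqrt(sw / det) * scale
    se_intercept = np.sqrt(swxx / det) * scale

    tdist = stats.t(j - 2)
    p_slope = 2.0 * float(tdist.sf(abs(slope) / se_slope)) if se_slope > 0 else 1.0
    p_intercept = (2.0 * float(tdist.sf(abs(intercept) / se_intercept))
                   if se_intercept > 0 else 1.0)
    est = MrEstimate.build("mr_egger", slope, se_slope, p_slope, j, level)
    het = HeterogeneityResult(
        q_stat=rss, df=j - 2, pval=float(stats.chi2.sf(rss, j - 2)),
        egger_intercept=float(intercept), egger_intercept_se=float(se_intercept),
        egger_intercept_pval=min(p_intercept, 1.0))
    return est, het


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="mergesort")
    r, w = ratio[order], weight[order]
    s = (np.cumsum(w) - w / 2.0) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(harmonized, n_boot: int = 1000, seed: int | None = None, *,
                    level: float = 0.95) -> MrEstimate:
    """Weighted-median estimate: consistent when valid instruments carry
    more than half of the inverse-variance weight.

    The SE comes from a parametric bootstrap (``n_boot`` draws of the
    exposure and outcome betas from their sampling distributions); the
    ``seed`` is mandatory so the SE is reproducible.
    """
    if seed is None:
        raise EstimationError("weighted_median requires an explicit bootstrap seed")
    if n_boot < 100:
        raise EstimationError("n_boot must be >= 100")
    df = _frame(harmonized)
    if len(df) < 3:
        raise EstimationError("weighted median requires at least 3 SNPs")
    wr = wald_ratios(df)
    weight = 1.0 / wr.se ** 2
    point = _weighted_median_point(wr.ratio, weight)

    sub = df[df["beta_exposure"] != 0.0]
    bx = sub["beta_exposure"].to_numpy(dtype=float)
    sx = sub["se_exposure"].to_numpy(dtype=float)
    by = sub["beta_outcome"].to_numpy(dtype=float)
    sy = sub["se_outcome"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    j = len(bx)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0.0
        ratio_b = by_b[ok] / bx_b[ok]
        weight_b = bx_b[ok] ** 2 / sy[ok] ** 2
        boots[b] = _weighted_median_point(ratio_b, weight_b)
    se = float(np.std(boots, ddof=1))
    pval = 2.0 * float(stats.norm.sf(abs(point) / se)) if se > 0 else (0.0 if point else 1.0)
    return MrEstimate.build("weighted_median", point, se, min(pval, 1.0), j, level)


def cochrans_q(harmonized, theta: float) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios about ``theta`` (chi-square, J-1 df)."""
    wr = wald_ratios(harmonized)
    if len(wr.ratio) < 2:
        raise EstimationError("Cochran's Q requires at least 2 SNPs")
    w = 1.0 / wr.se ** 2
    q = float(np.sum(w * (wr.ratio - theta) ** 2))
    dof = len(wr.ratio) - 1
    return HeterogeneityResult(q_stat=q, df=dof, pval=float(stats.chi2.sf(q, dof)))


def leave_one_out(harmonized, *, random_effects: str = "multiplicative",
                  level: float = 0.95) -> LeaveOneOutResult:
    """One IVW estimate per omitted SNP, flagging influential omissions.

    An omission is flagged when it changes the estimate's sign or moves it
    outside the full-set confidence interval.
    """
    df = _frame(harmonized).reset_index(drop=True)
    if len(df) < 3:
        raise EstimationError("leave-one-out requires at least 3 SNPs")
    full, _ = ivw(df, random_effects=random_effects, level=level)
    z = stats.norm.ppf((1 + level) / 2)
    lo, hi = full.beta - z * full.se, full.beta + z * full.se
    rows = []
    snp_ids = df["snp_id"] if "snp_id" in df else pd.Series(range(len(df)))
    for i in range(len(df)):
        est, _ = ivw(df.drop(index=i), random_effects=random_effects, level=level)
        rows.append({
            "omitted_snp": snp_ids.iloc[i],
            "beta": est.beta, "se": est.se, "pval": est.pval,
            "sign_change": bool(np.sign(est.beta) != np.sign(full.beta) and full.beta != 0),
            "outside_full_ci": bool(est.beta < lo or est.beta > hi),
        })
    return LeaveOneOutResult(table=pd.DataFrame(rows), full=full)
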