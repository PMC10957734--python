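"""Multivariable MR and two-step mediation with delta-method inference.

Multivariable IVW regresses the SNP-outcome effects jointly on the
SNP-effect columns of E exposures (no intercept, weights 1/se_outcome^2),
yielding each exposure's *direct* effect holding the others fixed.  With a
single exposure it reduces exactly to univariable IVW (same multiplicative
overdispersion floor, same normal p-value).

Two-step mediation multiplies the exposure->mediator effect (beta1) by the
mediator->outcome effect (beta2, by default the mediator's direct effect
from multivariable IVW adjusting for the exposure) into the indirect
effect beta1*beta2.  First-order delta method throughout, with zero
covariance assumed between the two steps (separate instrument sets and
non-overlapping samples):

    Var(beta1*beta2) = beta1^2 Var(beta2) + beta2^2 Var(beta1)
    Var(P) = P^2 (Var(ind)/ind^2 + Var(total)/total^2),  P = ind/total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrEstimate, ivw
from .exceptions import EstimationError, HarmonizationError
from .gwas_io import harmonize
from .instruments import clump, select_instruments

__all__ = [
    "MvmrDataset", "MediationResult", "mvmr_ivw", "build_mvmr_dataset",
    "two_step_mediation", "run_mediation",
]


@dataclass
class MvmrDataset:
    """Per-SNP outcome effects plus one beta column per exposure, all
    aligned to a common effect allele."""

    snp_id: np.ndarray
    exposure_labels: list[str]
    exposure_betas: np.ndarray        # (J, E)
    beta_outcome: np.ndarray          # (J,)
    se_outcome: np.ndarray            # (J,)
    exposure_ses: np.ndarray | None = None  # (J, E), for conditional-F diagnostics

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, dtype=float))
        if self.exposure_betas.shape[0] == 1 and len(self.beta_outcome) > 1:
            self.exposure_betas = self.exposure_betas.T
        if np.isnan(self.exposure_betas).any():
            raise EstimationError("MVMR dataset contains missing exposure betas")

    @property
    def n_snps(self) -> int:
        return len(self.beta_outcome)

    @property
    def n_exposures(self) -> int:
        return self.exposure_betas.shape[1]


@dataclass
class MediationResult:
    """Two-step mediation decomposition with delta-method inference."""

    beta1: float
    se1: float
    beta2: float
    se2: float
    total: float
    se_total: float
    indirect: float
    indirect_se: float
    indirect_pval: float
    proportion: float          # NaN when total == 0
    proportion_se: float
    proportion_ci: tuple[float, float]
    proportion_pval: float
    level: float = 0.95
    provenance: dict = field(default_factory=dict)


def mvmr_ivw(dataset: MvmrDataset, *, level: float = 0.95
             ) -> tuple[list[MrEstimate], dict]:
    """Multivariable IVW: one direct-effect estimate per exposure.

    Returns the per-exposure estimates and a diagnostics dict holding the
    overdispersion scale and, when exposure SEs are available, a
    conditional instrument-strength heuristic per exposure (the weak-
    instrument warning metric).
    """
    x = dataset.exposure_betas
    y = np.asarray(dataset.beta_outcome, dtype=float)
    sy = np.asarray(dataset.se_outcome, dtype=float)
    j, e = x.shape
    if j <= e + 1:
        raise EstimationError("MVMR requires more SNPs than exposures plus one")
    w = 1.0 / sy ** 2
    xtwx = x.T @ (w[:, None] * x)
    cond = np.linalg.cond(xtwx)
    if not np.isfinite(cond) or cond > 1e12:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            f"{dataset.exposure_labels[a]}~{dataset.exposure_labels[b]}"
            for a in range(e) for b in range(a + 1, e)
            if abs(corr[a, b]) > 0.999
        ]
        raise EstimationError(
            "rank-deficient exposure matrix"
            + (f" (collinear: {', '.join(pairs)})" if pairs else ""))
    xtwy = x.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - x @ coef
    rss = float(np.sum(w * resid ** 2))
    sigma2 = rss / (j - e)
    scale2 = max(1.0, sigma2)
    cov = np.linalg.inv(xtwx) * scale2
    ses = np.sqrt(np.diag(cov))

    estimates = []
    for i, label in enumerate(dataset.exposure_labels):
        pval = 2.0 * float(stats.norm.sf(abs(coef[i]) / ses[i])) if ses[i] > 0 else 1.0
        est = MrEstimate.build(f"mvmr_ivw[{label}]", coef[i], ses[i],
                               min(pval, 1.0), j, level)
        estimates.append(est)

    diagnostics: dict = {"overdispersion_scale": float(np.sqrt(scale2)), "rss": rss}
    if dataset.exposure_ses is not None:
        cond_f = {}
        sx = np.asarray(dataset.exposure_ses, dtype=float)
        for i in range(e):
            others = np.delete(x, i, axis=1)
            target = x[:, i]
            if others.shape[1]:
                g = np.linalg.lstsq(np.sqrt(w)[:, None] * others,
                                    np.sqrt(w) * target, rcond=None)[0]
                r = target - others @ g
            else:
                r = target
            # heuristic conditional strength: mean squared residual signal per SNP
            cond_f[dataset.exposure_labels[i]] = float(
                np.sum(r ** 2 / sx[:, i] ** 2) / max(j - (e - 1), 1))
        diagnostics["conditional_f"] = cond_f
        diagnostics["weak_conditional"] = sorted(
            k for k, v in cond_f.items() if v <= 10)
    return estimates, diagnostics


def build_mvmr_dataset(exposure_tables: dict[str, pd.DataFrame],
                       outcome_table: pd.DataFrame, *,
                       p_threshold: float = 5e-8,
                       ld_matrix: pd.DataFrame | None = None,
                       r2_threshold: float = 0.001,
                       window_kb: float = 10_000,
                       palindrome_policy: str = "conservative",
                       eaf_threshold: float = 0.42,
                       instrument_from: list[str] | None = None) -> MvmrDataset:
    """Assemble an MVMR dataset from per-exposure summary tables.

    The instrument set is the union, over exposures, of genome-wide-
    significant SNPs, clumped across exposures when an LD matrix is given
    (keeping each region's smallest cross-exposure p-value), then
    harmonized exposure-by-exposure to the outcome.  SNPs missing from any
    exposure table are dropped so no exposure beta is missing.
    ``instrument_from`` restricts which exposures contribute instruments
    (e.g. only the mediator in a two-step mediation design).
    """
    labels = list(exposure_tables)
    if len(labels) < 1:
        raise EstimationError("at least one exposure table is required")
    sources = labels if instrument_from is None else list(instrument_from)
    unknown = set(sources) - set(labels)
    if unknown:
        raise EstimationError(f"instrument_from names unknown exposures: {sorted(unknown)}")
    selected: list[pd.DataFrame] = []
    for label in sources:
        hits = exposure_tables[label][exposure_tables[label]["pval"] < p_threshold]
        selected.append(hits)
    union = pd.concat(selected, ignore_index=True)
    if len(union) == 0:
        raise EstimationError("no exposure provides a genome-wide-significant SNP")
    union = union.sort_values("pval", kind="mergesort").drop_duplicates("snp_id")
    if ld_matrix is not None:
        union = clump(union, ld_matrix, r2_threshold=r2_threshold, window_kb=window_kb)
    instrument_ids = set(union["snp_id"].astype(str))

    # Align every exposure to the OUTCOME's effect allele so all beta columns
    # share one reference: harmonize(outcome, exposure) leaves the outcome
    # orientation fixed and flips the exposure onto it.
    outcome_sub = outcome_table[outcome_table["snp_id"].astype(str).isin(instrument_ids)]
    aligned: dict[str, pd.DataFrame] = {}
    for label in labels:
        h = harmonize(outcome_sub, exposure_tables[label],
                      palindrome_policy=palindrome_policy, eaf_threshold=eaf_threshold)
        aligned[label] = h.data.set_index("snp_id")
    shared = sorted(set.intersection(*(set(a.index) for a in aligned.values())))
    if not shared:
        raise HarmonizationError("no SNP is shared across all exposures after harmonization")
    first = aligned[labels[0]].loc[shared]
    betas = np.column_stack([aligned[lb].loc[shared, "beta_outcome"] for lb in labels])
    ses = np.column_stack([aligned[lb].loc[shared, "se_outcome"] for lb in labels])
    return MvmrDataset(
        snp_id=np.array(shared), exposure_labels=labels, exposure_betas=betas,
        beta_outcome=first["beta_exposure"].to_numpy(dtype=float),
        se_outcome=first["se_exposure"].to_numpy(dtype=float),
        exposure_ses=ses)


def two_step_mediation(beta1: float, se1: float, beta2: float, se2: float,
                       total: float, se_total: float, *,
                       second_order: bool = False,
                       level: float = 0.95) -> MediationResult:
    """Combine the two MR steps into indirect effect and proportion mediated.

    ``indirect = beta1*beta2`` with first-order delta variance
    ``beta1^2 se2^2 + beta2^2 se1^2`` (``second_order=True`` adds the
    exact-product ``se1^2 se2^2`` term); the proportion ``indirect/total``
    gets the delta variance for a ratio of independent estimates.  When
    ``total`` is zero the proportion fields are NaN (the indirect effect is
    still returned).
    """
    for name, se in (("se1", se1), ("se2", se2), ("se_total", se_total)):
        if se < 0:
            raise EstimationError(f"{name} must be >= 0")
    indirect = beta1 * beta2
    var_ind = beta1 ** 2 * se2 ** 2 + beta2 ** 2 * se1 ** 2
    if second_order:
        var_ind += se1 ** 2 * se2 ** 2
    se_ind = float(np.sqrt(var_ind))
    z_ind = abs(indirect) / se_ind if se_ind > 0 else np.inf
    p_ind = 2.0 * float(stats.norm.sf(z_ind)) if se_ind > 0 else (0.0 if indirect else 1.0)

    z = stats.norm.ppf((1 + level) / 2)
    if total == 0:
        prop = prop_se = prop_p = float("nan")
        ci = (float("nan"), float("nan"))
    else:
        prop = indirect / total
        if indirect == 0:
            # delta form degenerates at ind=0; variance from beta1*beta2/total directly
            var_prop = var_ind / total ** 2
        else:
            var_prop = prop ** 2 * (var_ind / indirect ** 2 + se_total ** 2 / total ** 2)
        prop_se = float(np.sqrt(var_prop))
        ci = (prop - z * prop_se, prop + z * prop_se)
        prop_p = (2.0 * float(stats.norm.sf(abs(prop) / prop_se))
                  if prop_se > 0 else (0.0 if prop else 1.0))
    return MediationResult(
        beta1=float(beta1), se1=float(se1), beta2=float(beta2), se2=float(se2),
        total=float(total), se_total=float(se_total),
        indirect=float(indirect), indirect_se=se_ind, indirect_pval=min(p_ind, 1.0),
        proportion=float(prop), proportion_se=float(prop_se),
        proportion_ci=(float(ci[0]), float(ci[1])),
        proportion_pval=float(min(prop_p, 1.0)) if not np.isnan(prop_p) else prop_p,
        level=level)


def run_mediation(exposure_stats: pd.DataFrame, mediator_stats: pd.DataFrame,
                  outcome_stats: pd.DataFrame, *,
                  p_threshold: float = 5e-8,
                  beta2_method: str = "mvmr",
                  ld_matrix: pd.DataFrame | None = None,
                  palindrome_policy: str = "conservative",
                  eaf_threshold: float = 0.42,
                  level: float = 0.95) -> MediationResult:
    """Two-step MR mediation from three summary tables.

    Step 1 estimates the exposure->mediator effect (beta1) by univariable
    IVW on the exposure's instruments.  Step 2 estimates the mediator->
    outcome effect (beta2); by default from multivariable IVW of the
    outcome on (mediator, exposure) over the union of both instrument
    sets, which blocks the reverse-pathway contamination of the mediator's
    instruments; ``beta2_method="univariable"`` uses a plain IVW on the
    mediator's instruments instead.  The total effect is the univariable
    exposure->outcome IVW.  All three are combined by the delta method.
    """
    if beta2_method not in ("mvmr", "univariable"):
        raise EstimationError(f"unknown beta2_method: {beta2_method!r}")
    kw = dict(palindrome_policy=palindrome_policy, eaf_threshold=eaf_threshold)
    provenance: dict = {"beta2_method": beta2_method, "p_threshold": p_threshold}

    def _instruments(table, label):
        try:
            hits = select_instruments(table, p_threshold)
        except Exception as err:
            raise type(err)(f"[{label}] {err}") from err
        if ld_matrix is not None:
            return clump(hits, ld_matrix)
        return hits

    exp_inst = _instruments(exposure_stats, "step1: exposure instruments")
    provenance["n_exposure_instruments"] = len(exp_inst)

    h1 = harmonize(exp_inst, mediator_stats, **kw)
    est1, _ = ivw(h1)
    provenance["n_step1_snps"] = h1.n_snps

    h_total = harmonize(exp_inst, outcome_stats, **kw)
    total_est, _ = ivw(h_total)
    provenance["n_total_snps"] = h_total.n_snps

    if beta2_method == "univariable":
        med_inst = _instruments(mediator_stats, "step2: mediator instruments")
        h2 = harmonize(med_inst, outcome_stats, **kw)
        est2, _ = ivw(h2)
        provenance["n_step2_snps"] = h2.n_snps
        beta2, se2 = est2.beta, est2.se
    else:
        ds = build_mvmr_dataset(
            {"mediator": mediator_stats, "exposure": exposure_stats},
            outcome_stats, p_threshold=p_threshold, ld_matrix=ld_matrix,
            palindrome_policy=palindrome_policy, eaf_threshold=eaf_threshold,
            instrument_from=["mediator"])
        estimates, diag = mvmr_ivw(ds)
        beta2, se2 = estimates[0].beta, estimates[0].se
        provenance["n_step2_snps"] = ds.n_snps
        provenance["mvmr_diagnostics"] = diag

    result = two_step_mediation(est1.beta, est1.se, beta2, se2,
                                total_est.beta, total_est.se, level=level)
    result.provenance.update(provenance)
    return result
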