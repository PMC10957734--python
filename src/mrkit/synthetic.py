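"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure a two-sample MR analysis
of biobank-scale summary data assumes: for SNP j with minor-allele
frequency p_j, the per-SNP standard error of a standardized-trait GWAS is
se = 1/sqrt(2 p_j (1-p_j) n), the observed SNP-exposure effect is
beta_X,j ~ N(gamma_j, se_X,j^2) and the observed SNP-outcome effect is
beta_Y,j ~ N(theta * gamma_j + alpha_j, se_Y,j^2), where theta is the causal
effect (log-odds per SD for a binary outcome) and alpha_j is any direct
(horizontally pleiotropic) SNP-outcome effect.  Case-control outcomes are
simulated directly on the log-odds scale; no individual-level genotypes are
drawn.

Pleiotropy modes
----------------
``none``            alpha_j = 0 for all SNPs.
``balanced``        alpha_j ~ N(0, pleiotropy_sd^2) on affected SNPs.
``directional``     alpha_j ~ N(pleiotropy_mean, pleiotropy_sd^2).
``inside_violated`` alpha_j = kappa * gamma_j + N(pleiotropy_mean,
                    pleiotropy_sd^2): direct effects correlated with
                    instrument strength, breaking the InSIDE assumption.

By default instruments are reported aligned to the exposure-increasing
allele (gamma_j >= 0), as published instrument lists conventionally are;
set ``orient_exposure_increasing=False`` for sign-symmetric effects.

A ``noiseless`` flag replaces every sampling step by its mean, so exact
oracle identities (all Wald ratios equal theta) hold to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import ConfigurationError

__all__ = [
    "MediatorSpec", "LdSpec", "SimulationConfig", "StudyTruth", "SyntheticStudy",
    "simulate_two_sample", "simulate_mediation_chain", "simulate_ld_panel",
    "load_simulation_config",
]

_NONPALINDROMIC = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


@dataclass(frozen=True)
class MediatorSpec:
    """Exposure -> mediator -> outcome chain parameters.

    beta_xm: exposure effect on the mediator (per SD); beta_my: mediator
    effect on the outcome; beta_direct: exposure effect on the outcome not
    through the mediator.  The implied true proportion mediated is
    beta_xm*beta_my / (beta_direct + beta_xm*beta_my).
    """

    beta_xm: float
    beta_my: float
    beta_direct: float
    n_mediator: int = 300_000
    n_mediator_instruments: int = 30

    def __post_init__(self) -> None:
        if self.n_mediator < 2:
            raise ConfigurationError("mediator_spec.n_mediator must be >= 2")
        if self.n_mediator_instruments < 0:
            raise ConfigurationError("mediator_spec.n_mediator_instruments must be >= 0")

    @property
    def proportion_mediated(self) -> float:
        total = self.beta_direct + self.beta_xm * self.beta_my
        if total == 0:
            return float("nan")
        return self.beta_xm * self.beta_my / total


@dataclass(frozen=True)
class LdSpec:
    """Block-diagonal LD structure: equal pairwise correlation rho within
    each block, zero across blocks.  Within-block SNPs are placed closer
    than a clumping window, across-block SNPs farther apart."""

    block_sizes: tuple[int, ...]
    rho: float
    within_block_spacing_bp: int = 100_000
    block_spacing_bp: int = 20_000_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if any(b < 1 for b in self.block_sizes):
            raise ConfigurationError("ld_spec.block_sizes entries must be >= 1")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigurationError("ld_spec.rho must lie in [-1, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic two-sample study.

    Defaults mirror a biobank-scale design: 60 independent instruments for
    an exposure GWAS of n=329,821, an outcome GWAS of n=403,124, and
    instrument effects sized so the set explains ~1% of exposure variance
    (mean per-SNP F around 50).
    """

    n_snps: int = 60
    n_exposure: int = 329_821
    n_outcome: int = 403_124
    theta: float = 0.0
    maf_low: float = 0.05
    maf_high: float = 0.45
    gamma_sd: float = 0.0219
    pleiotropy_mode: str = "none"
    pleiotropy_fraction: float = 1.0
    pleiotropy_mean: float = 0.0018
    pleiotropy_sd: float = 0.0
    kappa: float = 0.1
    n_outliers: int = 0
    outlier_shift: float = 0.0
    palindromic_fraction: float = 0.2
    allele_swap_fraction: float = 0.3
    orient_exposure_increasing: bool = True
    noiseless: bool = False
    mediator_spec: MediatorSpec | None = None
    ld_spec: LdSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 3:
            raise ConfigurationError("n_snps must be >= 3")
        for name in ("n_exposure", "n_outcome"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2")
        if not 0 < self.maf_low <= self.maf_high < 0.5:
            raise ConfigurationError("require 0 < maf_low <= maf_high < 0.5")
        if self.gamma_sd < 0:
            raise ConfigurationError("gamma_sd must be >= 0")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violated"):
            raise ConfigurationError(f"unknown pleiotropy_mode: {self.pleiotropy_mode!r}")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")
        if not 0 <= self.pleiotropy_fraction <= 1:
            raise ConfigurationError("pleiotropy_fraction must lie in [0, 1]")
        if self.n_outliers < 0 or self.n_outliers > self.n_snps:
            raise ConfigurationError("n_outliers must lie in [0, n_snps]")
        if not 0 <= self.palindromic_fraction <= 1:
            raise ConfigurationError("palindromic_fraction must lie in [0, 1]")
        if not 0 <= self.allele_swap_fraction <= 1:
            raise ConfigurationError("allele_swap_fraction must lie in [0, 1]")


@dataclass
class StudyTruth:
    """Generating parameters of a synthetic study, for oracle checks."""

    theta: float
    gamma: pd.Series
    alpha: pd.Series
    outlier_snps: list[str] = field(default_factory=list)
    proportion_mediated: float | None = None
    mediator_instruments: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None


@dataclass
class SyntheticStudy:
    """Summary-statistic tables for a simulated two-sample design."""

    exposure_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    mediator_stats: pd.DataFrame | None = None
    exposure2_stats: pd.DataFrame | None = None
    ld_matrix: pd.DataFrame | None = None
    truth: StudyTruth | None = None



def _streams(seed: int, noise_seed: int | None):
    """Two independent generators: study structure vs observation noise.

    The structure stream (MAF, true effects, pleiotropy, alleles, outlier
    placement, allele-swap masks) depends only on ``seed``; the noise
    stream drives the observed beta draws and can be varied independently
    via ``noise_seed`` to replicate a study with its architecture fixed.
    """
    rng_structure = np.random.default_rng(np.random.SeedSequence((int(seed), 11)))
    noise_key = int(seed) if noise_seed is None else int(noise_seed)
    rng_noise = np.random.default_rng(np.random.SeedSequence((noise_key, 13)))
    return rng_structure, rng_noise


def _draw_alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    pal = rng.random(n) < palindromic_fraction
    pairs = np.empty((n, 2), dtype=object)
    idx_p = rng.integers(0, len(_PALINDROMIC), size=n)
    idx_n = rng.integers(0, len(_NONPALINDROMIC), size=n)
    for i in range(n):
        pairs[i] = _PALINDROMIC[idx_p[i]] if pal[i] else _NONPALINDROMIC[idx_n[i]]
    return pairs[:, 0], pairs[:, 1]


def _wald_pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta) / se
    return 2.0 * stats.norm.sf(z)


def _per_snp_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _table(snp_id, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame({
        "snp_id": snp_id, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": _wald_pvals(np.asarray(beta), np.asarray(se)),
        "n": float(n),
    })


def _swap_orientation(table: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    """Report a subset of rows on the opposite allele (a statistical no-op)."""
    out = table.copy()
    ea = out["effect_allele"].to_numpy(copy=True)
    oa = out["other_allele"].to_numpy(copy=True)
    out.loc[mask, "effect_allele"] = oa[mask]
    out.loc[mask, "other_allele"] = ea[mask]
    out.loc[mask, "beta"] = -out.loc[mask, "beta"]
    out.loc[mask, "eaf"] = 1.0 - out.loc[mask, "eaf"]
    return out


def _draw_pleiotropy(rng: np.random.Generator, cfg: SimulationConfig,
                     gamma: np.ndarray) -> np.ndarray:
    j = len(gamma)
    alpha = np.zeros(j)
    if cfg.pleiotropy_mode == "none":
        return alpha
    n_affected = int(round(cfg.pleiotropy_fraction * j))
    affected = rng.choice(j, size=n_affected, replace=False)
    if cfg.pleiotropy_mode == "balanced":
        alpha[affected] = rng.normal(0.0, cfg.pleiotropy_sd, n_affected)
    elif cfg.pleiotropy_mode == "directional":
        alpha[affected] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n_affected)
    else:  # inside_violated
        alpha[affected] = (cfg.kappa * gamma[affected]
                           + rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n_affected))
    return alpha


def _maybe_noise(rng, mean, se, noiseless):
    return mean.copy() if noiseless else rng.normal(mean, se)


def simulate_two_sample(config: SimulationConfig,
                        noise_seed: int | None = None) -> SyntheticStudy:
    """Simulate exposure and outcome summary statistics for independent SNPs.

    Reproducible for a fixed ``config.seed``; with ``noiseless=True`` and no
    pleiotropy every Wald ratio equals ``theta`` exactly (after
    harmonization, since a fraction of outcome rows is reported on the
    opposite allele to exercise that step).
    """
    cfg = config
    rng, rng_noise = _streams(cfg.seed, noise_seed)
    j = cfg.n_snps
    snp_id = np.array([f"rs{i + 1}" for i in range(j)])
    chrom = np.array(["1"] * j)
    pos = (1 + np.arange(j) * 1_000_000).astype(int)

    maf = rng.uniform(cfg.maf_low, cfg.maf_high, j)
    gamma = rng.normal(0.0, cfg.gamma_sd, j)
    if cfg.orient_exposure_increasing:
        gamma = np.abs(gamma)
    alpha = _draw_pleiotropy(rng, cfg, gamma)
    ea, oa = _draw_alleles(rng, j, cfg.palindromic_fraction)

    se_x = _per_snp_se(maf, cfg.n_exposure)
    se_y = _per_snp_se(maf, cfg.n_outcome)
    beta_x = _maybe_noise(rng_noise, gamma, se_x, cfg.noiseless)
    mean_y = cfg.theta * gamma + alpha
    beta_y = _maybe_noise(rng_noise, mean_y, se_y, cfg.noiseless)

    outlier_snps: list[str] = []
    if cfg.n_outliers:
        which = rng.choice(j, size=cfg.n_outliers, replace=False)
        beta_y[which] = beta_y[which] + cfg.outlier_shift * se_y[which]
        outlier_snps = list(snp_id[which])

    exposure = _table(snp_id, chrom, pos, ea, oa, maf, beta_x, se_x, cfg.n_exposure)
    outcome = _table(snp_id, chrom, pos, ea, oa, maf, beta_y, se_y, cfg.n_outcome)
    swap = rng.random(j) < cfg.allele_swap_fraction
    outcome = _swap_orientation(outcome, swap)

    truth = StudyTruth(
        theta=cfg.theta,
        gamma=pd.Series(gamma, index=snp_id),
        alpha=pd.Series(alpha, index=snp_id),
        outlier_snps=outlier_snps,
        config=cfg,
    )
    return SyntheticStudy(exposure_stats=exposure, outcome_stats=outcome, truth=truth)


def simulate_mediation_chain(config: SimulationConfig,
                             noise_seed: int | None = None) -> SyntheticStudy:
    """Simulate an exposure -> mediator -> outcome chain.

    The shared pathway SNPs instrument the exposure; the mediator carries
    ``n_mediator_instruments`` additional SNPs of its own (effects ~
    N(0, gamma_sd^2) on the mediator only, reaching the outcome only
    through the mediator).  All three tables share the full SNP set, so
    genome-wide-significance screening behaves as it would on real data.
    """
    cfg = config
    if cfg.mediator_spec is None:
        raise ConfigurationError("mediator_spec is required for simulate_mediation_chain")
    med = cfg.mediator_spec
    rng, rng_noise = _streams(cfg.seed, noise_seed)

    j_x = cfg.n_snps
    j_m = med.n_mediator_instruments
    j = j_x + j_m
    snp_id = np.array([f"rs{i + 1}" for i in range(j)])
    chrom = np.array(["1"] * j)
    pos = (1 + np.arange(j) * 1_000_000).astype(int)

    maf = rng.uniform(cfg.maf_low, cfg.maf_high, j)
    gamma_x = np.zeros(j)
    gamma_x[:j_x] = rng.normal(0.0, cfg.gamma_sd, j_x)
    gamma_m_own = np.zeros(j)
    gamma_m_own[j_x:] = rng.normal(0.0, cfg.gamma_sd, j_m)
    if cfg.orient_exposure_increasing:
        gamma_x = np.abs(gamma_x)
        gamma_m_own = np.abs(gamma_m_own)
    alpha = np.zeros(j)
    alpha[:j_x] = _draw_pleiotropy(rng, cfg, gamma_x[:j_x])
    ea, oa = _draw_alleles(rng, j, cfg.palindromic_fraction)

    se_x = _per_snp_se(maf, cfg.n_exposure)
    se_m = _per_snp_se(maf, med.n_mediator)
    se_y = _per_snp_se(maf, cfg.n_outcome)

    mean_x = gamma_x
    mean_m = med.beta_xm * gamma_x + gamma_m_own
    total_effect = med.beta_direct + med.beta_xm * med.beta_my
    mean_y = total_effect * gamma_x + med.beta_my * gamma_m_own + alpha

    beta_x = _maybe_noise(rng_noise, mean_x, se_x, cfg.noiseless)
    beta_m = _maybe_noise(rng_noise, mean_m, se_m, cfg.noiseless)
    beta_y = _maybe_noise(rng_noise, mean_y, se_y, cfg.noiseless)

    exposure = _table(snp_id, chrom, pos, ea, oa, maf, beta_x, se_x, cfg.n_exposure)
    mediator = _table(snp_id, chrom, pos, ea, oa, maf, beta_m, se_m, med.n_mediator)
    outcome = _table(snp_id, chrom, pos, ea, oa, maf, beta_y, se_y, cfg.n_outcome)
    mediator = _swap_orientation(mediator, rng.random(j) < cfg.allele_swap_fraction)
    outcome = _swap_orientation(outcome, rng.random(j) < cfg.allele_swap_fraction)

    truth = StudyTruth(
        theta=total_effect,
        gamma=pd.Series(gamma_x, index=snp_id),
        alpha=pd.Series(alpha, index=snp_id),
        proportion_mediated=med.proportion_mediated,
        mediator_instruments=list(snp_id[j_x:]),
        config=cfg,
    )
    return SyntheticStudy(exposure_stats=exposure, outcome_stats=outcome,
                          mediator_stats=mediator, truth=truth)


def _block_correlation(block_sizes: tuple[int, ...], rho: float) -> np.ndarray:
    j = sum(block_sizes)
    r = np.eye(j)
    start = 0
    for size in block_sizes:
        r[start:start + size, start:start + size] = rho
        np.fill_diagonal(r[start:start + size, start:start + size], 1.0)
        start += size
    return r


def simulate_ld_panel(config: SimulationConfig,
                     noise_seed: int | None = None) -> SyntheticStudy:
    """Simulate SNPs in LD blocks, returning the LD matrix alongside.

    Each block carries one underlying causal signal; the marginal effect of
    a block member is its correlation with the block's lead SNP times the
    lead effect, and observed effects share correlated noise with the same
    LD structure, so clumping has real work to do.
    """
    cfg = config
    if cfg.ld_spec is None:
        raise ConfigurationError("ld_spec is required for simulate_ld_panel")
    ld = cfg.ld_spec
    if sum(ld.block_sizes) != cfg.n_snps:
        raise ConfigurationError("ld_spec.block_sizes must sum to n_snps")
    corr = _block_correlation(ld.block_sizes, ld.rho)
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-8:
        raise ConfigurationError("ld_spec implies a non-positive-semidefinite correlation")
    chol = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))

    rng, rng_noise = _streams(cfg.seed, noise_seed)
    j = cfg.n_snps
    snp_id = np.array([f"rs{i + 1}" for i in range(j)])
    chrom = np.array(["1"] * j)
    pos = np.empty(j, dtype=int)
    start = 0
    for b, size in enumerate(ld.block_sizes):
        pos[start:start + size] = (1 + b * ld.block_spacing_bp
                                   + np.arange(size) * ld.within_block_spacing_bp)
        start += size

    maf = rng.uniform(cfg.maf_low, cfg.maf_high, j)
    gamma = np.zeros(j)
    start = 0
    for size in ld.block_sizes:
        lead = rng.normal(0.0, cfg.gamma_sd)
        if cfg.orient_exposure_increasing:
            lead = abs(lead)
        gamma[start:start + size] = corr[start:start + size, start] * lead
        start += size
    alpha = _draw_pleiotropy(rng, cfg, gamma)

    se_x = _per_snp_se(maf, cfg.n_exposure)
    se_y = _per_snp_se(maf, cfg.n_outcome)
    if cfg.noiseless:
        beta_x, beta_y = gamma.copy(), cfg.theta * gamma + alpha
    else:
        beta_x = gamma + se_x * (chol @ rng_noise.standard_normal(j))
        beta_y = cfg.theta * gamma + alpha + se_y * (chol @ rng_noise.standard_normal(j))

    exposure = _table(snp_id, chrom, pos, *_draw_alleles(rng, j, cfg.palindromic_fraction),
                      maf, beta_x, se_x, cfg.n_exposure)
    outcome = exposure.copy()
    outcome["beta"] = beta_y
    outcome["se"] = se_y
    outcome["pval"] = _wald_pvals(beta_y, se_y)
    outcome["n"] = float(cfg.n_outcome)

    ld_matrix = pd.DataFrame(corr, index=snp_id, columns=snp_id)
    truth = StudyTruth(theta=cfg.theta, gamma=pd.Series(gamma, index=snp_id),
                       alpha=pd.Series(alpha, index=snp_id), config=cfg)
    return SyntheticStudy(exposure_stats=exposure, outcome_stats=outcome,
                          ld_matrix=ld_matrix, truth=truth)


def load_simulation_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML/JSON file whose keys are
    the config field names (``mediator_spec`` and ``ld_spec`` as mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("simulation config file must hold a mapping")
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation config field(s): {sorted(unknown)}")
    if raw.get("mediator_spec") is not None:
        raw["mediator_spec"] = MediatorSpec(**raw["mediator_spec"])
    if raw.get("ld_spec") is not None:
        spec = dict(raw["ld_spec"])
        spec["block_sizes"] = tuple(spec["block_sizes"])
        raw["ld_spec"] = LdSpec(**spec)
    return SimulationConfig(**raw)
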