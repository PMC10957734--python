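"""Reading, writing and harmonizing GWAS summary-statistic tables.

Summary statistics live in pandas DataFrames with the canonical columns

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

(`chrom`, `pos`, `eaf` and `n` optional).  ``beta`` is the per-effect-allele
association estimate: log-odds for binary traits, per-SD units for
quantitative traits.  :func:`harmonize` aligns an exposure and an outcome
table to a shared effect allele per SNP, which is the unit every estimator
in :mod:`mrkit.estimators` consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FormatError, HarmonizationError

__all__ = [
    "CANONICAL_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "GwasSummaryRecord",
    "LoadReport",
    "HarmonizedDataset",
    "OddsRatio",
    "read_summary_table",
    "write_summary_table",
    "harmonize",
    "to_odds_ratio",
]

#: Canonical column order for summary-statistic tables.
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

MANDATORY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval"]

#: Default source-column names (the common TwoSampleMR-style dialect).
#: Matching against a file header is case-insensitive.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "samplesize",
}

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class GwasSummaryRecord:
    """One SNP's association summary."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise FormatError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.snp_id}: effect and other allele are identical")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise FormatError(f"{self.snp_id}: eaf outside [0, 1]")


@dataclass
class LoadReport:
    """Row accounting for :func:`read_summary_table`."""

    n_read: int = 0
    n_kept: int = 0
    drop_count: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def add_drops(self, reason: str, count: int) -> None:
        if count:
            self.drop_count += count
            self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + count


#: Audit actions recorded by :func:`harmonize`.
HARMONY_ACTIONS = (
    "kept", "allele_flipped", "palindromic_kept",
    "palindromic_dropped", "incompatible_dropped",
)


@dataclass
class HarmonizedDataset:
    """Per-SNP exposure and outcome effects aligned to a common effect allele.

    ``data`` has columns snp_id, beta_exposure, se_exposure, beta_outcome,
    se_outcome, eaf; ``audit`` has one row per shared SNP with the action
    taken (kept / allele_flipped / palindromic_kept / palindromic_dropped /
    incompatible_dropped).
    """

    data: pd.DataFrame
    audit: pd.DataFrame

    @property
    def n_snps(self) -> int:
        return len(self.data)

    def action_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(HARMONY_ACTIONS, 0)
        counts.update(self.audit["action"].value_counts().to_dict())
        return counts

    @classmethod
    def from_arrays(cls, beta_exposure, se_exposure, beta_outcome, se_outcome,
                    snp_id=None, eaf=None) -> "HarmonizedDataset":
        """Build a dataset directly from aligned arrays (mostly for testing)."""
        beta_exposure = np.asarray(beta_exposure, dtype=float)
        j = len(beta_exposure)
        if snp_id is None:
            snp_id = [f"rs{i + 1}" for i in range(j)]
        data = pd.DataFrame({
            "snp_id": snp_id,
            "beta_exposure": beta_exposure,
            "se_exposure": np.asarray(se_exposure, dtype=float),
            "beta_outcome": np.asarray(beta_outcome, dtype=float),
            "se_outcome": np.asarray(se_outcome, dtype=float),
            "eaf": np.full(j, np.nan) if eaf is None else np.asarray(eaf, dtype=float),
        })
        audit = pd.DataFrame({"snp_id": snp_id, "action": "kept"})
        return cls(data=data, audit=audit)


@dataclass(frozen=True)
class OddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def _resolve_columns(header: list[str], column_map: Mapping[str, str]) -> dict[str, str]:
    """Map canonical field names to actual header names, case-insensitively."""
    lower = {h.lower(): h for h in header}
    resolved = {}
    for canonical, source in column_map.items():
        actual = lower.get(source.lower(), lower.get(canonical.lower()))
        if actual is not None:
            resolved[canonical] = actual
    return resolved


def read_summary_table(source, column_map: Mapping[str, str] | None = None, *,
                       sep: str = "\t", allow_indels: bool = False,
                       ) -> tuple[pd.DataFrame, LoadReport]:
    """Read a delimited summary-statistics table into canonical form.

    Parameters
    ----------
    source
        Path or file-like object holding a delimited table with a header.
    column_map
        Canonical-field -> source-column mapping; defaults to the common
        ``SNP/effect_allele/other_allele/eaf/beta/se/pval/samplesize``
        dialect.  Header matching is case-insensitive.
    allow_indels
        Keep multi-base alleles (rejected by default; the estimators assume
        biallelic SNPs).

    Returns
    -------
    (table, report)
        The validated table in canonical column order and a
        :class:`LoadReport` counting dropped rows per reason.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(source, sep=sep, dtype={"SNP": str}, na_values=["NA", ""])
    if raw.shape[1] == 0 or len(raw) == 0 and raw.shape[1] == 0:
        raise FormatError("empty table")
    resolved = _resolve_columns(list(raw.columns), cmap)
    for col in MANDATORY_COLUMNS:
        if col not in resolved:
            raise FormatError(f"missing mandatory column: {cmap[col]!r} (field {col!r})")
    df = pd.DataFrame({canonical: raw[actual] for canonical, actual in resolved.items()})
    if len(df) == 0:
        raise FormatError("empty table")

    report = LoadReport(n_read=len(df))
    df["snp_id"] = df["snp_id"].astype(str)
    for allele_col in ("effect_allele", "other_allele"):
        df[allele_col] = df[allele_col].astype(str).str.upper()
    for num_col in ("beta", "se", "pval", "eaf", "n", "pos"):
        if num_col in df:
            df[num_col] = pd.to_numeric(df[num_col], errors="coerce")
    if "chrom" in df:
        df["chrom"] = df["chrom"].astype(str)

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        mask = mask.fillna(False) if mask.dtype == object else mask
        report.add_drops(reason, int(mask.sum()))
        df = df[~mask]

    _drop(df[["beta", "se", "pval"]].isna().any(axis=1), "missing_numeric_field")
    _drop(df["se"] <= 0, "nonpositive_se")
    _drop(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval_out_of_range")
    if "eaf" in df:
        _drop(df["eaf"].notna() & ~df["eaf"].between(0, 1), "eaf_out_of_range")
    valid_allele = df["effect_allele"].isin(_BASES) & df["other_allele"].isin(_BASES)
    if not allow_indels:
        _drop(~valid_allele, "non_biallelic_or_indel")
    _drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    _drop(df["snp_id"].duplicated(keep="first"), "duplicate_snp_id")

    report.n_kept = len(df)
    for col in CANONICAL_COLUMNS:
        if col not in df:
            df[col] = np.nan
    return df[CANONICAL_COLUMNS].reset_index(drop=True), report


def _format_float(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.10g}"


def write_summary_table(table: pd.DataFrame, sink) -> None:
    """Write a canonical summary-statistics TSV (floats at 10 significant digits)."""
    out = table.copy()
    for col in CANONICAL_COLUMNS:
        if col not in out:
            out[col] = np.nan
    out = out[CANONICAL_COLUMNS]
    for col in ("eaf", "beta", "se", "pval", "n"):
        out[col] = out[col].map(_format_float)
    out["pos"] = out["pos"].map(lambda x: "NA" if pd.isna(x) else str(int(x)))
    out["chrom"] = out["chrom"].map(lambda x: "NA" if pd.isna(x) or x == "nan" else str(x))
    out.to_csv(sink, sep="\t", index=False)


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a1 == a2.map(_COMPLEMENT)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame, *,
              palindrome_policy: str = "conservative",
              eaf_threshold: float = 0.42) -> HarmonizedDataset:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Matching is by ``snp_id``.  For each shared SNP:

    * same allele orientation -> kept;
    * swapped alleles -> outcome beta negated, eaf reflected (allele_flipped);
    * strand-complement (and complement+swap) orientations are reconciled
      the same way for non-palindromic SNPs;
    * palindromic SNPs (A/T, G/C) cannot be strand-resolved from alleles.
      Under policy ``"conservative"`` they are kept only when both allele
      frequencies fall on the same side of 0.5 and outside
      ``[eaf_threshold, 1 - eaf_threshold]``; policy ``"drop"`` always
      removes them;
    * irreconcilable allele sets are dropped (incompatible_dropped).

    Raises :class:`HarmonizationError` when no SNP is shared.
    """
    if palindrome_policy not in ("conservative", "drop"):
        raise HarmonizationError(f"unknown palindrome policy: {palindrome_policy!r}")
    merged = exposure.merge(outcome, on="snp_id", suffixes=("_exp", "_out"), how="inner")
    if len(merged) == 0:
        raise HarmonizationError("no shared SNPs between exposure and outcome tables")

    ea_e, oa_e = merged["effect_allele_exp"], merged["other_allele_exp"]
    ea_o, oa_o = merged["effect_allele_out"], merged["other_allele_out"]
    ea_oc, oa_oc = ea_o.map(_COMPLEMENT), oa_o.map(_COMPLEMENT)

    palindromic = _is_palindromic(ea_e, oa_e)
    same = (ea_e == ea_o) & (oa_e == oa_o)
    swapped = (ea_e == oa_o) & (oa_e == ea_o)
    comp_same = (ea_e == ea_oc) & (oa_e == oa_oc)
    comp_swapped = (ea_e == oa_oc) & (oa_e == ea_oc)

    beta_out = merged["beta_out"].to_numpy(dtype=float).copy()
    eaf_out = merged["eaf_out"].to_numpy(dtype=float).copy()
    action = np.full(len(merged), "incompatible_dropped", dtype=object)

    flip = (~palindromic & ~same & (swapped | comp_swapped)) | (palindromic & swapped)
    keep_plain = (~palindromic & (same | comp_same))
    beta_out[flip] = -beta_out[flip]
    eaf_out[flip] = 1.0 - eaf_out[flip]
    action[keep_plain] = "kept"
    action[flip & ~palindromic] = "allele_flipped"

    # Palindromic SNPs: letters cannot distinguish a swap from a strand flip;
    # align by letters, then demand unambiguous, concordant frequencies.
    pal_aligned = palindromic & (same | swapped)
    if palindrome_policy == "drop":
        action[palindromic] = "palindromic_dropped"
    else:
        eaf_exp = merged["eaf_exp"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            informative = (
                ~np.isnan(eaf_exp) & ~np.isnan(eaf_out)
                & (np.minimum(eaf_exp, eaf_out) < eaf_threshold)
                & (np.maximum(eaf_exp, eaf_out) < eaf_threshold)
                | (~np.isnan(eaf_exp) & ~np.isnan(eaf_out)
                   & (np.minimum(eaf_exp, eaf_out) > 1 - eaf_threshold)
                   & (np.maximum(eaf_exp, eaf_out) > 1 - eaf_threshold))
            )
        keep_pal = pal_aligned.to_numpy() & informative
        action[pal_aligned] = "palindromic_dropped"
        action[keep_pal] = "palindromic_kept"

    audit = pd.DataFrame({"snp_id": merged["snp_id"], "action": action})
    kept_mask = np.isin(action, ("kept", "allele_flipped", "palindromic_kept"))
    data = pd.DataFrame({
        "snp_id": merged["snp_id"],
        "beta_exposure": merged["beta_exp"].astype(float),
        "se_exposure": merged["se_exp"].astype(float),
        "beta_outcome": beta_out,
        "se_outcome": merged["se_out"].astype(float),
        "eaf": merged["eaf_exp"].astype(float),
    })[kept_mask].reset_index(drop=True)
    return HarmonizedDataset(data=data, audit=audit)


def to_odds_ratio(beta: float, se: float, level: float = 0.95) -> OddsRatio:
    """Exponentiate a log-odds effect into an odds ratio with a Wald CI."""
    if se < 0:
        raise ValueError("se must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf((1 + level) / 2)
    return OddsRatio(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        level=level,
    )
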