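"""Instrument selection, LD clumping and instrument-strength statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EstimationError, InstrumentSelectionError, LdMatrixError

__all__ = [
    "InstrumentStrength", "select_instruments", "clump",
    "per_snp_r2", "f_statistic", "instrument_strength",
]

#: Conventional weak-instrument threshold: F <= 10 signals weak instruments.
WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class InstrumentStrength:
    """Joint strength of an instrument set: F = ((n-k-1)/k) * R2/(1-R2)."""

    n: int
    k: int
    r2_total: float
    f_stat: float
    weak: bool
    mean_f: float | None = None  #: mean per-SNP F (secondary convention)


def select_instruments(records: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Keep SNPs with ``pval`` strictly below the genome-wide threshold.

    Raises :class:`InstrumentSelectionError` when nothing survives, so a
    pipeline cannot silently continue without instruments.
    """
    kept = records[records["pval"] < p_threshold]
    if len(kept) == 0:
        raise InstrumentSelectionError(
            f"no SNP reached p < {p_threshold:g}; cannot build an instrument set")
    return kept.reset_index(drop=True)


def _ld_lookup(ld_matrix) -> tuple[np.ndarray, dict[str, int]]:
    if isinstance(ld_matrix, pd.DataFrame):
        ids = {s: i for i, s in enumerate(ld_matrix.index.astype(str))}
        return ld_matrix.to_numpy(dtype=float), ids
    raise LdMatrixError("ld_matrix must be a DataFrame indexed by snp_id")


def clump(records: pd.DataFrame, ld_matrix: pd.DataFrame, *,
          r2_threshold: float = 0.001, window_kb: float = 10_000) -> pd.DataFrame:
    """Greedy LD clumping.

    SNPs are visited in order of ascending p-value (ties broken by
    ``snp_id``); each index SNP removes every remaining SNP on the same
    chromosome whose squared correlation with it is >= ``r2_threshold`` and
    whose position lies within ``window_kb``.  Index SNPs are returned in
    selection order.  A missing LD entry for an in-window pair raises
    :class:`LdMatrixError` rather than assuming independence.
    """
    r, ids = _ld_lookup(ld_matrix)
    window_bp = window_kb * 1000.0
    order = records.sort_values(["pval", "snp_id"], kind="mergesort")
    remaining = list(order.index)
    pos = order["pos"].astype(float)
    chrom = order["chrom"].astype(str) if "chrom" in order else pd.Series("1", index=order.index)

    selected = []
    remaining_set = set(remaining)
    for idx in order.index:
        if idx not in remaining_set:
            continue
        remaining_set.discard(idx)
        selected.append(idx)
        lead = order.loc[idx]
        for other in list(remaining_set):
            if chrom[other] != chrom[idx]:
                continue
            p_lead, p_other = pos[idx], pos[other]
            in_window = (np.isnan(p_lead) or np.isnan(p_other)
                         or abs(p_lead - p_other) <= window_bp)
            if not in_window:
                continue
            sid_lead, sid_other = str(lead["snp_id"]), str(order.loc[other, "snp_id"])
            if sid_lead not in ids or sid_other not in ids:
                raise LdMatrixError(
                    f"LD entry missing for in-window pair ({sid_lead}, {sid_other})")
            r2 = r[ids[sid_lead], ids[sid_other]] ** 2
            if np.isnan(r2):
                raise LdMatrixError(
                    f"LD entry missing for in-window pair ({sid_lead}, {sid_other})")
            if r2 >= r2_threshold:
                remaining_set.discard(other)
    return records.loc[selected].reset_index(drop=True)


def per_snp_r2(beta, se, n, *, method: str = "z", eaf=None):
    """Variance in the exposure explained by one SNP.

    ``method="z"`` (default) uses the allele-frequency-free approximation
    r2 = beta^2 / (beta^2 + se^2 * n); ``method="eaf"`` uses the
    standardized-trait form 2 p (1-p) beta^2.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise EstimationError("per_snp_r2 requires se > 0")
    if np.any(np.asarray(n) <= 2):
        raise EstimationError("per_snp_r2 requires n > 2")
    if method == "z":
        return beta ** 2 / (beta ** 2 + se ** 2 * np.asarray(n, dtype=float))
    if method == "eaf":
        if eaf is None:
            raise EstimationError("method='eaf' requires allele frequencies")
        p = np.asarray(eaf, dtype=float)
        return 2.0 * p * (1.0 - p) * beta ** 2
    raise EstimationError(f"unknown per-SNP R2 method: {method!r}")


def f_statistic(n: int, k: int, r2_total: float) -> InstrumentStrength:
    """Joint instrument F statistic ((n-k-1)/k) * (R2/(1-R2)).

    Flags the set as weak when F <= 10, the conventional threshold below
    which weak-instrument bias is a concern.
    """
    if not 0 <= r2_total < 1:
        raise EstimationError("r2_total must lie in [0, 1)")
    if k < 1:
        raise EstimationError("k must be >= 1")
    if n <= k + 1:
        raise EstimationError("require n > k + 1")
    f = ((n - k - 1) / k) * (r2_total / (1.0 - r2_total))
    return InstrumentStrength(n=int(n), k=int(k), r2_total=float(r2_total),
                              f_stat=float(f), weak=bool(f <= WEAK_F_THRESHOLD))


def instrument_strength(records: pd.DataFrame, n: int | None = None) -> InstrumentStrength:
    """Strength of an instrument set from its summary statistics.

    Sums per-SNP R2 over (assumed independent) SNPs, capped just below 1,
    and evaluates the joint F formula; also reports the mean per-SNP F
    (each SNP's F with k=1), the other convention seen in applied work.
    """
    if n is None:
        n_col = records["n"].dropna()
        if len(n_col) == 0:
            raise EstimationError("no sample size available for the F statistic")
        n = int(round(float(n_col.max())))
    r2 = per_snp_r2(records["beta"], records["se"], n)
    r2_total = float(np.minimum(np.sum(r2), 1.0 - 1e-12))
    k = len(records)
    strength = f_statistic(n, k, r2_total)
    per_f = ((n - 2) / 1) * (r2 / (1.0 - r2))
    return InstrumentStrength(n=strength.n, k=strength.k, r2_total=strength.r2_total,
                              f_stat=strength.f_stat, weak=strength.weak,
                              mean_f=float(np.mean(per_f)))
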